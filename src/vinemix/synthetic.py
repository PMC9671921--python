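"""Simulation of vine copula mixture data.

A scenario fixes, per cluster, the marginal distributions, the R-vine copula
model, and the sample size; simulation draws copula samples through the
inverse-Rosenblatt transform and maps them to the data scale with the margin
quantile functions.

The packaged default scenario emulates the two-cluster 6-dimensional design
used throughout the package's benchmarks: margins

==========  ====================  ====================
variable    cluster 1             cluster 2
==========  ====================  ====================
1           Normal(1, 0.4)        Normal(1.5, 0.2)
2           Normal(10, 4)         Gamma(1.5, 0.5)
3           Normal(1.2, 0.2)      Normal(1, 0.3)
4           Gamma(0.9, 0.9)       Gamma(1.5, 0.25)
5           Normal(1.2, 0.45)     Normal(1.3, 0.3)
6           Normal(0.8, 0.8)      Log-normal(1.2, 0.25)
==========  ====================  ====================

(gamma as shape/rate), one D-vine-structured and one C-vine-structured
component, both truncated at tree 2, with a pruned (independence) pair in
tree 2 of each cluster.  The pair-copula table of the packaged scenario is a
synthetic stand-in chosen once to produce moderate-to-strong dependence with
a mix of symmetric and asymmetric, positive and negative pairs; see the
scenario JSON itself for the exact families and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .margins import MarginalModel, inverse_pit
from .rvine import RVineModel, rvine_sample

__all__ = ["ScenarioSpec", "simulate_mixture", "default_scenario",
           "load_scenario", "save_scenario", "DEFAULT_SCENARIO_FILE"]

DEFAULT_SCENARIO_FILE = "two_cluster_6d_synthetic.json"


@dataclass
class ScenarioSpec:
    """A fully specified mixture simulation design."""

    margins: list          # per cluster: list of MarginalModel
    vines: list            # per cluster: RVineModel
    n_per_cluster: tuple   # observations drawn from each cluster
    name: str = "scenario"

    def __post_init__(self):
        dims = {len(m) for m in self.margins} | {v.n for v in self.vines}
        if len(dims) != 1:
            raise ValueError("cluster dimensions differ")
        if len(self.margins) != len(self.vines) or len(self.margins) != len(self.n_per_cluster):
            raise ValueError("margins, vines and n_per_cluster must align per cluster")
        if any(n < 1 for n in self.n_per_cluster):
            raise ValueError("sample sizes must be >= 1")
        self.n_per_cluster = tuple(int(n) for n in self.n_per_cluster)

    @property
    def n_clusters(self) -> int:
        return len(self.vines)

    @property
    def n_features(self) -> int:
        return self.vines[0].n

    @property
    def weights(self) -> np.ndarray:
        n = np.asarray(self.n_per_cluster, dtype=float)
        return n / n.sum()

    def with_sizes(self, n_per_cluster) -> "ScenarioSpec":
        return ScenarioSpec(self.margins, self.vines, tuple(n_per_cluster), self.name)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_per_cluster": list(self.n_per_cluster),
            "clusters": [
                {"margins": [m.to_dict() for m in ms], "vine": v.to_dict()}
                for ms, v in zip(self.margins, self.vines)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        margins = [[MarginalModel.from_dict(m) for m in c["margins"]]
                   for c in d["clusters"]]
        vines = [RVineModel.from_dict(c["vine"]) for c in d["clusters"]]
        return cls(margins, vines, tuple(d["n_per_cluster"]), d.get("name", "scenario"))


def simulate_mixture(spec: ScenarioSpec, seed=None, rng=None, shuffle=True):
    """Draw one data set from the scenario.

    Returns ``(X, labels)``: a (T, n) data matrix and the true cluster labels
    (0-based).  Per cluster, copula samples from the vine are pushed through
    the marginal quantile functions; rows are then shuffled (labels kept in
    step) so cluster order carries no information.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for g, (ms, vine, n_g) in enumerate(zip(spec.margins, spec.vines, spec.n_per_cluster)):
        U = rvine_sample(vine, n_g, rng=rng)
        X = np.column_stack([inverse_pit(m, U[:, j]) for j, m in enumerate(ms)])
        blocks.append(X)
        labels.append(np.full(n_g, g, dtype=int))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    if shuffle:
        perm = rng.permutation(len(y))
        X, y = X[perm], y[perm]
    return X, y


def load_scenario(path) -> ScenarioSpec:
    with open(path) as fh:
        return ScenarioSpec.from_dict(json.load(fh))


def save_scenario(spec: ScenarioSpec, path):
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=1)


def default_scenario(n_per_cluster=None) -> ScenarioSpec:
    """The packaged two-cluster 6-dimensional benchmark scenario.

    ``n_per_cluster`` overrides the stored (300, 300) sample sizes.
    """
    try:
        ref = resources.files("vinemix").joinpath("scenarios", DEFAULT_SCENARIO_FILE)
        spec = ScenarioSpec.from_dict(json.loads(ref.read_text()))
    except FileNotFoundError as exc:  # pragma: no cover
        raise FileNotFoundError(
            f"packaged scenario {DEFAULT_SCENARIO_FILE} missing; reinstall the "
            "package or pass an explicit scenario file") from exc
    if n_per_cluster is not None:
        spec = spec.with_sizes(n_per_cluster)
    return spec
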