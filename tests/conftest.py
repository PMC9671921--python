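"""Shared fixtures.

The replicate studies of the benchmark scenario are expensive (each Tvcmm fit
runs structure selection plus ECM), so they are session-scoped and shared by
the acceptance tests that look at different aspects of the same runs
(misclassification, ECM ascent, truncation levels).
"""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.cluster import KMeans

from vinemix import (
    VineCopulaMixture,
    default_scenario,
    misclassification_rate,
    simulate_mixture,
)

STUDY_SEED = 20205  # fixed seed for the replicate studies
N_REPLICATES = 10


def run_replicate_study(n_per_cluster, replicates=N_REPLICATES, seed=STUDY_SEED):
    """Simulate the benchmark scenario repeatedly; fit Tvcmm and k-means.

    Returns a dict with per-replicate misclassification rates, ECM traces and
    selected truncation levels.
    """
    spec = default_scenario(n_per_cluster)
    out = {"tvcmm": [], "kmeans": [], "traces": [], "trunc": []}
    for child in np.random.SeedSequence(seed).spawn(replicates):
        rng = np.random.default_rng(child)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        X, y = simulate_mixture(spec, rng=rng)
        est = VineCopulaMixture(n_components=2, random_state=fit_seed).fit(X)
        out["tvcmm"].append(misclassification_rate(y, est.labels_))
        out["traces"].append(list(est.loglik_trace_))
        out["trunc"].append(list(est.truncation_levels_))
        km = KMeans(n_clusters=2, n_init=10, random_state=fit_seed).fit_predict(X)
        out["kmeans"].append(misclassification_rate(y, km))
    return out


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def study_300():
    return run_replicate_study((300, 300))


@pytest.fixture(scope="session")
def study_500():
    return run_replicate_study((500, 500))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
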