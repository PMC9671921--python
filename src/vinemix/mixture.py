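"""Finite mixtures of vine copula densities, estimated by ECM.

A component g consists of a weight pi_g, one parametric margin per variable,
and an R-vine copula over the probability-integral-transformed data.  The
mixture density is

    h(x) = sum_g pi_g * [ prod_j f_{gj}(x_j) ] * c_g( F_{g1}(x_1), ..., F_{gn}(x_n) )

Estimation follows the expectation / conditional-maximization scheme: the
E-step computes responsibilities, CM-step 1 updates the weights in closed
form, CM-step 2 numerically updates the marginal parameters (through the full
component density, since the margins enter the copula arguments), and
CM-step 3 re-estimates the pair-copula parameters tree by tree with the
responsibilities as observation weights.  Families, vine structures, pruned
edges and truncation levels stay frozen during ECM; they are re-selected only
in a final refit on the hard-assigned clusters.

The full pipeline (the estimator's ``fit``):

1. k-means partition of the standardized data;
2. per-cluster margin fits and probability integral transform;
3. per-cluster pruned vine fit with mBICV-selected truncation;
4. ECM iterations to convergence of the observed log-likelihood;
5. hard re-assignment by maximum responsibility;
6. full per-cluster re-selection (margins, structure, pruning, truncation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .margins import MarginalModel, fit_margin, pit, DegenerateClusterError
from .rvine import RVineModel, count_parameters, rvine_logdensity
from .selection import fit_rvine, refit_pair_params, select_truncation_mbicv

__all__ = [
    "VineMixtureModel",
    "ClusteringResult",
    "VineCopulaMixture",
    "mixture_logdensity",
    "e_step",
    "cm_step_weights",
    "cm_step_margins",
    "cm_step_copulas",
    "observed_loglik",
    "complete_loglik",
    "fit_tvcmm",
]


@dataclass
class VineMixtureModel:
    """Parameters of a G-component vine copula mixture."""

    weights: np.ndarray                 # (G,)
    margins: list                       # G lists of n MarginalModel
    vines: list                         # G RVineModel

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights <= 0) or np.any(self.weights >= 1):
            if len(self.weights) > 1:
                raise ValueError("mixture weights must lie strictly in (0,1)")
        dims = {len(m) for m in self.margins} | {v.n for v in self.vines}
        if len(dims) != 1:
            raise ValueError("inconsistent dimensions across components")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_features(self) -> int:
        return len(self.margins[0])

    def n_parameters(self) -> int:
        return count_parameters(self.vines, self.margins, self.n_components)

    def component_logdensity(self, X, g: int) -> np.ndarray:
        """Per-row log density of component g (margins times vine copula).

        Rows outside a margin's support get density zero (log density -inf);
        their copula arguments are clipped so the vine term stays finite.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ll = np.zeros(X.shape[0])
        U = np.empty_like(X)
        for j, m in enumerate(self.margins[g]):
            ll += m.logpdf(X[:, j])  # -inf outside the support
            U[:, j] = np.clip(m.cdf(X[:, j]), 1e-10, 1.0 - 1e-10)
        vine_ll = rvine_logdensity(self.vines[g], U)
        with np.errstate(invalid="ignore"):
            out = ll + vine_ll
        out[np.isneginf(ll)] = -np.inf
        return out

    def component_logdensities(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([self.component_logdensity(X, g)
                                for g in range(self.n_components)])

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "margins": [[m.to_dict() for m in ms] for ms in self.margins],
            "vines": [v.to_dict() for v in self.vines],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VineMixtureModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            margins=[[MarginalModel.from_dict(m) for m in ms] for ms in d["margins"]],
            vines=[RVineModel.from_dict(v) for v in d["vines"]],
        )


@dataclass
class ClusteringResult:
    model: VineMixtureModel
    responsibilities: np.ndarray
    labels: np.ndarray
    loglik_trace: list
    truncation_levels: list
    n_parameters: int
    loglik: float
    bic: float
    n_iter: int
    converged: bool
    misclassification: float | None = None


# ----------------------------------------------------------------------
# core operations
# ----------------------------------------------------------------------

def mixture_logdensity(m: VineMixtureModel, X) -> np.ndarray:
    """log h(x) = log sum_g pi_g h_g(x), computed with log-sum-exp."""
    lls = m.component_logdensities(X)
    return logsumexp(lls + np.log(m.weights)[None, :], axis=1)


def e_step(m: VineMixtureModel, X) -> np.ndarray:
    """Posterior membership probabilities r_{t,g} (rows sum to one)."""
    lls = m.component_logdensities(X) + np.log(m.weights)[None, :]
    norm = logsumexp(lls, axis=1, keepdims=True)
    if not np.all(np.isfinite(norm)):
        bad = int(np.flatnonzero(~np.isfinite(norm.ravel()))[0])
        raise FloatingPointError(f"zero mixture density at row {bad}")
    return np.exp(lls - norm)


def cm_step_weights(r: np.ndarray) -> np.ndarray:
    """Closed-form weight update: pi_g = mean_t r_{t,g}."""
    r = np.asarray(r, dtype=float)
    col = r.sum(axis=0)
    if np.any(col <= 0):
        g = int(np.flatnonzero(col <= 0)[0])
        raise DegenerateClusterError(
            f"component {g} received zero total responsibility; restart with a "
            "different initialization")
    return col / r.shape[0]


# unconstrained reparameterizations for the numeric margin update
_MARGIN_PACK = {
    "normal": (lambda p: (p[0], math.log(p[1])),
               lambda z: (z[0], math.exp(z[1]))),
    "lognormal": (lambda p: (p[0], math.log(p[1])),
                  lambda z: (z[0], math.exp(z[1]))),
    "gamma": (lambda p: (math.log(p[0]), math.log(p[1])),
              lambda z: (math.exp(z[0]), math.exp(z[1]))),
    "logistic": (lambda p: (p[0], math.log(p[1])),
                 lambda z: (z[0], math.exp(z[1]))),
    "student_t": (lambda p: (math.log(p[0]), p[1], math.log(p[2])),
                  lambda z: (min(max(math.exp(z[0]), 2.05), 200.0), z[1], math.exp(z[2]))),
}


def _weighted_component_obj(X, w, margins, vine):
    """sum_t w_t ln h_g(x_t) for one component.

    Rows with (numerically) zero responsibility are excluded, so a component
    is not penalized for observations outside its margins' support that it
    anyway does not claim.
    """
    active = w > 1e-14
    Xa, wa = X[active], w[active]
    ll = np.zeros(Xa.shape[0])
    U = np.empty_like(Xa)
    try:
        for j, m in enumerate(margins):
            ll += m.logpdf(Xa[:, j])
            U[:, j] = np.clip(m.cdf(Xa[:, j]), 1e-10, 1.0 - 1e-10)
        ll += rvine_logdensity(vine, U)
    except (ValueError, FloatingPointError):
        return -np.inf
    if not np.all(np.isfinite(ll)):
        return -np.inf
    return float(np.sum(wa * ll))


def cm_step_margins(X, r, model: VineMixtureModel, max_nm_iter: int = 150) -> VineMixtureModel:
    """CM-step 2: numeric coordinate update of the marginal parameters.

    For each component and variable, the weighted *full* component
    log-likelihood (margins and vine, since the margin enters the copula
    arguments through the PIT) is maximized over that margin's parameters,
    keeping everything else fixed.  One pass per variable; an update is kept
    only if it improves the objective, so the step is a conditional ascent.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    new_margins = [list(ms) for ms in model.margins]
    for g in range(model.n_components):
        w = r[:, g]
        vine = model.vines[g]
        for j in range(model.n_features):
            incumbent = new_margins[g][j]
            pack, unpack = _MARGIN_PACK[incumbent.family]
            base = _weighted_component_obj(X, w, new_margins[g], vine)

            def neg_obj(z, j=j, g=g):
                try:
                    cand = MarginalModel(incumbent.family, unpack(z),
                                         incumbent.parameterization)
                except ValueError:
                    return 1e300  # large finite keeps Nelder-Mead quiet
                if not cand.support_contains(X[:, j]):
                    return 1e300
                trial = list(new_margins[g])
                trial[j] = cand
                val = _weighted_component_obj(X, w, trial, vine)
                return -val if np.isfinite(val) else 1e300

            res = optimize.minimize(neg_obj, x0=np.asarray(pack(incumbent.params)),
                                    method="Nelder-Mead",
                                    options={"maxiter": max_nm_iter,
                                             "xatol": 1e-5, "fatol": 1e-8})
            if np.isfinite(res.fun) and -res.fun > base:
                new_margins[g][j] = MarginalModel(incumbent.family, unpack(res.x),
                                                  incumbent.parameterization)
    return VineMixtureModel(model.weights, new_margins, model.vines)


def cm_step_copulas(X, r, model: VineMixtureModel) -> VineMixtureModel:
    """CM-step 3: weighted sequential re-estimation of pair-copula parameters.

    Structures, families, pruned edges and truncation levels stay frozen; the
    copula data are refreshed from the current margins.  Reverts a
    component's update if it does not improve that component's weighted
    log-likelihood (sequential per-edge estimation is not exactly joint
    maximization).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    new_vines = []
    for g in range(model.n_components):
        active = r[:, g] > 1e-14
        w = r[active, g]
        U = np.column_stack([
            np.clip(m.cdf(X[active, j]), 1e-10, 1.0 - 1e-10)
            for j, m in enumerate(model.margins[g])
        ])
        cand = refit_pair_params(model.vines[g], U, weights=w)
        before = float(np.sum(w * rvine_logdensity(model.vines[g], U)))
        after = float(np.sum(w * rvine_logdensity(cand, U)))
        new_vines.append(cand if after >= before else model.vines[g])
    return VineMixtureModel(model.weights, model.margins, new_vines)


def observed_loglik(m: VineMixtureModel, X) -> float:
    """Observed-data log-likelihood: sum of log mixture densities."""
    return float(np.sum(mixture_logdensity(m, X)))


def complete_loglik(m: VineMixtureModel, X, z) -> float:
    """Complete-data log-likelihood given hard labels z in 0..G-1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    z = np.asarray(z, dtype=int)
    lls = m.component_logdensities(X)
    return float(np.sum(np.log(m.weights)[z] + lls[np.arange(len(z)), z]))


# ----------------------------------------------------------------------
# the estimator
# ----------------------------------------------------------------------

class VineCopulaMixture(BaseEstimator, ClusterMixin):
    """Model-based clustering with a mixture of pruned, truncated R-vines.

    Parameters
    ----------
    n_components : int
        Number of mixture components G (assumed known).
    margin_families : sequence of str or None
        Candidate marginal families (default: normal, lognormal, gamma,
        logistic, student_t; positive-support families are offered only for
        positive columns).
    copula_families : sequence of str or None
        Candidate pair-copula families (default: full catalogue with
        rotations handled internally).
    prune_alpha : float
        Level of the Kendall-tau independence test used to prune edges;
        0 disables pruning.
    psi0 : float
        Prior probability that a tree-1 pair-copula is non-independent; the
        prior decays as psi0^i with tree level i in the mBICV.
    truncation : "mbicv" | int | "none"
        Truncation-level selection at the initial and final vine fits.
    final_truncation : like ``truncation``, or None
        Override for the final (step 6) vine fits; None reuses ``truncation``.
        Setting ``truncation=1, final_truncation="none", prune_alpha=0``
        recovers the antecedent fixed-Markov-tree pipeline (Fvcmm).
    final_refit : bool
        Whether step 6 re-selects margins/structure/truncation on the
        hard-assigned clusters.
    tol : float
        Relative observed log-likelihood change declaring ECM convergence.
    max_iter : int
        Maximum ECM iterations.
    min_cluster_size : int
        Minimum observations per initial cluster; smaller clusters trigger a
        re-initialization (bounded retries).
    random_state : int or None
        Seed for k-means initialization and any internal randomness.

    Attributes (after ``fit``)
    --------------------------
    model_ : VineMixtureModel
    weights_, margins_, vines_ : unpacked model parameters
    responsibilities_ : (T, G) posterior membership probabilities
    labels_ : hard assignments
    loglik_trace_ : observed log-likelihood per ECM iteration (nondecreasing)
    truncation_levels_ : selected level per component
    n_parameters_ : total parameter count delta
    bic_ : -2 loglik + delta ln T of the final model
    n_iter_, converged_
    """

    def __init__(self, n_components=2, margin_families=None, copula_families=None,
                 prune_alpha=0.05, psi0=0.9, truncation="mbicv", final_truncation=None,
                 final_refit=True, tol=1e-4, max_iter=100, min_cluster_size=15,
                 kmeans_restarts=10, random_state=None):
        self.n_components = n_components
        self.margin_families = margin_families
        self.copula_families = copula_families
        self.prune_alpha = prune_alpha
        self.psi0 = psi0
        self.truncation = truncation
        self.final_truncation = final_truncation
        self.final_refit = final_refit
        self.tol = tol
        self.max_iter = max_iter
        self.min_cluster_size = min_cluster_size
        self.kmeans_restarts = kmeans_restarts
        self.random_state = random_state

    # -- helpers --------------------------------------------------------
    def _fit_cluster_margins(self, Xg):
        return [fit_margin(Xg[:, j], family_set=self.margin_families)
                for j in range(Xg.shape[1])]

    def _fit_cluster_vine(self, U, weights=None, final=False):
        trunc = self.truncation
        if final and self.final_truncation is not None:
            trunc = self.final_truncation
        if trunc == "mbicv":
            model, _ = select_truncation_mbicv(
                U, family_set=self.copula_families, prune_alpha=self.prune_alpha,
                psi0=self.psi0, weights=weights)
            return model
        trunc = "none" if trunc in (None, "none") else int(trunc)
        return fit_rvine(U, family_set=self.copula_families,
                         prune_alpha=self.prune_alpha, trunc=trunc,
                         weights=weights, psi0=self.psi0)

    def _initial_partition(self, X, rng):
        G = self.n_components
        for attempt in range(8):
            seed = int(rng.integers(0, 2**31 - 1))
            Xs = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
            km = KMeans(n_clusters=G, n_init=self.kmeans_restarts, random_state=seed)
            labels = km.fit_predict(Xs)
            sizes = np.bincount(labels, minlength=G)
            if np.all(sizes >= self.min_cluster_size):
                return labels
        raise DegenerateClusterError(
            f"k-means produced a cluster below {self.min_cluster_size} observations "
            "in every retry")

    def _build_model(self, X, labels):
        G = self.n_components
        weights = np.bincount(labels, minlength=G) / len(labels)
        weights = np.clip(weights, 1e-6, None)
        weights = weights / weights.sum()
        margins, vines = [], []
        for g in range(G):
            Xg = X[labels == g]
            ms = self._fit_cluster_margins(Xg)
            U = np.column_stack([pit(m, Xg[:, j]) for j, m in enumerate(ms)])
            vines.append(self._fit_cluster_vine(U))
            margins.append(ms)
        return VineMixtureModel(weights, margins, vines)

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        T, n = X.shape
        G = self.n_components
        if T <= G * self.min_cluster_size:
            raise ValueError(f"need more than {G * self.min_cluster_size} rows for G={G}")
        rng = np.random.default_rng(self.random_state)

        if G == 1:
            labels = np.zeros(T, dtype=int)
        else:
            labels = self._initial_partition(X, rng)
        model = self._build_model(X, labels)

        trace = []
        converged = False
        prev_ll = -np.inf
        r = np.eye(G)[labels]
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            r = e_step(model, X)
            if G > 1:
                model = VineMixtureModel(cm_step_weights(r), model.margins, model.vines)
            model = cm_step_margins(X, r, model)
            model = cm_step_copulas(X, r, model)
            ll = observed_loglik(model, X)
            trace.append(ll)
            if np.isfinite(prev_ll):
                rel = abs(ll - prev_ll) / max(abs(prev_ll), 1.0)
                if rel < self.tol:
                    converged = True
                    break
            prev_ll = ll

        r = e_step(model, X)
        labels = np.argmax(r, axis=1)  # argmax ties resolve to the lower index

        if self.final_refit and G > 1:
            sizes = np.bincount(labels, minlength=G)
            if np.all(sizes >= max(self.min_cluster_size, n + 1)):
                model = VineMixtureModel(model.weights,
                                         *self._refit_components(X, labels))
                r = e_step(model, X)
                labels = np.argmax(r, axis=1)
            else:
                warnings.warn("skipping final refit: a hard cluster is too small")

        ll = observed_loglik(model, X)
        delta = model.n_parameters()
        self.model_ = model
        self.weights_ = model.weights
        self.margins_ = model.margins
        self.vines_ = model.vines
        self.responsibilities_ = r
        self.labels_ = labels
        self.loglik_trace_ = trace
        self.truncation_levels_ = [v.truncation_level for v in model.vines]
        self.n_parameters_ = delta
        self.loglik_ = ll
        self.bic_ = -2.0 * ll + delta * math.log(T)
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def _refit_components(self, X, labels):
        margins, vines = [], []
        for g in range(self.n_components):
            Xg = X[labels == g]
            ms = self._fit_cluster_margins(Xg)
            U = np.column_stack([pit(m, Xg[:, j]) for j, m in enumerate(ms)])
            vines.append(self._fit_cluster_vine(U, final=True))
            margins.append(ms)
        return margins, vines

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)

    def predict_proba(self, X):
        return e_step(self.model_, X)

    def score(self, X, y=None):
        """Mean observed log-likelihood per observation."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return observed_loglik(self.model_, X) / X.shape[0]

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def result(self, y_true=None) -> ClusteringResult:
        """Bundle the fitted state as a :class:`ClusteringResult`."""
        mis = None
        if y_true is not None:
            from .evaluation import misclassification_rate

            mis = misclassification_rate(y_true, self.labels_)
        return ClusteringResult(
            model=self.model_, responsibilities=self.responsibilities_,
            labels=self.labels_, loglik_trace=self.loglik_trace_,
            truncation_levels=self.truncation_levels_,
            n_parameters=self.n_parameters_, loglik=self.loglik_,
            bic=self.bic_, n_iter=self.n_iter_, converged=self.converged_,
            misclassification=mis)


def fit_tvcmm(X, G: int = 2, y_true=None, **kwargs) -> ClusteringResult:
    """Run the full pruned/truncated vine mixture pipeline.

    Thin functional wrapper over :class:`VineCopulaMixture`; keyword
    arguments are forwarded to the estimator.
    """
    est = VineCopulaMixture(n_components=G, **kwargs)
    est.fit(np.asarray(X, dtype=float))
    return est.result(y_true=y_true)
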