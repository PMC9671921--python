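"""Data-driven vine construction.

The structure of each tree is chosen greedily: a maximum spanning tree on
absolute empirical Kendall's tau, restricted (from tree 2 on) to pairs of
edges satisfying the proximity condition.  Each selected edge is first
screened with the asymptotic Kendall-tau independence test — if independence
is not rejected the edge is *pruned* (assigned the independence copula) —
otherwise its pair-copula family is chosen by AIC among the candidate
catalogue.  The truncation level is selected by a modified BIC (mBICV) that
places a geometrically decaying prior on non-independence copulas per tree:
trees are added one at a time until the criterion stops improving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .bivariate import (
    INDEPENDENCE,
    BivariateCopula,
    FAMILIES,
    bicop_hfunc,
    fit_bicop,
    _weighted_tau,
)
from .rvine import RVineModel, RVineStructure, VineEdge

__all__ = [
    "kendall_tau",
    "independence_test",
    "IndependenceTestResult",
    "aic",
    "bic",
    "mbicv",
    "fit_rvine",
    "select_truncation_mbicv",
    "TruncationSearchTrace",
    "refit_pair_params",
]


def kendall_tau(x, y) -> float:
    """Kendall's tau-b (ties-corrected concordance measure)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("kendall_tau needs two equal-length vectors of size >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Kendall's tau undefined for a constant vector")
    return float(stats.kendalltau(x, y).statistic)


@dataclass(frozen=True)
class IndependenceTestResult:
    tau_hat: float
    statistic: float
    critical_value: float
    rejected: bool
    alpha: float
    n: float


def independence_test(tau_hat: float, n, alpha: float = 0.05) -> IndependenceTestResult:
    """Asymptotic test of pairwise independence based on Kendall's tau.

    Under independence, tau_hat * sqrt(9 n (n-1) / (2 (2n+5))) is
    approximately standard normal; the two-sided test compares its absolute
    value to the (1 - alpha/2) normal quantile.
    """
    if n < 10:
        raise ValueError("independence test requires n >= 10")
    statistic = abs(tau_hat) * math.sqrt(9.0 * n * (n - 1.0) / (2.0 * (2.0 * n + 5.0)))
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return IndependenceTestResult(
        tau_hat=float(tau_hat), statistic=float(statistic),
        critical_value=float(crit), rejected=bool(statistic > crit),
        alpha=float(alpha), n=float(n))


def aic(loglik: float, p: int) -> float:
    return -2.0 * loglik + 2.0 * p


def bic(loglik: float, p: int, T) -> float:
    if T < 1:
        raise ValueError("T must be >= 1")
    return -2.0 * loglik + p * math.log(T)


def mbicv(m: RVineModel, U, psi0: float = 0.9, weights=None) -> float:
    """Modified BIC for vines with a tree-decaying sparsity prior.

    -2 loglik + nparams * ln T - 2 * sum_i [ q_i ln(psi0^i)
                                             + (n-i-q_i) ln(1-psi0^i) ]
    with q_i the non-independence copula count in tree i and prior
    probability psi0^i that a tree-i edge is non-independent.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    from .rvine import rvine_logdensity

    if weights is None:
        w = np.ones(U.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    ll = float(np.sum(w * rvine_logdensity(m, U)))
    T = float(np.sum(w))
    return _mbicv_from_parts(ll, m.n_copula_params(), m.nonindependence_counts(),
                             m.n, T, psi0)


def _mbicv_from_parts(loglik, n_params, q, n, T, psi0):
    prior = 0.0
    for i in range(1, n):
        p_i = psi0 ** i
        prior += q[i - 1] * math.log(p_i) + (n - i - q[i - 1]) * math.log(1.0 - p_i)
    return -2.0 * loglik + n_params * math.log(T) - 2.0 * prior


@dataclass
class TruncationSearchTrace:
    levels: list = field(default_factory=list)
    mbicv_values: list = field(default_factory=list)
    q_per_level: list = field(default_factory=list)
    n_params_per_level: list = field(default_factory=list)
    selected_level: int = 0

    def to_rows(self):
        return [
            {"level": l, "mbicv": v, "q": q, "n_params": p}
            for l, v, q, p in zip(self.levels, self.mbicv_values,
                                  self.q_per_level, self.n_params_per_level)
        ]


# ----------------------------------------------------------------------
# greedy sequential construction
# ----------------------------------------------------------------------

class _Node:
    """A node of the tree being built: wraps an edge of the previous tree."""

    __slots__ = ("variables", "conditioning", "parents", "pseudo_keys")

    def __init__(self, variables, conditioning, parents):
        self.variables = frozenset(variables)
        self.conditioning = frozenset(conditioning)
        self.parents = parents  # pair of previous-tree node indices (adjacency tracking)


class _VineBuilder:
    """Incremental Dissmann-style construction with pruning.

    Keeps the pseudo-observation cache so trees can be added one at a time
    (used by the mBICV truncation search).
    """

    def __init__(self, U, weights=None, family_set=None, prune_alpha=0.05,
                 criterion="aic"):
        U = np.atleast_2d(np.asarray(U, dtype=float))
        self.U = U
        self.T, self.n = U.shape
        if self.n < 2:
            raise ValueError("need at least 2 variables")
        for j in range(self.n):
            if np.allclose(U[:, j], U[0, j]):
                raise ValueError(f"column {j} is degenerate (constant)")
        self.w = np.ones(self.T) if weights is None else np.asarray(weights, dtype=float)
        self.uniform_w = weights is None or np.allclose(self.w, self.w[0])
        self.n_eff = (float(np.sum(self.w)) ** 2 / float(np.sum(self.w ** 2))
                      if not self.uniform_w else float(self.T))
        self.family_set = list(FAMILIES) if family_set is None else list(family_set)
        self.prune_alpha = float(prune_alpha)
        self.criterion = criterion
        self.pseudo = {(j, frozenset()): U[:, j] for j in range(self.n)}
        # current nodes: the variables themselves
        self.nodes = [_Node({j}, frozenset(), (j,)) for j in range(self.n)]
        self.trees: list = []
        self.copulas: list = []
        self.loglik_per_tree: list = []

    def _tau(self, u1, u2):
        if self.uniform_w:
            return float(stats.kendalltau(u1, u2).statistic)
        return _weighted_tau(u1, u2, self.w)

    def _edge_between(self, i, j):
        ni, nj = self.nodes[i], self.nodes[j]
        cond = ni.variables & nj.variables
        a, b = sorted(ni.variables ^ nj.variables)
        return VineEdge(a, b, cond)

    def add_tree(self):
        """Select and fit the next tree; returns its weighted log-likelihood."""
        import networkx as nx

        level = len(self.trees) + 1
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        candidates = {}
        for i in range(len(self.nodes)):
            for j in range(i + 1, len(self.nodes)):
                if level > 1:
                    # proximity: the two previous-tree edges must share a node
                    if not (set(self.nodes[i].parents) & set(self.nodes[j].parents)):
                        continue
                e = self._edge_between(i, j)
                u1 = self.pseudo[(e.a, e.conditioning)]
                u2 = self.pseudo[(e.b, e.conditioning)]
                tau = self._tau(u1, u2)
                candidates[(i, j)] = (e, tau)
                g.add_edge(i, j, weight=-abs(tau))
        if g.number_of_nodes() > 1 and nx.number_connected_components(g) > 1:
            raise RuntimeError("proximity graph disconnected; invalid builder state")
        mst = nx.minimum_spanning_tree(g, algorithm="kruskal")

        tree_edges, tree_cops, new_nodes = [], [], []
        ll_tree = 0.0
        for i, j in sorted(mst.edges()):
            e, tau = candidates[(i, j)]
            u1 = self.pseudo[(e.a, e.conditioning)]
            u2 = self.pseudo[(e.b, e.conditioning)]
            test = independence_test(tau, self.n_eff, self.prune_alpha) \
                if self.prune_alpha > 0 else None
            if test is not None and not test.rejected:
                cop = INDEPENDENCE
            else:
                cop = fit_bicop(u1, u2, weights=None if self.uniform_w else self.w,
                                family_set=self.family_set, criterion=self.criterion,
                                tau_hat=tau)
            if cop.family != "independence":
                ll_tree += float(np.sum(self.w * cop.logpdf(u1, u2)))
            self.pseudo[(e.a, e.conditioning | {e.b})] = bicop_hfunc(cop, u1, u2, "second")
            self.pseudo[(e.b, e.conditioning | {e.a})] = bicop_hfunc(cop, u1, u2, "first")
            tree_edges.append(e)
            tree_cops.append(cop)
            new_nodes.append(_Node(e.variables, e.conditioning, (i, j)))
        self.trees.append(tree_edges)
        self.copulas.append(tree_cops)
        self.loglik_per_tree.append(ll_tree)
        self.nodes = new_nodes
        return ll_tree

    def model(self, truncation_level=None) -> RVineModel:
        k = len(self.trees) if truncation_level is None else truncation_level
        return RVineModel(
            RVineStructure(self.n, self.trees[:max(k, 0)] if k < len(self.trees) else self.trees),
            self.copulas[:k] if k < len(self.copulas) else self.copulas,
            truncation_level=k,
        )


def fit_rvine(U, family_set=None, prune_alpha: float = 0.05, trunc="none",
              weights=None, criterion="aic", psi0: float = 0.9) -> RVineModel:
    """Fit an R-vine copula to pseudo-observations.

    Parameters
    ----------
    trunc : "none", "mbicv", or an integer level
        "none" builds all n-1 trees; an integer stops after that many trees
        (higher trees set to independence); "mbicv" selects the level by the
        modified BIC search.
    """
    if trunc == "mbicv":
        model, _ = select_truncation_mbicv(U, family_set=family_set,
                                           prune_alpha=prune_alpha, psi0=psi0,
                                           weights=weights, criterion=criterion)
        return model
    builder = _VineBuilder(U, weights=weights, family_set=family_set,
                           prune_alpha=prune_alpha, criterion=criterion)
    n_trees = builder.n - 1 if trunc in (None, "none") else int(trunc)
    if not (0 <= n_trees <= builder.n - 1):
        raise ValueError(f"truncation level {n_trees} out of range")
    for _ in range(n_trees):
        builder.add_tree()
    return builder.model(truncation_level=n_trees)


def select_truncation_mbicv(U, family_set=None, prune_alpha: float = 0.05,
                            psi0: float = 0.9, weights=None, criterion="aic"):
    """Grow the vine one tree at a time until mBICV stops improving.

    Returns ``(model, trace)``: the model truncated at the selected level and
    the search trace (levels, criterion values, per-tree non-independence
    counts).
    """
    builder = _VineBuilder(U, weights=weights, family_set=family_set,
                           prune_alpha=prune_alpha, criterion=criterion)
    n = builder.n
    T_eff = float(np.sum(builder.w))
    trace = TruncationSearchTrace()

    def record(level):
        ll = float(np.sum(builder.loglik_per_tree[:level]))
        q = [sum(1 for c in tc if c.family != "independence")
             for tc in builder.copulas[:level]]
        q = q + [0] * (n - 1 - len(q))
        n_params = sum(c.n_params for tc in builder.copulas[:level] for c in tc)
        val = _mbicv_from_parts(ll, n_params, q, n, T_eff, psi0)
        trace.levels.append(level)
        trace.mbicv_values.append(val)
        trace.q_per_level.append(q[:level])
        trace.n_params_per_level.append(n_params)
        return val

    builder.add_tree()
    best_val = record(1)
    best_level = 1
    for level in range(2, n):
        builder.add_tree()
        val = record(level)
        if val >= best_val:
            break
        best_val, best_level = val, level
    trace.selected_level = best_level
    return builder.model(truncation_level=best_level), trace


# ----------------------------------------------------------------------
# parameter-only refits (ECM CM-step for the copulas)
# ----------------------------------------------------------------------

def refit_pair_params(m: RVineModel, U, weights=None) -> RVineModel:
    """Re-estimate pair-copula parameters with families/structure frozen.

    Walks the trees in order (so conditional pseudo-observations reflect the
    updated lower-tree parameters) and maximizes each edge's weighted
    log-likelihood within its family, starting from the incumbent parameters.
    """
    from scipy import optimize

    from .bivariate import _PARAM_BOUNDS, _weighted_negloglik

    U = np.atleast_2d(np.asarray(U, dtype=float))
    w = np.ones(U.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    pseudo = {(j, frozenset()): np.clip(U[:, j], 1e-10, 1 - 1e-10) for j in range(m.n)}
    new_copulas = []
    for t, (tree, cops) in enumerate(zip(m.structure.trees, m.copulas)):
        new_tree_cops = []
        for e, cop in zip(tree, cops):
            u1 = pseudo[(e.a, e.conditioning)]
            u2 = pseudo[(e.b, e.conditioning)]
            if cop.family != "independence" and t < m.truncation_level:
                bounds = _PARAM_BOUNDS[cop.family]
                incumbent_nll = _weighted_negloglik(cop.family, cop.rotation,
                                                    cop.params, u1, u2, w)

                def nll(p):
                    return _weighted_negloglik(cop.family, cop.rotation, p, u1, u2, w)

                if len(bounds) == 1:
                    res = optimize.minimize_scalar(lambda th: nll([th]),
                                                   bounds=bounds[0], method="bounded",
                                                   options={"xatol": 1e-6})
                    cand, val = (float(res.x),), res.fun
                else:
                    res = optimize.minimize(nll, x0=np.array(cop.params),
                                            method="L-BFGS-B", bounds=bounds,
                                            options={"maxiter": 25, "ftol": 1e-9})
                    cand, val = tuple(float(x) for x in res.x), res.fun
                if np.isfinite(val) and val < incumbent_nll:
                    cop = BivariateCopula(cop.family, cand, cop.rotation)
            new_tree_cops.append(cop)
            pseudo[(e.a, e.conditioning | {e.b})] = bicop_hfunc(cop, u1, u2, "second")
            pseudo[(e.b, e.conditioning | {e.a})] = bicop_hfunc(cop, u1, u2, "first")
        new_copulas.append(new_tree_cops)
    return RVineModel(m.structure, new_copulas, m.truncation_level)
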