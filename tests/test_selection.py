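"""Structure selection, pruning, information criteria, truncation search."""

import math

import numpy as np
import pytest

from vinemix.bivariate import BivariateCopula as B, bicop_sample, par_to_tau
from vinemix.rvine import RVineModel, RVineStructure, VineEdge, rvine_sample
from vinemix.selection import (
    aic,
    bic,
    fit_rvine,
    independence_test,
    kendall_tau,
    mbicv,
    refit_pair_params,
    select_truncation_mbicv,
)

fs = frozenset


def brute_force_tau(x, y):
    """O(n^2) concordance count oracle (no ties)."""
    n = len(x)
    c = d = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            c += s > 0
            d += s < 0
    return (c - d) / (n * (n - 1) / 2)


def test_kendall_tau_perfect_and_reversed():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert kendall_tau(x, x) == pytest.approx(1.0)
    assert kendall_tau(x, -x) == pytest.approx(-1.0)


def test_kendall_tau_small_example_brute_force():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 3.0, 2.0, 4.0])
    assert brute_force_tau(x, y) == pytest.approx(2 / 3)
    assert kendall_tau(x, y) == pytest.approx(2 / 3)


def test_kendall_tau_matches_brute_force_random(rng):
    x = rng.normal(size=60)
    y = 0.5 * x + rng.normal(size=60)
    assert kendall_tau(x, y) == pytest.approx(brute_force_tau(x, y), abs=1e-12)


def test_kendall_tau_constant_vector_raises():
    with pytest.raises(ValueError, match="constant"):
        kendall_tau(np.ones(10), np.arange(10.0))


def test_independence_test_statistic_formula():
    res = independence_test(0.0, 200, alpha=0.05)
    assert res.statistic == 0.0 and not res.rejected
    res = independence_test(0.3, 100, alpha=0.05)
    expected = 0.3 * math.sqrt(9 * 100 * 99 / (2 * 205))
    assert res.statistic == pytest.approx(expected)
    assert res.statistic == pytest.approx(4.4225, abs=1e-3)
    assert res.rejected and res.critical_value == pytest.approx(1.959964, abs=1e-5)
    assert res.rejected == (abs(res.statistic) > res.critical_value)


def test_aic_bic_arithmetic():
    assert aic(0.0, 0) == 0.0
    assert aic(-100.0, 4) == 208.0
    assert bic(0.0, 0, 10) == 0.0
    assert bic(-100.0, 4, 100) == pytest.approx(200 + 4 * math.log(100))
    assert aic(-50.0, 1) < aic(-50.0, 3)


def test_mbicv_all_independence_value():
    n, T, psi0 = 4, 200, 0.9
    s = RVineStructure.dvine(list(range(n)))
    cops = [[B("independence")] * (n - 1 - t) for t in range(n - 1)]
    m = RVineModel(s, cops)
    U = np.random.default_rng(0).uniform(size=(T, n))
    expected = -2.0 * sum((n - i) * math.log(1 - psi0 ** i) for i in range(1, n))
    assert mbicv(m, U, psi0) == pytest.approx(expected)


def test_mbicv_hand_computed_three_dim():
    # n=3, T=100, psi0=0.9, one 1-parameter tree-1 edge, copula loglik = 50
    n, T, psi0, loglik, npar = 3, 100, 0.9, 50.0, 1
    q = [1, 0]
    prior = (q[0] * math.log(psi0) + (n - 1 - q[0]) * math.log(1 - psi0)
             + q[1] * math.log(psi0 ** 2) + (n - 2 - q[1]) * math.log(1 - psi0 ** 2))
    expected = -2 * loglik + npar * math.log(T) - 2 * prior
    from vinemix.selection import _mbicv_from_parts

    assert _mbicv_from_parts(loglik, npar, q, n, T, psi0) == pytest.approx(expected)


def test_mbicv_penalizes_useless_edge():
    # adding a zero-gain 1-parameter tree-1 edge increases mBICV whenever
    # ln(T) - 2 ln(psi0/(1-psi0)) > 0
    from vinemix.selection import _mbicv_from_parts

    n, psi0 = 4, 0.9
    T = 200  # ln 200 = 5.3 > 2 ln 9 = 4.39
    base = _mbicv_from_parts(0.0, 0, [0, 0, 0], n, T, psi0)
    plus = _mbicv_from_parts(0.0, 1, [1, 0, 0], n, T, psi0)
    assert plus - base == pytest.approx(
        math.log(T) - 2 * math.log(psi0 / (1 - psi0)))
    assert plus > base


def test_two_dim_independent_uniforms_pruned(rng):
    U = rng.uniform(size=(400, 2))
    m = fit_rvine(U, trunc="none")
    assert m.copulas[0][0].family == "independence"


def test_prune_alpha_zero_forces_parametric_fit(rng):
    U = rng.uniform(size=(400, 2))
    m = fit_rvine(U, prune_alpha=0.0, trunc="none",
                  family_set=["gaussian"])
    assert m.copulas[0][0].family == "gaussian"
    assert abs(m.copulas[0][0].params[0]) < 0.15


def test_fit_rvine_recovers_three_dim_taus():
    s = RVineStructure(3, [[VineEdge(2, 1), VineEdge(1, 0)],
                           [VineEdge(2, 0, fs({1}))]])
    cops = [[B("clayton", (2.0,)), B("gumbel", (1.8,))], [B("gaussian", (0.5,))]]
    true = RVineModel(s, cops)
    U = rvine_sample(true, 2000, seed=11)
    fit = fit_rvine(U, trunc="none")
    emp = {frozenset((e.a, e.b)): par_to_tau(c) for e, c in
           zip(fit.structure.trees[0], fit.copulas[0])}
    true_taus = {frozenset((2, 1)): 0.5, frozenset((1, 0)): 1 - 1 / 1.8}
    for pair, tau in true_taus.items():
        if pair in emp:  # tree 1 of the greedy fit normally recovers both
            assert emp[pair] == pytest.approx(tau, abs=0.05)
    assert sum(pair in emp for pair in true_taus) >= 1


def test_pruned_edges_pass_independence_test(rng):
    U = rng.uniform(size=(300, 4))
    m = fit_rvine(U, prune_alpha=0.05, trunc="none")
    for e, c in zip(m.structure.trees[0], m.copulas[0]):
        if c.family == "independence":
            tau = kendall_tau(U[:, e.a], U[:, e.b])
            assert not independence_test(tau, 300, 0.05).rejected


def test_tree_one_mst_beats_random_spanning_trees(rng):
    import itertools

    from vinemix.selection import kendall_tau as kt

    d = 5
    A = rng.normal(size=(300, d)) @ rng.normal(size=(d, d))
    U = (np.argsort(np.argsort(A, axis=0), axis=0) + 0.5) / 300
    m = fit_rvine(U, trunc=1, prune_alpha=0.0)
    mst_weight = sum(abs(kt(U[:, e.a], U[:, e.b])) for e in m.structure.trees[0])
    rng2 = np.random.default_rng(0)
    for _ in range(20):
        # random spanning tree via random Prufer sequence
        prufer = rng2.integers(0, d, size=d - 2)
        import networkx as nx

        tree = nx.from_prufer_sequence(list(prufer))
        w = sum(abs(kt(U[:, a], U[:, b])) for a, b in tree.edges())
        assert w <= mst_weight + 1e-12


def test_truncation_search_trace_consistent(rng):
    s = RVineStructure.cvine([0, 1, 2, 3])
    cops = [[B("gaussian", (0.7,)), B("clayton", (2.0,)), B("gumbel", (2.0,))],
            [B("frank", (4.0,)), B("gaussian", (0.4,))],
            [B("independence")]]
    true = RVineModel(s, cops, truncation_level=2)
    U = rvine_sample(true, 800, seed=21)
    model, trace = select_truncation_mbicv(U)
    assert np.all(np.isfinite(trace.mbicv_values))
    assert trace.selected_level == trace.levels[np.argmin(trace.mbicv_values)]
    if len(trace.mbicv_values) > trace.selected_level:
        assert (trace.mbicv_values[trace.selected_level - 1]
                <= trace.mbicv_values[trace.selected_level])
    assert model.truncation_level == trace.selected_level


def test_independence_data_yields_sparse_models():
    """On independent data, edges are pruned at rate ~1-alpha and the
    selected models carry (almost) no parametric copulas."""
    total_edges = 0
    pruned_edges = 0
    total_params = 0
    for rep in range(20):
        U = np.random.default_rng(100 + rep).uniform(size=(500, 4))
        model, _ = select_truncation_mbicv(U)
        for _, c in model.edges():
            total_edges += 1
            pruned_edges += c.family == "independence"
        total_params += model.n_copula_params()
    # NB: the MST picks the largest |tau| pairs, so the tested edges are
    # extremes of several and reject more often than the nominal alpha;
    # the model must still be overwhelmingly sparse.
    assert pruned_edges / total_edges >= 0.70
    assert total_params / 20 <= 1.0


def test_refit_pair_params_weight_neutral():
    s = RVineStructure(3, [[VineEdge(0, 1), VineEdge(1, 2)],
                           [VineEdge(0, 2, fs({1}))]])
    cops = [[B("gaussian", (0.5,)), B("clayton", (1.5,))], [B("frank", (2.0,))]]
    true = RVineModel(s, cops)
    U = rvine_sample(true, 1500, seed=31)
    # perturb parameters, then refit with and without unit weights
    pert = RVineModel(s, [[B("gaussian", (0.2,)), B("clayton", (0.8,))],
                          [B("frank", (1.0,))]])
    a = refit_pair_params(pert, U)
    b = refit_pair_params(pert, U, weights=np.ones(1500))
    for (_, ca), (_, cb) in zip(a.edges(), b.edges()):
        assert np.allclose(ca.params, cb.params, atol=1e-6)
    # and the refit should approach the generating parameters
    assert a.copulas[0][0].params[0] == pytest.approx(0.5, abs=0.07)
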