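"""Mixture model and ECM: responsibilities, CM steps, ascent, recovery."""

import math

import numpy as np
import pytest

from vinemix.bivariate import BivariateCopula as B
from vinemix.margins import MarginalModel as M, fit_margin
from vinemix.rvine import RVineModel, RVineStructure, VineEdge
from vinemix.mixture import (
    VineCopulaMixture,
    VineMixtureModel,
    cm_step_margins,
    cm_step_weights,
    complete_loglik,
    e_step,
    fit_tvcmm,
    mixture_logdensity,
    observed_loglik,
    _weighted_component_obj,
)
from vinemix.synthetic import ScenarioSpec, simulate_mixture
from vinemix.evaluation import misclassification_rate

fs = frozenset


def independence_vine(n):
    s = RVineStructure.dvine(list(range(n)))
    cops = [[B("independence")] * (n - 1 - t) for t in range(n - 1)]
    return RVineModel(s, cops)


def two_component_normal_model(mu=(0.0, 3.0), sd=(1.0, 1.0), w=(0.4, 0.6)):
    """1-dimensional two-component normal mixture as a degenerate vine mixture."""
    margins = [[M("normal", (mu[0], sd[0]))], [M("normal", (mu[1], sd[1]))]]
    vines = [RVineModel(RVineStructure(1, []), []) for _ in range(2)]
    return VineMixtureModel(np.array(w), margins, vines)


@pytest.fixture
def toy_2d_model():
    margins = [[M("normal", (0.0, 1.0)), M("normal", (0.0, 2.0))],
               [M("normal", (4.0, 1.0)), M("gamma", (2.0, 1.0))]]
    vines = [independence_vine(2), independence_vine(2)]
    return VineMixtureModel(np.array([0.3, 0.7]), margins, vines)


def test_identical_components_give_prior_responsibilities():
    margins = [[M("normal", (0.0, 1.0))], [M("normal", (0.0, 1.0))]]
    vines = [RVineModel(RVineStructure(1, []), []) for _ in range(2)]
    m = VineMixtureModel(np.array([0.3, 0.7]), margins, vines)
    X = np.random.default_rng(0).normal(size=(50, 1))
    r = e_step(m, X)
    assert np.allclose(r, [0.3, 0.7])
    assert np.allclose(mixture_logdensity(m, X),
                       m.component_logdensity(X, 0))


def test_e_step_matches_bayes_posterior_hand_computed():
    m = two_component_normal_model()
    x = np.array([[1.0]])
    from scipy.stats import norm

    num = np.array([0.4 * norm.pdf(1.0, 0.0, 1.0), 0.6 * norm.pdf(1.0, 3.0, 1.0)])
    expected = num / num.sum()
    assert np.allclose(e_step(m, x)[0], expected, atol=1e-12)


def test_single_component_responsibilities_are_one():
    margins = [[M("normal", (0.0, 1.0)), M("logistic", (0.0, 1.0))]]
    m = VineMixtureModel(np.array([1.0]), margins, [independence_vine(2)])
    X = np.random.default_rng(1).normal(size=(20, 2))
    assert np.allclose(e_step(m, X), 1.0)
    assert observed_loglik(m, X) == pytest.approx(
        float(np.sum(m.component_logdensity(X, 0))))


def test_cm_step_weights_examples():
    r = np.array([[1.0, 0.0]] * 5 + [[0.0, 1.0]] * 5)
    assert np.allclose(cm_step_weights(r), [0.5, 0.5])
    r = np.tile([0.2, 0.8], (30, 1))
    assert np.allclose(cm_step_weights(r), [0.2, 0.8])
    rng = np.random.default_rng(2)
    r = rng.dirichlet([1, 1, 1], size=100)
    assert np.allclose(cm_step_weights(r), r.mean(axis=0), atol=1e-15)


def test_mixture_density_independence_vines_direct_arithmetic(toy_2d_model):
    X = np.array([[0.5, 1.0], [3.5, 2.0]])
    m = toy_2d_model
    direct = np.log(
        0.3 * np.exp(m.margins[0][0].logpdf(X[:, 0]) + m.margins[0][1].logpdf(X[:, 1]))
        + 0.7 * np.exp(m.margins[1][0].logpdf(X[:, 0]) + m.margins[1][1].logpdf(X[:, 1])))
    assert np.allclose(mixture_logdensity(m, X), direct, atol=1e-12)


def test_complete_loglik_toy_arithmetic(toy_2d_model):
    X = np.array([[0.5, 1.0], [3.5, 2.0]])
    z = np.array([0, 1])
    m = toy_2d_model
    expected = (math.log(0.3) + float(m.component_logdensity(X[:1], 0)[0])
                + math.log(0.7) + float(m.component_logdensity(X[1:], 1)[0]))
    assert complete_loglik(m, X, z) == pytest.approx(expected, abs=1e-10)


def test_observed_loglik_doubles_with_duplicated_rows(toy_2d_model):
    X = np.array([[0.5, 1.0], [3.5, 2.0]])
    assert observed_loglik(toy_2d_model, np.vstack([X, X])) == pytest.approx(
        2 * observed_loglik(toy_2d_model, X))


def test_cm_step_margins_matches_weighted_mle_for_independence_vine(rng):
    X = np.column_stack([rng.normal(1.0, 0.5, 400), rng.normal(-2.0, 1.5, 400)])
    w = rng.uniform(0.2, 1.0, size=400)
    # start from deliberately wrong margins
    margins = [[M("normal", (0.0, 1.0)), M("normal", (0.0, 1.0))]]
    model = VineMixtureModel(np.array([1.0]), margins, [independence_vine(2)])
    r = w[:, None]
    updated = cm_step_margins(X, r, model)
    for j in range(2):
        mle = fit_margin(X[:, j], weights=w, family_set=["normal"])
        got = updated.margins[0][j]
        obj_mle = np.sum(w * mle.logpdf(X[:, j]))
        obj_got = np.sum(w * got.logpdf(X[:, j]))
        assert obj_got >= obj_mle - 1e-3
        assert got.params[0] == pytest.approx(mle.params[0], rel=0.02, abs=0.02)
        assert got.params[1] == pytest.approx(mle.params[1], rel=0.02)


def test_cm_steps_do_not_decrease_weighted_objective(rng):
    X = np.column_stack([rng.normal(0, 1, 300), rng.normal(0, 1, 300)])
    margins = [[M("normal", (0.3, 1.2)), M("normal", (-0.2, 0.8))]]
    model = VineMixtureModel(np.array([1.0]), margins, [independence_vine(2)])
    w = np.ones((300, 1))
    before = _weighted_component_obj(X, w[:, 0], model.margins[0], model.vines[0])
    after_model = cm_step_margins(X, w, model)
    after = _weighted_component_obj(X, w[:, 0], after_model.margins[0],
                                    after_model.vines[0])
    assert after >= before - 1e-8


def small_mixture_spec():
    """Well-separated 2-component 3-dim mixture with light dependence."""
    s = RVineStructure.dvine([0, 1, 2])
    v1 = RVineModel(s, [[B("gaussian", (0.6,)), B("clayton", (1.5,))],
                        [B("independence")]], truncation_level=1)
    v2 = RVineModel(s, [[B("frank", (-4.0,)), B("gumbel", (1.8,))],
                        [B("independence")]], truncation_level=1)
    m1 = [M("normal", (0.0, 1.0)), M("normal", (0.0, 1.0)), M("gamma", (2.0, 1.0))]
    m2 = [M("normal", (6.0, 1.0)), M("normal", (4.0, 1.0)), M("gamma", (2.0, 0.25))]
    return ScenarioSpec([m1, m2], [v1, v2], (150, 150))


def test_ecm_ascent_and_convergence_small():
    X, y = simulate_mixture(small_mixture_spec(), seed=5)
    est = VineCopulaMixture(n_components=2, random_state=0, truncation=1).fit(X)
    d = np.diff(est.loglik_trace_)
    assert np.all(d >= -1e-8)
    assert misclassification_rate(y, est.labels_) < 0.05


def test_label_permutation_invariance():
    m = two_component_normal_model()
    swapped = VineMixtureModel(m.weights[::-1].copy(),
                               [m.margins[1], m.margins[0]],
                               [m.vines[1], m.vines[0]])
    X = np.random.default_rng(3).normal(1.5, 2.0, size=(100, 1))
    assert np.allclose(mixture_logdensity(m, X), mixture_logdensity(swapped, X))
    r1 = np.argmax(e_step(m, X), axis=1)
    r2 = np.argmax(e_step(swapped, X), axis=1)
    assert misclassification_rate(r1, r2) == 0.0


def test_single_component_fit_reduces_to_vine_fit():
    X, _ = simulate_mixture(small_mixture_spec(), seed=6)
    est = VineCopulaMixture(n_components=1, random_state=0, truncation=1,
                            max_iter=5).fit(X)
    assert np.allclose(est.responsibilities_, 1.0)
    assert est.weights_[0] == 1.0
    assert len(est.vines_) == 1


def test_fit_tvcmm_wrapper_reports_misclassification():
    X, y = simulate_mixture(small_mixture_spec(), seed=7)
    res = fit_tvcmm(X, G=2, y_true=y, random_state=1, truncation=1, max_iter=20)
    assert res.misclassification is not None and res.misclassification < 0.05
    assert res.n_parameters == res.model.n_parameters()
    assert len(res.truncation_levels) == 2
    assert res.responsibilities.shape == (300, 2)
    assert np.allclose(res.responsibilities.sum(axis=1), 1.0, atol=1e-12)


def test_sklearn_protocol():
    est = VineCopulaMixture(n_components=2, prune_alpha=0.1)
    params = est.get_params()
    assert params["prune_alpha"] == 0.1
    est.set_params(prune_alpha=0.2)
    assert est.prune_alpha == 0.2
    X, _ = simulate_mixture(small_mixture_spec(), seed=8)
    labels = est.set_params(truncation=1, random_state=0).fit_predict(X)
    assert set(labels) == {0, 1}
    proba = est.predict_proba(X[:10])
    assert proba.shape == (10, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
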