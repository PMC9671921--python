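"""Parametric univariate margins and probability-integral transforms.

Margins are the first stage of the two-stage estimation: each variable of a
cluster gets its own parametric distribution fitted by (weighted) maximum
likelihood, and the fitted cdf maps raw data to copula data on (0,1).

Families and parameterizations:

=============  =======================  ==========================
family         parameters               scipy backend
=============  =======================  ==========================
normal         (mean, sd)               norm(loc, scale)
lognormal      (meanlog, sdlog)         lognorm(s=sdlog, scale=e^meanlog)
gamma          (shape, rate)            gamma(a=shape, scale=1/rate)
logistic       (location, scale)        logistic(loc, scale)
student_t      (df, location, scale)    t(df, loc, scale)
=============  =======================  ==========================

The gamma bracket convention (shape, rate) mirrors the way such fits are
reported in the applied literature; a (shape, scale) reading is available via
``parameterization="scale"`` on :class:`MarginalModel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["MarginalModel", "fit_margin", "pit", "inverse_pit",
           "MARGIN_FAMILIES", "DegenerateClusterError"]

MARGIN_FAMILIES = ("normal", "lognormal", "gamma", "logistic", "student_t")
POSITIVE_SUPPORT = ("lognormal", "gamma")

_EPS = 1e-10


class DegenerateClusterError(RuntimeError):
    """Raised when the effective sample behind a fit is (near) empty."""


@dataclass(frozen=True)
class MarginalModel:
    family: str
    params: tuple
    parameterization: str = "rate"  # gamma only: "rate" or "scale"

    def __post_init__(self):
        if self.family not in MARGIN_FAMILIES:
            raise ValueError(f"unknown margin family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        for p in self._scales():
            if p <= 0:
                raise ValueError(f"{self.family} scale/shape parameters must be > 0: {self.params}")

    def _scales(self):
        if self.family == "normal":
            return (self.params[1],)
        if self.family == "lognormal":
            return (self.params[1],)
        if self.family == "gamma":
            return self.params
        if self.family == "logistic":
            return (self.params[1],)
        return (self.params[0], self.params[2])  # student_t: df, scale

    # ------------------------------------------------------------------
    def _dist_args(self):
        """(scipy distribution, shape args, loc/scale kwargs) — unfrozen, since
        freezing a scipy distribution rebuilds its docstring (slow in loops)."""
        f, p = self.family, self.params
        if f == "normal":
            return stats.norm, (), {"loc": p[0], "scale": p[1]}
        if f == "lognormal":
            return stats.lognorm, (p[1],), {"scale": math.exp(p[0])}
        if f == "gamma":
            scale = p[1] if self.parameterization == "scale" else 1.0 / p[1]
            return stats.gamma, (p[0],), {"scale": scale}
        if f == "logistic":
            return stats.logistic, (), {"loc": p[0], "scale": p[1]}
        return stats.t, (p[0],), {"loc": p[1], "scale": p[2]}

    @property
    def n_params(self) -> int:
        return len(self.params)

    def logpdf(self, x):
        d, a, kw = self._dist_args()
        return d.logpdf(np.asarray(x, dtype=float), *a, **kw)

    def pdf(self, x):
        d, a, kw = self._dist_args()
        return d.pdf(np.asarray(x, dtype=float), *a, **kw)

    def cdf(self, x):
        d, a, kw = self._dist_args()
        return d.cdf(np.asarray(x, dtype=float), *a, **kw)

    def ppf(self, u):
        d, a, kw = self._dist_args()
        return d.ppf(np.asarray(u, dtype=float), *a, **kw)

    def support_contains(self, x) -> bool:
        if self.family in POSITIVE_SUPPORT:
            return bool(np.all(np.asarray(x) > 0))
        return True

    def to_dict(self) -> dict:
        return {"family": self.family, "parameters": list(self.params),
                "parameterization": self.parameterization}

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalModel":
        return cls(d["family"], tuple(d["parameters"]),
                   d.get("parameterization", "rate"))

    def __repr__(self):
        pars = ", ".join(f"{p:.4g}" for p in self.params)
        return f"{self.family}({pars})"


def pit(m: MarginalModel, x):
    """Probability integral transform H(x; phi), clipped into (0,1)."""
    x = np.asarray(x, dtype=float)
    if not m.support_contains(x):
        raise ValueError(f"data outside the support of {m.family}")
    return np.clip(m.cdf(x), _EPS, 1.0 - _EPS)


def inverse_pit(m: MarginalModel, u):
    """Quantile transform H^{-1}(u; phi)."""
    u = np.clip(np.asarray(u, dtype=float), _EPS, 1.0 - _EPS)
    return m.ppf(u)


# ----------------------------------------------------------------------
# weighted maximum-likelihood fitting
# ----------------------------------------------------------------------

def _wmean(x, w):
    return float(np.sum(w * x) / np.sum(w))


def _wsd(x, w):
    mu = _wmean(x, w)
    return float(math.sqrt(max(np.sum(w * (x - mu) ** 2) / np.sum(w), 1e-12)))


def _fit_normal(x, w):
    return MarginalModel("normal", (_wmean(x, w), _wsd(x, w)))


def _fit_lognormal(x, w):
    lx = np.log(x)
    return MarginalModel("lognormal", (_wmean(lx, w), _wsd(lx, w)))


def _numeric_fit(family, x, w, start, transform):
    """Maximize weighted loglik over unconstrained coordinates."""

    def nll(z):
        try:
            m = MarginalModel(family, transform(z))
        except ValueError:
            return 1e300  # large finite keeps Nelder-Mead quiet
        ll = m.logpdf(x)
        if not np.all(np.isfinite(ll)):
            return 1e300
        return -float(np.sum(w * ll))

    res = optimize.minimize(nll, x0=np.asarray(start), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400})
    if not np.isfinite(res.fun) or res.fun >= 1e299:
        return None
    return MarginalModel(family, transform(res.x))


def _fit_gamma(x, w):
    mu, sd = _wmean(x, w), _wsd(x, w)
    shape0 = max((mu / sd) ** 2, 1e-3)
    rate0 = max(mu / sd ** 2, 1e-6)
    return _numeric_fit("gamma", x, w,
                        (math.log(shape0), math.log(rate0)),
                        lambda z: (math.exp(z[0]), math.exp(z[1])))


def _fit_logistic(x, w):
    mu, sd = _wmean(x, w), _wsd(x, w)
    return _numeric_fit("logistic", x, w,
                        (mu, math.log(max(sd * math.sqrt(3.0) / math.pi, 1e-8))),
                        lambda z: (z[0], math.exp(z[1])))


def _fit_student_t(x, w):
    mu, sd = _wmean(x, w), _wsd(x, w)
    return _numeric_fit("student_t", x, w,
                        (math.log(8.0), mu, math.log(max(sd, 1e-8))),
                        lambda z: (min(max(math.exp(z[0]), 2.05), 200.0),
                                   z[1], math.exp(z[2])))


_FITTERS = {
    "normal": _fit_normal,
    "lognormal": _fit_lognormal,
    "gamma": _fit_gamma,
    "logistic": _fit_logistic,
    "student_t": _fit_student_t,
}


def fit_margin(x, weights=None, family_set=None, criterion="aic") -> MarginalModel:
    """Fit candidate marginal families by weighted MLE and select by AIC/BIC.

    Positive-support families are only offered when ``min(x) > 0``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("margin data must be finite")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
    if np.sum(w) < 2.0:
        raise DegenerateClusterError(
            f"effective sample size {np.sum(w):.3f} too small for a margin fit")
    if family_set is None:
        family_set = list(MARGIN_FAMILIES)
    n_eff = float(np.sum(w))

    best, best_crit = None, np.inf
    for family in family_set:
        if family in POSITIVE_SUPPORT and np.min(x) <= 0:
            continue
        m = _FITTERS[family](x, w)
        if m is None:
            continue
        ll = float(np.sum(w * m.logpdf(x)))
        if not np.isfinite(ll):
            continue
        if criterion == "aic":
            crit = -2.0 * ll + 2.0 * m.n_params
        elif criterion == "bic":
            crit = -2.0 * ll + m.n_params * math.log(n_eff)
        else:
            raise ValueError("criterion must be 'aic' or 'bic'")
        if crit < best_crit:
            best, best_crit = m, crit
    if best is None:
        raise DegenerateClusterError("no marginal family could be fitted")
    return best
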