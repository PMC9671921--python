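"""Parametric bivariate copula families.

Each copula couples two uniform margins on the open unit square.  The family
catalogue covers the elliptical pair (Gaussian, Student-t) and the one-parameter
Archimedean families (Clayton, Gumbel, Frank, Joe), plus the independence
copula.  Asymmetric families can be rotated by 90/180/270 degrees to reach all
four corners of the dependence plane.

The h-functions (conditional cdfs obtained as partial derivatives of the
copula cdf) and their inverses are the work-horses of vine densities and
inverse-Rosenblatt sampling; they are implemented in closed form wherever one
exists and by monotone root bracketing otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "BivariateCopula",
    "FAMILIES",
    "bicop_pdf",
    "bicop_hfunc",
    "bicop_hinv",
    "par_to_tau",
    "tau_to_par",
    "fit_bicop",
    "bicop_sample",
    "ParameterError",
]

EPS = 1e-10  # boundary clip for pseudo-observations

FAMILIES = (
    "independence",
    "gaussian",
    "student_t",
    "clayton",
    "gumbel",
    "frank",
    "joe",
)

# families whose dependence is sign-restricted and therefore need rotations
ROTATABLE = ("clayton", "gumbel", "joe")

# admissible parameter boxes (base, i.e. unrotated, parameterization)
_PARAM_BOUNDS = {
    "independence": [],
    "gaussian": [(-0.9999, 0.9999)],
    "student_t": [(-0.9999, 0.9999), (2.05, 30.0)],
    "clayton": [(1e-4, 28.0)],
    "gumbel": [(1.0, 17.0)],
    "frank": [(-35.0, 35.0)],
    "joe": [(1.0, 30.0)],
}


class ParameterError(ValueError):
    """Raised when copula parameters violate the family's admissible domain."""


def _clip(u):
    return np.clip(np.asarray(u, dtype=float), EPS, 1.0 - EPS)


@dataclass(frozen=True)
class BivariateCopula:
    """A parametric bivariate copula with optional rotation.

    Parameters
    ----------
    family : str
        One of ``FAMILIES``.
    params : tuple of float
        Family parameters (empty for independence; (rho,) for Gaussian;
        (rho, df) for Student-t; (theta,) for the Archimedeans).
    rotation : int
        0, 90, 180 or 270 degrees.  Rotation by 90/270 flips the sign of the
        dependence, 180 reflects it into the survival copula.
    """

    family: str
    params: tuple = ()
    rotation: int = 0

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown copula family {self.family!r}")
        if self.rotation not in (0, 90, 180, 270):
            raise ParameterError(f"rotation must be 0/90/180/270, got {self.rotation}")
        if self.family == "independence":
            if self.params or self.rotation != 0:
                raise ParameterError("independence copula takes no parameters and rotation 0")
        else:
            bounds = _PARAM_BOUNDS[self.family]
            if len(self.params) != len(bounds):
                raise ParameterError(
                    f"{self.family} expects {len(bounds)} parameter(s), got {len(self.params)}"
                )
            for p, (lo, hi) in zip(self.params, bounds):
                if not (lo <= p <= hi):
                    raise ParameterError(
                        f"{self.family} parameter {p:.6g} outside admissible [{lo}, {hi}]"
                    )
            if self.family == "frank" and abs(self.params[0]) < 1e-8:
                raise ParameterError("frank requires theta != 0 (use independence instead)")
        if self.rotation in (90, 180, 270) and self.family not in ROTATABLE:
            raise ParameterError(f"rotation only supported for {ROTATABLE}, not {self.family}")

    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.params)

    def pdf(self, u, v):
        return bicop_pdf(self, u, v)

    def logpdf(self, u, v):
        return _rotated_logpdf(self, _clip(u), _clip(v))

    def hfunc(self, u, v, cond_on="second"):
        return bicop_hfunc(self, u, v, cond_on=cond_on)

    def hinv(self, p, v, cond_on="second"):
        return bicop_hinv(self, p, v, cond_on=cond_on)

    def tau(self) -> float:
        return par_to_tau(self)

    def sample(self, n, seed=None, rng=None):
        return bicop_sample(self, n, seed=seed, rng=rng)

    def to_dict(self) -> dict:
        return {"family": self.family, "rotation": self.rotation, "parameters": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "BivariateCopula":
        return cls(family=d["family"], params=tuple(d.get("parameters", ())),
                   rotation=int(d.get("rotation", 0)))

    def __repr__(self):  # compact, e.g. clayton(2.00)@180
        pars = ", ".join(f"{p:.3g}" for p in self.params)
        rot = f"@{self.rotation}" if self.rotation else ""
        return f"{self.family}({pars}){rot}"


INDEPENDENCE = BivariateCopula("independence")


# ----------------------------------------------------------------------
# base-family (rotation 0) log densities
# ----------------------------------------------------------------------

def _gaussian_logpdf(u, v, rho):
    x = special.ndtri(u)
    y = special.ndtri(v)
    r2 = 1.0 - rho * rho
    return (-0.5 * math.log(r2)
            + (2.0 * rho * x * y - rho * rho * (x * x + y * y)) / (2.0 * r2))


def _student_logpdf(u, v, rho, df):
    x = stats.t.ppf(u, df)
    y = stats.t.ppf(v, df)
    r2 = 1.0 - rho * rho
    # log bivariate t density minus the two univariate t log densities;
    # bivariate normalizer is Gamma((df+2)/2) / (Gamma(df/2) * df * pi * sqrt(r2))
    log_biv = (special.gammaln((df + 2) / 2.0) - special.gammaln(df / 2.0)
               - math.log(df * math.pi) - 0.5 * math.log(r2)
               - (df + 2) / 2.0 * np.log1p((x * x - 2 * rho * x * y + y * y) / (df * r2)))
    log_marg = stats.t.logpdf(x, df) + stats.t.logpdf(y, df)
    return log_biv - log_marg


def _clayton_logpdf(u, v, theta):
    lu, lv = np.log(u), np.log(v)
    s = np.expm1(-theta * lu) + np.expm1(-theta * lv) + 1.0  # u^-t + v^-t - 1
    s = np.maximum(s, EPS)
    return (math.log1p(theta) - (1.0 + theta) * (lu + lv)
            - (2.0 + 1.0 / theta) * np.log(s))


def _gumbel_logcdf_terms(u, v, theta):
    lu = -np.log(u)  # > 0
    lv = -np.log(v)
    a = theta * np.log(lu)
    b = theta * np.log(lv)
    # S = lu^theta + lv^theta computed stably
    m = np.maximum(a, b)
    logS = m + np.log(np.exp(a - m) + np.exp(b - m))
    return lu, lv, logS


def _gumbel_logpdf(u, v, theta):
    lu, lv, logS = _gumbel_logcdf_terms(u, v, theta)
    A = np.exp(logS / theta)  # (lu^t + lv^t)^(1/t)
    logC = -A
    return (logC - np.log(u) - np.log(v)
            + (theta - 1.0) * (np.log(lu) + np.log(lv))
            + (1.0 / theta - 2.0) * logS
            + np.log(A + theta - 1.0))


def _frank_logpdf(u, v, theta):
    # c = theta (1-e^-t) e^{-t(u+v)} / [ (1-e^-t) - (1-e^{-tu})(1-e^{-tv}) ]^2
    et = -np.expm1(-theta)          # 1 - e^-theta
    eu = -np.expm1(-theta * u)
    ev = -np.expm1(-theta * v)
    denom = et - eu * ev
    denom = np.where(np.abs(denom) < 1e-300, np.sign(denom) * 1e-300 + 1e-300, denom)
    return (np.log(np.abs(theta)) + np.log(np.abs(et))
            - theta * (u + v) - 2.0 * np.log(np.abs(denom)))


def _joe_logpdf(u, v, theta):
    x = (1.0 - u) ** theta
    y = (1.0 - v) ** theta
    A = x + y - x * y
    A = np.maximum(A, EPS)
    return ((1.0 / theta - 2.0) * np.log(A)
            + (theta - 1.0) * (np.log1p(-u) + np.log1p(-v))
            + np.log(theta - 1.0 + A))


_BASE_LOGPDF = {
    "gaussian": lambda u, v, p: _gaussian_logpdf(u, v, p[0]),
    "student_t": lambda u, v, p: _student_logpdf(u, v, p[0], p[1]),
    "clayton": lambda u, v, p: _clayton_logpdf(u, v, p[0]),
    "gumbel": lambda u, v, p: _gumbel_logpdf(u, v, p[0]),
    "frank": lambda u, v, p: _frank_logpdf(u, v, p[0]),
    "joe": lambda u, v, p: _joe_logpdf(u, v, p[0]),
}


# ----------------------------------------------------------------------
# base-family h-functions: h2(u|v) = dC/dv.  By exchange symmetry of all
# base families, h1(v|u) = h2 with arguments swapped.
# ----------------------------------------------------------------------

def _gaussian_h(u, v, rho):
    x = special.ndtri(u)
    y = special.ndtri(v)
    return special.ndtr((x - rho * y) / math.sqrt(1.0 - rho * rho))


def _gaussian_hinv(p, v, rho):
    y = special.ndtri(v)
    z = special.ndtri(p)
    return special.ndtr(z * math.sqrt(1.0 - rho * rho) + rho * y)


def _student_h(u, v, rho, df):
    x = stats.t.ppf(u, df)
    y = stats.t.ppf(v, df)
    scale = np.sqrt((df + y * y) * (1.0 - rho * rho) / (df + 1.0))
    return stats.t.cdf((x - rho * y) / scale, df + 1.0)


def _student_hinv(p, v, rho, df):
    y = stats.t.ppf(v, df)
    scale = np.sqrt((df + y * y) * (1.0 - rho * rho) / (df + 1.0))
    x = stats.t.ppf(p, df + 1.0) * scale + rho * y
    return stats.t.cdf(x, df)


def _clayton_h(u, v, theta):
    s = u ** (-theta) + v ** (-theta) - 1.0
    s = np.maximum(s, EPS)
    return v ** (-theta - 1.0) * s ** (-1.0 - 1.0 / theta)


def _clayton_hinv(p, v, theta):
    t1 = (p * v ** (theta + 1.0)) ** (-theta / (theta + 1.0))
    s = t1 + 1.0 - v ** (-theta)
    s = np.maximum(s, EPS)
    return s ** (-1.0 / theta)


def _gumbel_h(u, v, theta):
    lu, lv, logS = _gumbel_logcdf_terms(u, v, theta)
    A = np.exp(logS / theta)
    logh = -A - np.log(v) + (theta - 1.0) * np.log(lv) + (1.0 / theta - 1.0) * logS
    return np.exp(logh)


def _frank_h(u, v, theta):
    eu = np.expm1(-theta * u)     # e^{-tu} - 1
    ev = np.expm1(-theta * v)
    e1 = np.expm1(-theta)
    return np.exp(-theta * v) * eu / (e1 + eu * ev)


def _frank_hinv(p, v, theta):
    # solve p = e^{-tv} w / (e1 + w (e^{-tv}-1)) for w = e^{-tu}-1
    e1 = np.expm1(-theta)
    ev = np.exp(-theta * v)
    evm = np.expm1(-theta * v)
    w = p * e1 / (ev - p * evm)
    return -np.log1p(w) / theta


def _joe_h(u, v, theta):
    x = (1.0 - u) ** theta
    y = (1.0 - v) ** theta
    A = np.maximum(x + y - x * y, EPS)
    return A ** (1.0 / theta - 1.0) * (1.0 - v) ** (theta - 1.0) * (1.0 - x)


_BASE_H = {
    "gaussian": lambda u, v, p: _gaussian_h(u, v, p[0]),
    "student_t": lambda u, v, p: _student_h(u, v, p[0], p[1]),
    "clayton": lambda u, v, p: _clayton_h(u, v, p[0]),
    "gumbel": lambda u, v, p: _gumbel_h(u, v, p[0]),
    "frank": lambda u, v, p: _frank_h(u, v, p[0]),
    "joe": lambda u, v, p: _joe_h(u, v, p[0]),
}

_BASE_HINV = {
    "gaussian": lambda p, v, par: _gaussian_hinv(p, v, par[0]),
    "student_t": lambda p, v, par: _student_hinv(p, v, par[0], par[1]),
    "clayton": lambda p, v, par: _clayton_hinv(p, v, par[0]),
    "frank": lambda p, v, par: _frank_hinv(p, v, par[0]),
}


def _numeric_hinv(family, params, p, v):
    """Monotone bisection solve of h(u|v) = p; h is increasing in u."""
    h = _BASE_H[family]
    p = np.atleast_1d(np.asarray(p, dtype=float))
    v = np.broadcast_to(np.atleast_1d(np.asarray(v, dtype=float)), p.shape).copy()
    lo = np.full_like(p, EPS)
    hi = np.full_like(p, 1.0 - EPS)
    for _ in range(60):  # 2^-60 << 1e-8 tolerance
        mid = 0.5 * (lo + hi)
        too_low = h(mid, v, params) < p
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


# ----------------------------------------------------------------------
# rotation plumbing.  With base cdf C(u,v):
#   C_90(u,v)  = v - C(1-u, v)
#   C_180(u,v) = u + v - 1 + C(1-u, 1-v)
#   C_270(u,v) = u - C(u, 1-v)
# ----------------------------------------------------------------------

def _rotated_logpdf(cop, u, v):
    if cop.family == "independence":
        return np.zeros(np.broadcast(u, v).shape)
    f = _BASE_LOGPDF[cop.family]
    r = cop.rotation
    if r == 0:
        return f(u, v, cop.params)
    if r == 90:
        return f(1.0 - u, v, cop.params)
    if r == 180:
        return f(1.0 - u, 1.0 - v, cop.params)
    return f(u, 1.0 - v, cop.params)  # 270


def _rotated_h2(cop, u, v):
    """h(u|v) = dC_rot/dv."""
    if cop.family == "independence":
        return u * np.ones(np.broadcast(u, v).shape)
    h = _BASE_H[cop.family]
    r = cop.rotation
    if r == 0:
        return h(u, v, cop.params)
    if r == 90:
        return 1.0 - h(1.0 - u, v, cop.params)
    if r == 180:
        return 1.0 - h(1.0 - u, 1.0 - v, cop.params)
    return h(u, 1.0 - v, cop.params)  # 270


def _rotated_h2inv(cop, p, v):
    if cop.family == "independence":
        return p * np.ones(np.broadcast(p, v).shape)

    def base_inv(pp, vv):
        if cop.family in _BASE_HINV:
            return _BASE_HINV[cop.family](pp, vv, cop.params)
        return _numeric_hinv(cop.family, cop.params, pp, vv)

    r = cop.rotation
    if r == 0:
        return base_inv(p, v)
    if r == 90:
        return 1.0 - base_inv(1.0 - p, v)
    if r == 180:
        return 1.0 - base_inv(1.0 - p, 1.0 - v)
    return base_inv(p, 1.0 - v)  # 270


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def bicop_pdf(cop: BivariateCopula, u, v):
    """Copula density c(u, v), vectorized; inputs are clipped away from {0,1}."""
    out = np.exp(_rotated_logpdf(cop, _clip(u), _clip(v)))
    if np.isscalar(u) and np.isscalar(v):
        return float(np.asarray(out).ravel()[0])
    return out


def bicop_hfunc(cop: BivariateCopula, u, v, cond_on="second"):
    """Conditional cdf from the copula.

    ``cond_on='second'`` returns h(u|v) = dC(u,v)/dv; ``cond_on='first'``
    returns h(v|u) = dC(u,v)/du.  All implemented base families are
    exchangeable, so conditioning on the first argument is evaluated by
    swapping arguments of the appropriately re-rotated copula.
    """
    uc, vc = _clip(u), _clip(v)
    if cond_on == "second":
        out = _rotated_h2(cop, uc, vc)
    elif cond_on == "first":
        out = _rotated_h2(_transpose(cop), vc, uc)
    else:
        raise ValueError("cond_on must be 'first' or 'second'")
    out = np.clip(out, EPS, 1.0 - EPS)
    if np.isscalar(u) and np.isscalar(v):
        return float(np.asarray(out).ravel()[0])
    return out


def _transpose(cop: BivariateCopula) -> BivariateCopula:
    """Copula of (V, U): for exchangeable base families only the 90/270
    rotations swap."""
    if cop.rotation == 90:
        return BivariateCopula(cop.family, cop.params, 270)
    if cop.rotation == 270:
        return BivariateCopula(cop.family, cop.params, 90)
    return cop


def bicop_hinv(cop: BivariateCopula, p, v, cond_on="second"):
    """Inverse of :func:`bicop_hfunc` in its non-conditioning argument.

    ``v`` is always the conditioning value.  For ``cond_on='second'`` the
    result u solves h(u|v) = bicop_hfunc(cop, u, v, 'second') = p; for
    ``cond_on='first'`` it solves bicop_hfunc(cop, v, u, 'first') = p (the
    conditioning value occupies the first slot of the h-function).
    """
    pc, vc = _clip(p), _clip(v)
    if cond_on == "second":
        out = _rotated_h2inv(cop, pc, vc)
    elif cond_on == "first":
        out = _rotated_h2inv(_transpose(cop), pc, vc)
    else:
        raise ValueError("cond_on must be 'first' or 'second'")
    out = np.clip(out, EPS, 1.0 - EPS)
    if np.isscalar(p) and np.isscalar(v):
        return float(np.asarray(out).ravel()[0])
    return out


# ----------------------------------------------------------------------
# Kendall's tau <-> parameter maps
# ----------------------------------------------------------------------

def _frank_tau(theta):
    if abs(theta) < 1e-8:
        return 0.0
    # tau = 1 - 4/theta * (1 - D1(theta)), D1 the first Debye function
    d1 = integrate.quad(lambda t: t / math.expm1(t), 0.0, abs(theta), limit=200)[0] / abs(theta)
    tau = 1.0 - 4.0 / abs(theta) * (1.0 - d1)
    return math.copysign(tau, theta)


def _joe_tau(theta):
    if theta <= 1.0 + 1e-12:
        return 0.0
    # series form: tau = 1 - 4 * sum_{k>=1} 1 / (k (theta k + 2) (theta (k-1) + 2))
    k = np.arange(1.0, 20001.0)
    return float(1.0 - 4.0 * np.sum(1.0 / (k * (theta * k + 2.0) * (theta * (k - 1.0) + 2.0))))


def par_to_tau(cop: BivariateCopula) -> float:
    """Population Kendall's tau implied by the copula parameters."""
    fam = cop.family
    if fam == "independence":
        return 0.0
    if fam in ("gaussian", "student_t"):
        tau = 2.0 / math.pi * math.asin(cop.params[0])
    elif fam == "clayton":
        tau = cop.params[0] / (cop.params[0] + 2.0)
    elif fam == "gumbel":
        tau = 1.0 - 1.0 / cop.params[0]
    elif fam == "frank":
        tau = _frank_tau(cop.params[0])
    elif fam == "joe":
        tau = _joe_tau(cop.params[0])
    else:  # pragma: no cover
        raise ParameterError(fam)
    if cop.rotation in (90, 270):
        tau = -tau
    return float(tau)


def tau_to_par(family: str, tau: float, rotation: int = 0):
    """Invert the tau map of a one-parameter family (Gaussian/Student rho).

    The tau is interpreted on the *rotated* copula scale: for 90/270 rotations
    the base parameter is obtained from -tau.
    """
    if family == "independence":
        return ()
    t = -tau if rotation in (90, 270) else tau
    if family in ("gaussian", "student_t"):
        rho = math.sin(math.pi * t / 2.0)
        return (float(np.clip(rho, -0.9999, 0.9999)),)
    if family == "clayton":
        if t <= 0:
            raise ParameterError(
                f"clayton (rotation {rotation}) cannot reach tau={tau:.3f}; try a 90/270 rotation")
        theta = 2.0 * t / (1.0 - t)
        return (float(np.clip(theta, 1e-4, 28.0)),)
    if family == "gumbel":
        if t < 0:
            raise ParameterError(
                f"gumbel (rotation {rotation}) cannot reach tau={tau:.3f}; try a 90/270 rotation")
        theta = 1.0 / max(1.0 - t, 1e-6)
        return (float(np.clip(theta, 1.0, 17.0)),)
    if family == "frank":
        if abs(t) < 1e-6:
            return (1e-4,)
        theta = optimize.brentq(lambda th: _frank_tau(th) - t, -35.0, 35.0, xtol=1e-10)
        return (float(theta),)
    if family == "joe":
        if t < 0:
            raise ParameterError(
                f"joe (rotation {rotation}) cannot reach tau={tau:.3f}; try a 90/270 rotation")
        if t < 1e-6:
            return (1.0,)
        hi = 30.0
        if _joe_tau(hi) < t:
            return (hi,)
        theta = optimize.brentq(lambda th: _joe_tau(th) - t, 1.0 + 1e-9, hi, xtol=1e-10)
        return (float(theta),)
    raise ParameterError(f"unknown family {family!r}")


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _weighted_negloglik(family, rotation, params, u, v, w):
    try:
        cop = BivariateCopula(family, tuple(params), rotation)
    except ParameterError:
        return np.inf
    ll = _rotated_logpdf(cop, u, v)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(np.sum(w * ll))


def _candidate_rotations(family, tau_hat):
    if family not in ROTATABLE:
        return (0,)
    return (0, 180) if tau_hat >= 0 else (90, 270)


def _fit_one_family(family, rotation, u, v, w, tau_hat):
    """Weighted MLE for one (family, rotation); returns (copula, loglik)."""
    try:
        start = tau_to_par(family, tau_hat, rotation)
    except ParameterError:
        return None
    bounds = _PARAM_BOUNDS[family]
    if family == "student_t":
        start = (start[0], 6.0)

    def nll(p):
        return _weighted_negloglik(family, rotation, p, u, v, w)

    if len(bounds) == 1:
        res = optimize.minimize_scalar(
            lambda th: nll([th]), bounds=bounds[0], method="bounded",
            options={"xatol": 1e-6})
        params = (float(res.x),)
        best = res.fun
    else:
        res = optimize.minimize(
            nll, x0=np.array(start), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 40, "ftol": 1e-9})
        params = tuple(float(x) for x in res.x)
        best = res.fun
    if not np.isfinite(best):
        return None
    try:
        cop = BivariateCopula(family, params, rotation)
    except ParameterError:
        return None
    return cop, -best


def fit_bicop(u, v, weights=None, family_set=None, criterion="aic",
              tau_hat=None) -> BivariateCopula:
    """Select and fit a pair-copula by weighted maximum likelihood.

    Every candidate family (with sign-appropriate rotations for the
    asymmetric families) is fitted from a Kendall-tau inversion start; the
    model minimizing the information criterion (AIC by default) is returned.
    Falls back to independence with a warning if every parametric fit fails.
    """
    u = _clip(u)
    v = _clip(v)
    if weights is None:
        w = np.ones_like(u)
    else:
        w = np.asarray(weights, dtype=float)
        if np.sum(w) <= 0:
            raise ValueError("weights must have positive sum")
    if family_set is None:
        family_set = list(FAMILIES)
    if tau_hat is None:
        tau_hat = _weighted_tau(u, v, None if weights is None else w)

    n_eff = float(np.sum(w))
    best_cop, best_crit, best_ll = None, np.inf, None
    for family in family_set:
        if family == "independence":
            cand = (INDEPENDENCE, 0.0)
        else:
            cand = None
            for rot in _candidate_rotations(family, tau_hat):
                fit = _fit_one_family(family, rot, u, v, w, tau_hat)
                if fit is not None and (cand is None or fit[1] > cand[1]):
                    cand = fit
            if cand is None:
                continue
        cop, ll = cand
        if criterion == "aic":
            crit = -2.0 * ll + 2.0 * cop.n_params
        elif criterion == "bic":
            crit = -2.0 * ll + cop.n_params * math.log(max(n_eff, 2.0))
        else:
            raise ValueError("criterion must be 'aic' or 'bic'")
        if crit < best_crit:
            best_cop, best_crit, best_ll = cop, crit, ll
    if best_cop is None:
        warnings.warn("all pair-copula fits failed; falling back to independence")
        return INDEPENDENCE
    return best_cop


def _weighted_tau(u, v, w=None):
    """Kendall's tau; weighted version uses pairwise products of weights."""
    from scipy.stats import kendalltau

    if w is None or np.allclose(w, w[0]):
        return float(kendalltau(u, v).statistic)
    du = np.sign(u[:, None] - u[None, :])
    dv = np.sign(v[:, None] - v[None, :])
    ww = w[:, None] * w[None, :]
    num = float(np.sum(ww * du * dv))
    den = float(np.sum(ww * np.abs(du) * np.abs(dv)))
    return num / den if den > 0 else 0.0


# ----------------------------------------------------------------------
# sampling
# ----------------------------------------------------------------------

def bicop_sample(cop: BivariateCopula, n: int, seed=None, rng=None):
    """Draw n pairs by the conditional-inversion method.

    v ~ U(0,1), p ~ U(0,1), u = h^{-1}(p | v).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    v = rng.uniform(size=n)
    p = rng.uniform(size=n)
    u = bicop_hinv(cop, p, v, cond_on="second")
    return np.column_stack([u, v])
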