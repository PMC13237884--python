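"""Closed-form parametric survival distributions and economic uncertainty distributions.

Six time-to-event families are supported, in the parameterizations used by
``flexsurv``-style survival extrapolation:

``exponential``
    constant hazard ``rate``; S(t) = exp(-rate*t).
``weibull``
    ``scale`` (lambda) and ``shape`` (k); S(t) = exp(-(t/lambda)**k).
``gompertz``
    ``shape`` (eta, any real) and ``rate`` (b > 0); h(t) = b*exp(eta*t).
    Note: published parameter tables sometimes label b "scale"; it is the
    rate-like parameter of the hazard, not a time scale.
``loglogistic``
    ``scale`` (alpha) and ``shape`` (beta); S(t) = 1/(1 + (t/alpha)**beta).
``lognormal``
    ``mu`` (location of log-time) and ``sigma``; S(t) = 1 - Phi((ln t - mu)/sigma).
``gengamma``
    generalized gamma in the location/scale/shape (mu, sigma, Q) form
    (Prentice); Q -> 0 recovers the lognormal, Q = 1 the Weibull.

All distributions carry an explicit ``time_unit`` (months by default) so that
parameter vectors are never interpreted in an implicit unit.

The module also provides the beta-PERT three-point distribution and
moment-matched gamma/beta samplers used for probabilistic sensitivity
analysis of costs, utilities and probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats

__all__ = [
    "ParametricSurvival",
    "PertSpec",
    "UncertainParam",
    "pert_from_three_points",
    "psa_dist_from_range",
    "FAMILY_PARAMS",
    "TIME_UNIT_DAYS",
]

TIME_UNIT_DAYS = {
    "days": 1.0,
    "weeks": 7.0,
    "cycles": 21.0,
    "months": 365.25 / 12.0,
    "years": 365.25,
}

#: parameter names per family, in the order expected in ``params``
FAMILY_PARAMS = {
    "exponential": ("rate",),
    "weibull": ("scale", "shape"),
    "gompertz": ("shape", "rate"),
    "loglogistic": ("scale", "shape"),
    "lognormal": ("mu", "sigma"),
    "gengamma": ("mu", "sigma", "Q"),
}

# positions of parameters constrained strictly positive
_POSITIVE = {
    "exponential": (0,),
    "weibull": (0, 1),
    "gompertz": (1,),
    "loglogistic": (0, 1),
    "lognormal": (1,),
    "gengamma": (1,),
}

_GG_LOGNORMAL_SWITCH = 1e-5  # |Q| below which gengamma falls back to lognormal


def _as_nonneg_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    return t


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival distribution: family tag + ordered parameter vector."""

    family: str
    params: tuple
    time_unit: str = "months"

    def __post_init__(self):
        if self.family not in FAMILY_PARAMS:
            raise ValueError(f"unknown survival family {self.family!r}")
        if self.time_unit not in TIME_UNIT_DAYS:
            raise ValueError(f"unknown time unit {self.time_unit!r}")
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        names = FAMILY_PARAMS[self.family]
        if len(params) != len(names):
            raise ValueError(
                f"{self.family} expects {len(names)} parameters {names}, got {len(params)}"
            )
        if not all(math.isfinite(p) for p in params):
            raise ValueError("parameters must be finite")
        for i in _POSITIVE[self.family]:
            if params[i] <= 0:
                raise ValueError(
                    f"{self.family} parameter {names[i]!r} must be > 0, got {params[i]}"
                )

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_named(cls, family, time_unit="months", **named):
        """Build from named parameters, e.g. ``from_named('weibull', scale=21.5, shape=1.0)``."""
        names = FAMILY_PARAMS.get(family)
        if names is None:
            raise ValueError(f"unknown survival family {family!r}")
        missing = set(names) - set(named)
        extra = set(named) - set(names)
        if missing or extra:
            raise ValueError(
                f"{family} takes parameters {names}; missing={sorted(missing)}, unknown={sorted(extra)}"
            )
        return cls(family, tuple(named[n] for n in names), time_unit)

    @property
    def param_dict(self):
        return dict(zip(FAMILY_PARAMS[self.family], self.params))

    def to_unit(self, unit):
        """Return an equivalent distribution expressed in another time unit."""
        if unit == self.time_unit:
            return self
        # factor converts new-unit times into current-unit times
        c = TIME_UNIT_DAYS[unit] / TIME_UNIT_DAYS[self.time_unit]
        p = self.param_dict
        f = self.family
        if f == "exponential":
            new = (p["rate"] * c,)
        elif f == "weibull":
            new = (p["scale"] / c, p["shape"])
        elif f == "gompertz":
            new = (p["shape"] * c, p["rate"] * c)
        elif f == "loglogistic":
            new = (p["scale"] / c, p["shape"])
        elif f == "lognormal":
            new = (p["mu"] - math.log(c), p["sigma"])
        else:  # gengamma
            new = (p["mu"] - math.log(c), p["sigma"], p["Q"])
        return replace(self, params=new, time_unit=unit)

    # -- core mathematics ------------------------------------------------------

    def cumhaz(self, t):
        """Cumulative hazard H(t) = -ln S(t), vectorized, exact closed forms."""
        t = _as_nonneg_times(t)
        p = self.params
        f = self.family
        if f == "exponential":
            return p[0] * t
        if f == "weibull":
            lam, k = p
            return (t / lam) ** k
        if f == "gompertz":
            eta, b = p
            x = eta * t
            # expm1 is numerically exact for all eta, including eta ~ 0
            with np.errstate(over="ignore"):
                out = np.where(
                    np.abs(x) < 1e-12, b * t, b * np.expm1(x) / np.where(eta == 0.0, 1.0, eta)
                )
            if eta == 0.0:
                out = b * t
            return out
        if f == "loglogistic":
            alpha, beta = p
            return np.log1p((t / alpha) ** beta)
        if f == "lognormal":
            mu, sigma = p
            with np.errstate(divide="ignore"):
                z = (np.log(t) - mu) / sigma
            return -stats.norm.logsf(z)
        # gengamma
        s = self._gg_survival(t)
        with np.errstate(divide="ignore"):
            return -np.log(s)

    def survival(self, t):
        """S(t) in [0, 1]; S(0) = 1 exactly."""
        t = _as_nonneg_times(t)
        if self.family == "gengamma":
            return self._gg_survival(t)
        return np.exp(-self.cumhaz(t))

    def _gg_survival(self, t):
        mu, sigma, Q = self.params
        if abs(Q) < _GG_LOGNORMAL_SWITCH:
            with np.errstate(divide="ignore"):
                z = (np.log(t) - mu) / sigma
            return stats.norm.sf(z)
        gam = Q ** -2
        with np.errstate(divide="ignore"):
            w = (np.log(t) - mu) / sigma
        u = gam * np.exp(Q * w)
        u = np.where(np.isnan(u), 0.0, u)  # t=0, Q>0 -> w=-inf -> u=0
        if Q > 0:
            s = special.gammaincc(gam, u)
        else:
            # t=0 -> w=-inf -> u=+inf -> S=1
            u = np.where(np.isinf(u), np.inf, u)
            s = special.gammainc(gam, u)
        return np.where(t == 0.0, 1.0, s) if np.ndim(t) else (1.0 if t == 0 else float(s))

    def logpdf(self, t):
        """log f(t); -inf where the density is zero."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("logpdf requires strictly positive times")
        p = self.params
        f = self.family
        if f == "exponential":
            return np.log(p[0]) - p[0] * t
        if f == "weibull":
            lam, k = p
            z = t / lam
            return math.log(k / lam) + (k - 1) * np.log(z) - z**k
        if f == "gompertz":
            eta, b = p
            return np.log(b) + eta * t - self.cumhaz(t)
        if f == "loglogistic":
            alpha, beta = p
            z = (t / alpha) ** beta
            return math.log(beta / alpha) + (beta - 1) * np.log(t / alpha) - 2 * np.log1p(z)
        if f == "lognormal":
            mu, sigma = p
            z = (np.log(t) - mu) / sigma
            return -np.log(t * sigma) + stats.norm.logpdf(z)
        mu, sigma, Q = p
        if abs(Q) < _GG_LOGNORMAL_SWITCH:
            z = (np.log(t) - mu) / sigma
            return -np.log(t * sigma) + stats.norm.logpdf(z)
        gam = Q ** -2
        w = (np.log(t) - mu) / sigma
        u = gam * np.exp(Q * w)
        return (
            math.log(abs(Q))
            - np.log(sigma * t)
            - special.gammaln(gam)
            + gam * np.log(u)
            - u
        )

    def hazard(self, t):
        """Instantaneous hazard h(t) = f(t)/S(t).

        Where S(t) underflows to zero the hazard is reported as ``inf``
        (a documented positive-infinity sentinel), never NaN.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("hazard requires non-negative times")
        p = self.params
        f = self.family
        if f == "exponential":
            return np.full_like(t, p[0], dtype=float)
        if f == "gompertz":
            eta, b = p
            return b * np.exp(eta * t)
        if f == "weibull":
            lam, k = p
            with np.errstate(divide="ignore"):
                return (k / lam) * (t / lam) ** (k - 1)
        if f == "loglogistic":
            alpha, beta = p
            with np.errstate(divide="ignore"):
                z = (t / alpha) ** beta
                return (beta / t) * z / (1 + z)
        # lognormal / gengamma: f/S with an inf sentinel where S == 0
        tpos = np.where(t > 0, t, np.nan)
        s = self.survival(np.where(t > 0, t, 0.0))
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            h = np.exp(self.logpdf(np.where(t > 0, tpos, 1.0))) / s
        h = np.where(t == 0.0, self._hazard_at_zero(), h)
        return np.where(np.isnan(h) & (s <= 0), np.inf, h)

    def _hazard_at_zero(self):
        # limit of f/S as t -> 0+ for the log-location families
        return 0.0

    def quantile(self, p):
        """Time t with F(t) = p, i.e. S(t) = 1 - p, for p in (0, 1)."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("quantile requires p strictly inside (0, 1)")
        par = self.params
        f = self.family
        z = -np.log1p(-p)  # -ln(1-p), the target cumulative hazard
        if f == "exponential":
            return z / par[0]
        if f == "weibull":
            lam, k = par
            return lam * z ** (1.0 / k)
        if f == "gompertz":
            eta, b = par
            if eta == 0.0:
                return z / b
            arg = 1.0 + eta * z / b
            with np.errstate(invalid="ignore", divide="ignore"):
                q = np.where(arg > 0, np.log(np.maximum(arg, np.finfo(float).tiny)) / eta, np.inf)
            return q
        if f == "loglogistic":
            alpha, beta = par
            return alpha * (p / (1 - p)) ** (1.0 / beta)
        if f == "lognormal":
            mu, sigma = par
            return np.exp(mu + sigma * stats.norm.ppf(p))
        mu, sigma, Q = par
        if abs(Q) < _GG_LOGNORMAL_SWITCH:
            return np.exp(mu + sigma * stats.norm.ppf(p))
        gam = Q ** -2
        u = special.gammaincinv(gam, p if Q > 0 else 1 - p)
        w = np.log(u / gam) / Q
        return np.exp(mu + sigma * w)

    def sample(self, n, seed=None, rng=None):
        """Inverse-transform draws; reproducible given ``seed`` (or a Generator)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        u = rng.uniform(np.finfo(float).tiny, 1.0, size=int(n))
        return self.quantile(u)

    def mean(self, upper=None):
        """E[T], or the restricted mean ∫_0^upper S(t) dt when ``upper`` is given."""
        from scipy.integrate import quad

        hi = np.inf if upper is None else float(upper)
        val, _ = quad(lambda t: float(self.survival(t)), 0.0, hi, limit=200)
        return val

    # -- serialization ---------------------------------------------------------

    def to_config(self):
        return {
            "family": self.family,
            "params": self.param_dict,
            "time_unit": self.time_unit,
        }

    @classmethod
    def from_config(cls, cfg):
        return cls.from_named(
            cfg["family"], time_unit=cfg.get("time_unit", "months"), **cfg["params"]
        )


# ---------------------------------------------------------------------------
# beta-PERT three-point distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PertSpec:
    """Beta-PERT distribution on [min, max] from a (min, mode, max) triple.

    Standard PERT shape parameters: alpha = 1 + 4(mode-min)/(max-min),
    beta = 1 + 4(max-mode)/(max-min), giving mean (min + 4*mode + max)/6.
    A degenerate triple (min == max) is a point mass, not an error.
    """

    min: float
    mode: float
    max: float

    def __post_init__(self):
        if not (self.min <= self.mode <= self.max):
            raise ValueError(
                f"PERT triple must satisfy min <= mode <= max, got "
                f"({self.min}, {self.mode}, {self.max})"
            )

    @property
    def degenerate(self):
        return self.max == self.min

    @property
    def alpha(self):
        if self.degenerate:
            return math.nan
        return 1.0 + 4.0 * (self.mode - self.min) / (self.max - self.min)

    @property
    def beta(self):
        if self.degenerate:
            return math.nan
        return 1.0 + 4.0 * (self.max - self.mode) / (self.max - self.min)

    @property
    def mean(self):
        return (self.min + 4.0 * self.mode + self.max) / 6.0

    @property
    def var(self):
        if self.degenerate:
            return 0.0
        a, b = self.alpha, self.beta
        return (self.max - self.min) ** 2 * a * b / ((a + b) ** 2 * (a + b + 1))

    def rvs(self, rng, size=None):
        if self.degenerate:
            return np.full(size if size is not None else (), self.mode)
        return self.min + (self.max - self.min) * rng.beta(self.alpha, self.beta, size=size)


def pert_from_three_points(minimum, mode, maximum):
    """Parameterize a beta-PERT distribution from a three-point estimate."""
    return PertSpec(float(minimum), float(mode), float(maximum))


# ---------------------------------------------------------------------------
# PSA samplers for uncertain economic parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UncertainParam:
    """One uncertain model input with its base value, plausible range and PSA family.

    ``family`` is one of gamma / beta / beta_pert / fixed; ``role`` records the
    economic meaning (cost, utility, probability, disutility).  Disutilities are
    stated as negative numbers; sampling happens on the magnitude scale and the
    sign is restored afterwards.
    """

    name: str
    base: float
    lo: float
    hi: float
    family: str = "fixed"
    role: str = "cost"
    source: str = ""

    def __post_init__(self):
        if self.family not in ("gamma", "beta", "beta_pert", "fixed"):
            raise ValueError(f"{self.name}: unknown PSA family {self.family!r}")
        if self.role not in ("cost", "utility", "probability", "disutility"):
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        if self.role == "disutility":
            # stored as negatives; magnitude ordering checked below
            if not (abs(self.lo) <= abs(self.base) <= abs(self.hi)) and not (
                abs(self.hi) <= abs(self.base) <= abs(self.lo)
            ):
                raise ValueError(f"{self.name}: base magnitude outside range")
        elif not (self.lo <= self.base <= self.hi):
            raise ValueError(
                f"{self.name}: requires lo <= base <= hi, got ({self.lo}, {self.base}, {self.hi})"
            )


class _PointMass:
    def __init__(self, value):
        self.value = float(value)
        self.mean = float(value)

    def rvs(self, rng, size=None):
        return np.full(size if size is not None else (), self.value)


class _Signed:
    """Wrap a magnitude sampler, restoring a negative sign (disutilities)."""

    def __init__(self, inner):
        self.inner = inner
        self.mean = -inner.mean

    def rvs(self, rng, size=None):
        return -self.inner.rvs(rng, size=size)


class _GammaMoments:
    def __init__(self, mean, sd):
        self.mean = float(mean)
        self.shape = (mean / sd) ** 2
        self.scale = sd**2 / mean

    def rvs(self, rng, size=None):
        return rng.gamma(self.shape, self.scale, size=size)


class _BetaMoments:
    def __init__(self, mean, sd, name=""):
        m = float(mean)
        if not 0 < m < 1:
            raise ValueError(f"{name}: beta mean must lie in (0,1), got {m}")
        vmax = m * (1 - m)
        v = sd**2
        if v >= vmax:
            warnings.warn(
                f"{name}: implied sd {sd:.4g} incompatible with beta support; shrunk to feasibility"
            )
            v = 0.95 * vmax
        nu = vmax / v - 1.0
        self.mean = m
        self.a = m * nu
        self.b = (1 - m) * nu

    def rvs(self, rng, size=None):
        return rng.beta(self.a, self.b, size=size)


def psa_dist_from_range(p: UncertainParam, z=1.96):
    """Build a sampleable distribution for one uncertain parameter.

    Gamma and beta are fitted by the method of moments with mean = base and
    sd = (hi - lo) / (2 z): the printed range is treated as an approximate
    95% interval (z configurable).  ``beta_pert`` interprets (lo, base, hi)
    as the PERT (min, mode, max).  ``fixed`` is a point mass.
    """
    if p.family == "fixed":
        return _PointMass(p.base)
    if p.role == "disutility":
        lo, hi = sorted((abs(p.lo), abs(p.hi)))
        base = abs(p.base)
        inner_param = UncertainParam(p.name, base, lo, hi, p.family, "probability")
        return _Signed(psa_dist_from_range(inner_param, z=z))
    sd = (p.hi - p.lo) / (2.0 * z)
    if p.family == "beta_pert":
        return pert_from_three_points(p.lo, p.base, p.hi)
    if sd <= 0:
        return _PointMass(p.base)
    if p.family == "gamma":
        return _GammaMoments(p.base, sd)
    return _BetaMoments(p.base, sd, name=p.name)
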