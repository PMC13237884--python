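"""Maximum-likelihood fitting of parametric survival families and AIC/BIC selection.

Right-censored log-likelihood: sum over events of ln f(t) plus sum over
censored records of ln S(t).  Optimization runs on transformed parameter
scales (log for positivity-constrained parameters, identity otherwise) with
deterministic multi-starts, because the Gompertz and generalized-gamma
likelihood surfaces are ridge-prone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .km_tools import PseudoIPD, km_estimate
from .survdist import FAMILY_PARAMS, ParametricSurvival, _POSITIVE

log = logging.getLogger(__name__)

__all__ = ["FitResult", "fit_mle", "information_criteria", "select_model", "fit_all"]

# deterministic multiplicative perturbations applied to the moment-based start
_START_FACTORS = (1.0, 0.5, 2.0, 0.8, 1.25)


@dataclass
class FitResult:
    dist: ParametricSurvival | None
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    se: np.ndarray | None = None

    @property
    def aic(self):
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def bic(self):
        return self.n_params * np.log(self.n_obs) - 2.0 * self.loglik

    @property
    def family(self):
        return self.dist.family if self.dist is not None else "unconverged"


def _initial_params(times, events, family):
    """Moment-style starting values per family."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    tpos = np.clip(t, 1e-8, None)
    rate0 = max(e.sum(), 1) / tpos.sum()
    logt = np.log(tpos[e]) if e.any() else np.log(tpos)
    mu0 = float(np.mean(logt))
    sigma0 = float(np.std(logt)) or 1.0
    med0 = float(np.median(tpos[e])) if e.any() else float(np.median(tpos))
    med0 = med0 or 1.0
    if family == "exponential":
        return (rate0,)
    if family == "weibull":
        return (1.0 / rate0, 1.0)
    if family == "gompertz":
        return (1e-3, rate0)
    if family == "loglogistic":
        return (med0, 1.5)
    if family == "lognormal":
        return (mu0, sigma0)
    return (mu0, sigma0, 0.5)  # gengamma


def _to_unconstrained(params, family):
    x = np.asarray(params, dtype=float).copy()
    for i in _POSITIVE[family]:
        x[i] = np.log(x[i])
    return x


def _from_unconstrained(x, family):
    p = np.asarray(x, dtype=float).copy()
    for i in _POSITIVE[family]:
        p[i] = np.exp(p[i])
    return tuple(p)


def loglikelihood(dist: ParametricSurvival, times, events):
    """Right-censored log-likelihood of ``dist`` for the given records."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    ll = 0.0
    if e.any():
        ll += float(np.sum(dist.logpdf(np.clip(t[e], 1e-12, None))))
    if (~e).any():
        ll += float(-np.sum(dist.cumhaz(t[~e])))
    return ll


def fit_mle(ipd: PseudoIPD, family: str, time_unit="months") -> FitResult:
    """Fit one parametric family to (pseudo-)IPD by maximum likelihood.

    Requires at least 10 records with at least one event.  Non-convergence
    after all starts is flagged honestly (``converged=False``) rather than
    returning a spurious optimum.
    """
    if family not in FAMILY_PARAMS:
        raise ValueError(f"unknown family {family!r}")
    t, e = ipd.times, ipd.events
    if len(t) < 10 or e.sum() < 1:
        raise ValueError("fit_mle needs >= 10 records with >= 1 event")

    def nll(x):
        try:
            dist = ParametricSurvival(family, _from_unconstrained(x, family), time_unit)
            v = -loglikelihood(dist, t, e)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e12
        return v if np.isfinite(v) else 1e12

    p0 = np.asarray(_initial_params(t, e, family), dtype=float)
    best = None
    for f in _START_FACTORS:
        start = p0 * f
        # keep unconstrained (location-like) parameters additive, not scaled
        for i in range(len(start)):
            if i not in _POSITIVE[family]:
                start[i] = p0[i] + np.log(f)
        # positivity-constrained entries must be positive before log-transform
        safe = start.copy()
        for i in _POSITIVE[family]:
            safe[i] = max(safe[i], 1e-8)
        x0 = _to_unconstrained(safe, family)
        res = optimize.minimize(nll, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success and np.isfinite(best.fun) and best.fun < 1e11)
    dist = None
    ll = -float(best.fun)
    if converged:
        dist = ParametricSurvival(family, _from_unconstrained(best.x, family), time_unit)
    else:
        log.warning("fit_mle: %s did not converge", family)
    return FitResult(
        dist=dist,
        loglik=ll,
        n_params=len(FAMILY_PARAMS[family]),
        n_obs=len(t),
        converged=converged,
    )


def information_criteria(fit: FitResult):
    """(AIC, BIC) of a converged fit: 2k - 2lnL and k ln n - 2lnL."""
    if not fit.converged:
        raise ValueError("information criteria require a converged fit")
    return fit.aic, fit.bic


def fit_all(ipd: PseudoIPD, families=None, time_unit="months"):
    """Fit every requested family; unconverged fits are kept but flagged."""
    families = families or list(FAMILY_PARAMS)
    return [fit_mle(ipd, fam, time_unit=time_unit) for fam in families]


def select_model(fits, ipd: PseudoIPD | None = None):
    """Rank converged fits by AIC (ties: BIC, then fewer parameters).

    Returns a DataFrame report (family, loglik, aic, bic, rank) plus, when
    the originating IPD is supplied, fitted-survival overlay columns at the
    KM step times for visual validation.
    """
    usable = [f for f in fits if f.converged]
    dropped = [f for f in fits if not f.converged]
    for f in dropped:
        log.warning("select_model: excluding unconverged %s fit", f.family)
    if not usable:
        raise ValueError("no converged fits to select from")
    usable.sort(key=lambda f: (f.aic, f.bic, f.n_params))
    rows = [
        {
            "family": f.family,
            "loglik": f.loglik,
            "n_params": f.n_params,
            "aic": f.aic,
            "bic": f.bic,
            "rank": i + 1,
        }
        for i, f in enumerate(usable)
    ]
    report = pd.DataFrame(rows)
    overlay = None
    if ipd is not None:
        km = km_estimate(ipd)
        overlay = pd.DataFrame({"time": km.times, "km_survival": km.survival})
        for f in usable:
            overlay[f"S_{f.family}"] = f.dist.survival(km.times)
    return report, overlay
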