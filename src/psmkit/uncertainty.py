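"""Deterministic (one-way) and probabilistic sensitivity analysis.

The per-draw decision rule is net monetary benefit, NMB = WTP * dQ - dC,
rather than an ICER comparison: NMB is linear and sign-stable where the
ICER is a ratio with an ambiguous sign when the QALY increment changes
sign.  Parameters are sampled independently (no correlation structure is
asserted by the source inputs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psm_core import icer, run_strategy
from .survdist import psa_dist_from_range

log = logging.getLogger(__name__)

__all__ = [
    "DsaRow",
    "PsaSample",
    "one_way_dsa",
    "dsa_table",
    "run_psa",
    "psa_table",
    "ceac",
    "ce_plane_summary",
]


@dataclass
class DsaRow:
    parameter: str
    lo_input: float
    hi_input: float
    icer_lo: float | None
    icer_hi: float | None
    nmb_lo: float
    nmb_hi: float
    spread: float
    note: str = ""


@dataclass
class PsaSample:
    draw: int
    params: dict
    delta_cost: float
    delta_qaly: float
    nmb: float


def _evaluate(config, overrides=None):
    arms = config.build_strategies(overrides)
    utilities = config.build_utilities(overrides)
    res = {
        name: run_strategy(
            spec, config.settings, config.background_mortality, utilities, keep_trace=False
        )
        for name, spec in arms.items()
    }
    return icer(res[config.intervention], res[config.comparator])


def one_way_dsa(config, params=None):
    """Re-run the base case at each parameter's lo and hi, all others at base.

    Rows come back sorted by ICER spread, largest first (tornado order).
    Where a variation makes the QALY increment cross zero the ICER is
    unstable; the row is annotated and its spread falls back to the NMB
    spread scaled to the WTP, flagged in ``note``.
    """
    params = params if params is not None else config.uncertain_params()
    wtp = config.settings.wtp
    rows = []
    for p in params:
        results = {}
        for tag, v in (("lo", p.lo), ("hi", p.hi)):
            results[tag] = _evaluate(config, {p.name: v})
        nmb = {t: wtp * r.delta_qaly - r.delta_cost for t, r in results.items()}
        icers = {t: r.icer for t, r in results.items()}
        note = ""
        if any(r.delta_qaly <= 0 for r in results.values()):
            note = "dQ crosses 0: ICER unstable, NMB reported"
            spread = abs(nmb["hi"] - nmb["lo"])
        elif icers["lo"] is None or icers["hi"] is None:
            note = "ICER undefined at a bound"
            spread = abs(nmb["hi"] - nmb["lo"])
        else:
            spread = abs(icers["hi"] - icers["lo"])
        rows.append(
            DsaRow(
                parameter=p.name,
                lo_input=p.lo,
                hi_input=p.hi,
                icer_lo=icers["lo"],
                icer_hi=icers["hi"],
                nmb_lo=nmb["lo"],
                nmb_hi=nmb["hi"],
                spread=spread,
                note=note,
            )
        )
    rows.sort(key=lambda r: -r.spread)
    return rows


def dsa_table(rows):
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "lo_input": [r.lo_input for r in rows],
            "hi_input": [r.hi_input for r in rows],
            "icer_lo": [r.icer_lo for r in rows],
            "icer_hi": [r.icer_hi for r in rows],
            "nmb_lo": [r.nmb_lo for r in rows],
            "nmb_hi": [r.nmb_hi for r in rows],
            "spread": [r.spread for r in rows],
            "note": [r.note for r in rows],
        }
    )


def run_psa(config, n_iter=1000, seed=0, params=None, max_resample=100):
    """Second-order Monte Carlo: joint independent draws of all uncertain inputs.

    Each draw rebuilds both strategies and evaluates the full model.  Draws
    that produce an invalid configuration (e.g. a probability escaping [0,1]
    after scale mapping) are resampled; the count is logged.
    """
    params = params if params is not None else config.uncertain_params()
    rng = np.random.default_rng(seed)
    samplers = {p.name: psa_dist_from_range(p) for p in params}
    wtp = config.settings.wtp
    samples = []
    n_resampled = 0
    for i in range(int(n_iter)):
        for _ in range(max_resample):
            draw = {name: float(s.rvs(rng)) for name, s in samplers.items()}
            try:
                res = _evaluate(config, draw)
                break
            except (ValueError, KeyError):
                n_resampled += 1
        else:
            raise RuntimeError("PSA could not produce a valid draw after resampling")
        samples.append(
            PsaSample(
                draw=i,
                params=draw,
                delta_cost=res.delta_cost,
                delta_qaly=res.delta_qaly,
                nmb=wtp * res.delta_qaly - res.delta_cost,
            )
        )
    if n_resampled:
        log.info("run_psa: %d invalid draws resampled", n_resampled)
    if samples:
        se = np.std([s.nmb > 0 for s in samples]) / np.sqrt(len(samples))
        log.info("run_psa: SE of P(CE at reference WTP) ~ %.4f", se)
    return samples


def psa_table(samples):
    return pd.DataFrame(
        {
            "draw": [s.draw for s in samples],
            "delta_cost": [s.delta_cost for s in samples],
            "delta_qaly": [s.delta_qaly for s in samples],
            "nmb": [s.nmb for s in samples],
        }
    )


def ceac(samples, wtp_grid):
    """Cost-effectiveness acceptability curve over a WTP grid.

    P(WTP) is the fraction of draws with positive net monetary benefit at
    that WTP; a draw with NMB exactly zero counts as not cost-effective.
    In the two-strategy case the comparator probability is the complement.
    """
    if not len(samples):
        raise ValueError("ceac requires at least one PSA sample")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if np.any(np.diff(wtp_grid) < 0):
        raise ValueError("wtp grid must be ascending")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    p = np.array([np.mean(w * dq - dc > 0) for w in wtp_grid])
    return pd.DataFrame(
        {"wtp": wtp_grid, "p_intervention": p, "p_comparator": 1.0 - p}
    )


def ce_plane_summary(samples, wtp):
    """Quadrant counts on the cost-effectiveness plane plus mean increments."""
    if not len(samples):
        raise ValueError("ce_plane_summary requires at least one PSA sample")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    quadrants = {
        "NE": int(np.sum((dq > 0) & (dc > 0))),
        "NW": int(np.sum((dq <= 0) & (dc > 0))),
        "SE": int(np.sum((dq > 0) & (dc <= 0))),
        "SW": int(np.sum((dq <= 0) & (dc <= 0))),
    }
    below_ray = int(np.sum(wtp * dq - dc > 0))
    return {
        "n": len(samples),
        "quadrants": quadrants,
        "p_cost_effective": below_ray / len(samples),
        "mean_delta_cost": float(dc.mean()),
        "mean_delta_qaly": float(dq.mean()),
        "cov": np.cov(np.vstack([dq, dc])).tolist(),
    }
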