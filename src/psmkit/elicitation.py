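"""Structured expert elicitation processing.

Experts provide three-point (minimum, most likely, maximum) cost estimates
over two Delphi rounds.  Between rounds, estimates outside the 1.5xIQR
fences are flagged as extreme outliers (flag-and-report only: revision is
user input, never automatic).  Final-round estimates are aggregated by
equal-weight linear pooling, and the pooled triple feeds the beta-PERT
parameterization in :mod:`psmkit.survdist`.

Quartiles use the linear-interpolation convention (numpy default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survdist import pert_from_three_points

__all__ = [
    "ExpertEstimate",
    "flag_outliers",
    "dispersion_stats",
    "pool_estimates",
    "pool_table",
]

_STATS = ("min", "mode", "max")


@dataclass(frozen=True)
class ExpertEstimate:
    expert_id: str
    parameter: str
    round: int
    min: float
    mode: float
    max: float
    rationale: bool = False

    def __post_init__(self):
        if not (self.min <= self.mode <= self.max):
            raise ValueError(
                f"expert {self.expert_id}, {self.parameter}: requires min <= mode <= max"
            )
        if self.round not in (1, 2):
            raise ValueError("round must be 1 or 2")


def _frame(estimates):
    if isinstance(estimates, pd.DataFrame):
        return estimates
    return pd.DataFrame(
        {
            "expert_id": [e.expert_id for e in estimates],
            "min": [e.min for e in estimates],
            "mode": [e.mode for e in estimates],
            "max": [e.max for e in estimates],
        }
    )


def flag_outliers(estimates) -> pd.DataFrame:
    """Flag experts outside the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Each of the three statistics is screened independently; values exactly
    at a fence are not flagged (strict inequality).  Fewer than 4 experts
    gives no flags, with a warning: quartiles of a tiny panel are noise.
    """
    df = _frame(estimates)
    flags = pd.DataFrame({"expert_id": df["expert_id"]})
    if len(df) < 4:
        warnings.warn("flag_outliers: fewer than 4 experts; no flags raised")
        for s in _STATS:
            flags[f"{s}_outlier"] = False
        return flags
    for s in _STATS:
        v = df[s].to_numpy(dtype=float)
        q1, q3 = np.percentile(v, [25, 75])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        flags[f"{s}_outlier"] = (v < lo) | (v > hi)
    return flags


def dispersion_stats(estimates) -> pd.DataFrame:
    """Per-statistic IQR and, on the modes, the coefficient of variation.

    CV = sd/mean (population sd); a zero mean leaves the CV undefined (NaN)
    and flagged.
    """
    df = _frame(estimates)
    if len(df) < 2:
        raise ValueError("dispersion_stats needs at least 2 experts")
    rows = []
    for s in _STATS:
        v = df[s].to_numpy(dtype=float)
        q1, q3 = np.percentile(v, [25, 75])
        mean = v.mean()
        cv = np.nan if mean == 0 else float(v.std() / mean)
        if mean == 0:
            warnings.warn(f"dispersion_stats: zero mean for {s}; CV undefined")
        rows.append({"statistic": s, "iqr": q3 - q1, "cv": cv})
    return pd.DataFrame(rows)


def pool_estimates(estimates):
    """Equal-weight linear pooling: the arithmetic mean of each statistic.

    Means preserve the min <= mode <= max ordering, so the pooled triple is
    always a valid beta-PERT input; the matching PertSpec is returned with it.
    """
    df = _frame(estimates)
    if len(df) < 1:
        raise ValueError("pool_estimates needs at least 1 expert")
    pooled = tuple(float(df[s].mean()) for s in _STATS)
    return pooled, pert_from_three_points(*pooled)


def pool_table(df: pd.DataFrame, round_=2) -> pd.DataFrame:
    """Pool every parameter of one round from a long-format estimates table."""
    req = {"expert_id", "parameter", "round", "min", "mode", "max"}
    if not req.issubset(df.columns):
        raise ValueError(f"estimates table needs columns {sorted(req)}")
    sub = df[df["round"] == round_]
    rows = []
    for param, grp in sub.groupby("parameter"):
        (mn, mode, mx), spec = pool_estimates(grp)
        rows.append(
            {
                "parameter": param,
                "n_experts": len(grp),
                "min": mn,
                "mode": mode,
                "max": mx,
                "pert_mean": spec.mean,
                "pert_alpha": spec.alpha,
                "pert_beta": spec.beta,
            }
        )
    return pd.DataFrame(rows)
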