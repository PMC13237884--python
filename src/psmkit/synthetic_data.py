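"""Synthetic fixtures: simulated trial IPD, emulated digitized curves, expert
panels and a miniature end-to-end model configuration.

Everything here is seed-deterministic so fixtures regenerate byte-stably.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .km_tools import DigitizedCurve, KMCurve, PseudoIPD
from .psm_core import ModelSettings
from .survdist import ParametricSurvival

__all__ = [
    "simulate_trial_ipd",
    "emulate_digitization",
    "make_toy_config",
    "make_expert_panel",
]

_DOMINANCE_TOL = 0.02  # max tolerated sup-norm violation of S_os >= S_pfs


def simulate_trial_ipd(
    pfs_dist: ParametricSurvival,
    os_dist: ParametricSurvival,
    n,
    admin_censor_time,
    seed=0,
    arm="",
):
    """Simulate coupled PFS/OS records with administrative censoring.

    Progression time P and death time D are coupled through a shared
    uniform: P = Q_pfs(U), D = max(P, Q_os(U)), which guarantees D >= P for
    every subject and reproduces the OS marginal exactly wherever
    S_os(t) >= S_pfs(t).  If the OS curve is materially stochastically
    smaller than the PFS curve the pair is inconsistent with a partitioned
    survival structure and an error naming the inconsistency is raised.

    Returns ``(pfs_ipd, os_ipd)``; the PFS endpoint is min(P, D) (progression
    or death, whichever first), OS is D, both truncated at
    ``admin_censor_time`` (in the distributions' shared time unit).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if pfs_dist.time_unit != os_dist.time_unit:
        raise ValueError("PFS and OS distributions must share a time unit")
    grid = np.linspace(0.0, max(float(admin_censor_time), 1e-9) * 2 + 1e-9, 201)[1:]
    gap = float(np.max(pfs_dist.survival(grid) - os_dist.survival(grid), initial=0.0))
    if gap > _DOMINANCE_TOL:
        raise ValueError(
            f"OS is stochastically smaller than PFS (sup violation {gap:.3f}); "
            "the pair cannot define a partitioned survival cohort"
        )
    rng = np.random.default_rng(seed)
    u = rng.uniform(np.finfo(float).tiny, 1.0, size=int(n))
    p_time = pfs_dist.quantile(u)
    d_time = np.maximum(p_time, os_dist.quantile(u))
    c = float(admin_censor_time)

    pfs_raw = np.minimum(p_time, d_time)
    pfs_event = (pfs_raw <= c).astype(int)
    pfs_time = np.minimum(pfs_raw, c)
    os_event = (d_time <= c).astype(int)
    os_time = np.minimum(d_time, c)

    pfs_ipd = PseudoIPD(
        pd.DataFrame({"time": pfs_time, "event": pfs_event}), arm=arm, endpoint="PFS"
    )
    os_ipd = PseudoIPD(
        pd.DataFrame({"time": os_time, "event": os_event}), arm=arm, endpoint="OS"
    )
    return pfs_ipd, os_ipd


def emulate_digitization(km: KMCurve, grid_size=40, jitter_sd=0.0, seed=0, risk_times=None):
    """Read a KM curve at grid times with additive noise, as a plot digitizer would.

    Monotonicity violations introduced by the jitter are deliberately left
    in: repairing them is the downstream consumer's job.  The risk table is
    taken exactly from the curve (digitizers copy it from the printed
    numbers-at-risk row, which is exact).
    """
    rng = np.random.default_rng(seed)
    t_max = float(km.times[-1])
    grid = np.linspace(0.0, t_max, int(grid_size))
    s = np.asarray(km.at(grid), dtype=float)
    if jitter_sd > 0:
        s = np.clip(s + rng.normal(0.0, jitter_sd, size=s.shape), 0.0, 1.0)
        s[0] = 1.0
    if risk_times is None:
        risk_times = np.linspace(0.0, t_max, 9)[:-1]
    risk_times = np.asarray(risk_times, dtype=float)
    # number still at risk just before each risk time: those with T >= t
    n_risk = [
        int(km.n_at_risk[np.searchsorted(km.times, t, side="left")])
        if t <= km.times[-1] and np.searchsorted(km.times, t, side="left") < len(km.times)
        else 0
        for t in risk_times
    ]
    keep = [i for i, nr in enumerate(n_risk) if nr > 0]
    return DigitizedCurve(
        points=pd.DataFrame({"time": grid, "survival": s}),
        risk_table=pd.DataFrame(
            {"time": risk_times[keep], "n_risk": [n_risk[i] for i in keep]}
        ),
        total_events=int(km.n_events.sum()),
    )


def make_toy_config(seed=0):
    """A miniature, fully deterministic two-arm model for end-to-end tests.

    Three-year horizon, exponential curves, two adverse events and simple
    costs so that hand-computed cycle sums are feasible.  The seed argument
    is accepted for interface symmetry but the configuration is
    deterministic by construction.
    """
    from .io_cli import ModelConfig  # deferred: io_cli imports psm_core

    settings = ModelSettings(
        cycle_days=21.0,
        horizon_years=3.0,
        discount_annual=0.03,
        wtp=50_000.0,
        start_age=60.0,
    )
    dists = {
        "new": {
            "pfs": ParametricSurvival("exponential", (0.05,), "months"),
            "os": ParametricSurvival("exponential", (0.03,), "months"),
        },
        "std": {
            "pfs": ParametricSurvival("exponential", (0.09,), "months"),
            "os": ParametricSurvival("exponential", (0.05,), "months"),
        },
    }
    values = {
        "cost_drug_new": dict(base=1000.0, family="gamma", rel_range=0.3, role="cost"),
        "cost_drug_std": dict(base=200.0, family="gamma", rel_range=0.3, role="cost"),
        "cost_followup": dict(base=100.0, family="beta_pert", lo=60.0, hi=140.0, role="cost"),
        "cost_bsc": dict(base=150.0, family="beta_pert", lo=90.0, hi=210.0, role="cost"),
        "cost_subsequent": dict(base=400.0, family="gamma", rel_range=0.3, role="cost"),
        "cost_ae_a": dict(base=500.0, family="gamma", rel_range=0.3, role="cost"),
        "cost_ae_b": dict(base=800.0, family="gamma", rel_range=0.3, role="cost"),
        "inc_new_a": dict(base=0.10, family="beta", rel_range=0.2, role="probability"),
        "inc_new_b": dict(base=0.05, family="beta", rel_range=0.2, role="probability"),
        "inc_std_a": dict(base=0.20, family="beta", rel_range=0.2, role="probability"),
        "inc_std_b": dict(base=0.02, family="beta", rel_range=0.2, role="probability"),
        "dis_a": dict(base=-0.08, family="beta", rel_range=0.2, role="disutility"),
        "dis_b": dict(base=-0.05, family="beta", rel_range=0.2, role="disutility"),
        "u_pfs": dict(base=0.8, family="beta", rel_range=0.2, role="utility"),
        "u_pd": dict(base=0.6, family="beta", rel_range=0.2, role="utility"),
        "uptake_new": dict(base=0.5, family="beta", rel_range=0.2, role="probability"),
        "uptake_std": dict(base=0.5, family="beta", rel_range=0.2, role="probability"),
    }
    from .io_cli import _value_to_param

    params = {k: _value_to_param(k, v) for k, v in values.items()}

    def arm(drug_key, inc_a, inc_b, uptake_key):
        return {
            "induction_drug_keys": [drug_key],
            "n_induction_cycles": 4,
            "maintenance_drug_keys": [drug_key],
            "maintenance_cap_years": 1.0,
            "followup_key": "cost_followup",
            "bsc_key": "cost_bsc",
            "uptake_key": uptake_key,
            "subsequent": [
                {"share": 1.0, "cost_keys": ["cost_subsequent"], "duration_months": 2.0}
            ],
            "ae": [
                {
                    "name": "ae_a",
                    "incidence_key": inc_a,
                    "cost_key": "cost_ae_a",
                    "disutility_key": "dis_a",
                },
                {
                    "name": "ae_b",
                    "incidence_key": inc_b,
                    "cost_key": "cost_ae_b",
                    "disutility_key": "dis_b",
                },
            ],
        }

    return ModelConfig(
        name="toy",
        settings=settings,
        dists=dists,
        values=params,
        arm_structure={
            "new": arm("cost_drug_new", "inc_new_a", "inc_new_b", "uptake_new"),
            "std": arm("cost_drug_std", "inc_std_a", "inc_std_b", "uptake_std"),
        },
        intervention="new",
        comparator="std",
    )


def make_expert_panel(parameter, n_experts=10, center=1000.0, spread=0.25, n_outliers=0, seed=0):
    """A synthetic expert panel of three-point estimates for one parameter."""
    rng = np.random.default_rng(seed)
    modes = center * rng.normal(1.0, spread / 3, size=n_experts).clip(0.3)
    rows = []
    for i, m in enumerate(modes):
        lo = m * (1 - spread)
        hi = m * (1 + spread)
        if i < n_outliers:
            lo, m, hi = lo * 8, m * 8, hi * 8
        rows.append(
            {
                "expert_id": f"E{i + 1:02d}",
                "parameter": parameter,
                "round": 1,
                "min": lo,
                "mode": m,
                "max": hi,
            }
        )
    return pd.DataFrame(rows)
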