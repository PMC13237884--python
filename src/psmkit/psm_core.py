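"""The partitioned survival engine.

State occupancy is read directly off the two survival curves at each cycle's
evaluation time: progression-free (PFD) membership is S_PFS, progressive
disease (PD) is S_OS - S_PFS, and death is 1 - S_OS.  Disease-specific
overall survival can be blended with general-population background
mortality by a hazard-max rule (the all-cause hazard never falls below the
background hazard), after which the adjusted curve is re-integrated
cycle by cycle.  Costs and quality-adjusted life-years accrue per cycle and
are discounted at a discrete annual rate evaluated at the cycle's
(by default, midpoint) time - a half-cycle correction.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .survdist import TIME_UNIT_DAYS, ParametricSurvival

log = logging.getLogger(__name__)

#: the dosing cycle the per-cycle cost inputs refer to; evaluating the model
#: on a different cycle grid rescales cost rates accordingly
REF_CYCLE_DAYS = 21.0

__all__ = [
    "ModelSettings",
    "BackgroundMortality",
    "AdverseEvent",
    "SubsequentComponent",
    "StrategySpec",
    "Utilities",
    "OccupancyTrace",
    "StrategyResult",
    "CEResult",
    "build_trace",
    "cost_stream",
    "qaly_stream",
    "cycle_cost",
    "cycle_qaly",
    "discounted_total",
    "run_strategy",
    "icer",
    "run_base_case",
]


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings: 21-day cycles over a lifetime horizon, 3%/yr discount."""

    cycle_days: float = 21.0
    horizon_years: float = 16.0
    discount_annual: float = 0.03
    wtp: float = 90_000.0
    start_age: float = 64.0
    evaluation: str = "midpoint"  # or "start"

    def __post_init__(self):
        if self.cycle_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle length and horizon must be positive")
        if not 0 <= self.discount_annual < 1:
            raise ValueError("discount rate must lie in [0, 1)")
        if self.evaluation not in ("midpoint", "start"):
            raise ValueError("evaluation must be 'midpoint' or 'start'")
        if self.n_cycles < 1:
            raise ValueError("horizon shorter than one cycle")

    @property
    def n_cycles(self):
        return int(math.floor(self.horizon_years * 365.25 / self.cycle_days))

    @property
    def cycle_years(self):
        return self.cycle_days / 365.25


class BackgroundMortality:
    """General-population mortality as a step table of annual hazard by age.

    The base case ships with zero background mortality (national life-table
    values are a user-supplied input); :meth:`from_table` accepts any
    (age, annual_rate) table, and :meth:`zero` is the explicit null table.
    """

    def __init__(self, ages, annual_rates):
        self.ages = np.asarray(ages, dtype=float)
        self.rates = np.asarray(annual_rates, dtype=float)
        if len(self.ages) != len(self.rates):
            raise ValueError("ages and rates must have equal length")
        if len(self.ages) and (np.diff(self.ages) <= 0).any():
            raise ValueError("ages must be strictly increasing")
        if (self.rates < 0).any():
            raise ValueError("annual rates must be non-negative")

    @classmethod
    def zero(cls):
        return cls([], [])

    @classmethod
    def from_table(cls, df):
        df = pd.DataFrame(df)
        return cls(df["age"].to_numpy(), df["annual_rate"].to_numpy())

    def annual_hazard(self, age):
        age = np.asarray(age, dtype=float)
        if len(self.ages) == 0:
            return np.zeros_like(age)
        idx = np.clip(np.searchsorted(self.ages, age, side="right") - 1, 0, len(self.ages) - 1)
        out = self.rates[idx]
        return np.where(age < self.ages[0], 0.0, out)


@dataclass(frozen=True)
class AdverseEvent:
    """A grade >=3 adverse event: incidence, one-off management cost, one-off disutility."""

    name: str
    incidence: float
    cost: float
    disutility: float  # <= 0, in utility units

    def __post_init__(self):
        if not 0 <= self.incidence <= 1:
            raise ValueError(f"{self.name}: incidence must lie in [0, 1]")
        if self.cost < 0:
            raise ValueError(f"{self.name}: cost must be >= 0")
        if self.disutility > 0:
            raise ValueError(f"{self.name}: disutility must be <= 0")


@dataclass(frozen=True)
class SubsequentComponent:
    """One subsequent-therapy option: usage share, per-cycle cost, duration."""

    share: float
    cost_per_cycle: float
    duration_months: float

    def __post_init__(self):
        if not 0 <= self.share <= 1:
            raise ValueError("subsequent-therapy share must lie in [0, 1]")
        if self.cost_per_cycle < 0 or self.duration_months < 0:
            raise ValueError("subsequent-therapy cost and duration must be >= 0")


@dataclass(frozen=True)
class Utilities:
    pfs: float = 0.817
    pd: float = 0.779

    def __post_init__(self):
        for v in (self.pfs, self.pd):
            if not 0 <= v <= 1:
                raise ValueError("utilities must lie in [0, 1]")


@dataclass(frozen=True)
class StrategySpec:
    """One treatment arm: curves, dosing schedule and economic inputs.

    Drug costs are per 21-day cycle.  Induction covers the first
    ``n_induction_cycles`` cycles (chemotherapy plus, where applicable, the
    index drug); maintenance covers cycles up to ``maintenance_cap_years``.
    Routine follow-up accrues per progression-free cycle; best supportive
    care accrues per progressive-disease cycle for the fraction not taking
    active subsequent therapy; subsequent therapy itself is charged as a
    lump (per-cycle cost x duration) in the cycle of progression.
    """

    name: str
    pfs: ParametricSurvival
    os: ParametricSurvival
    induction_drug_cost: float = 0.0
    n_induction_cycles: int = 6
    maintenance_drug_cost: float = 0.0
    maintenance_cap_years: float = 3.0
    followup_cost: float = 0.0
    bsc_cost: float = 0.0
    ae_profile: tuple = ()
    subsequent_uptake: float = 0.0
    subsequent_components: tuple = ()

    def __post_init__(self):
        if not 0 <= self.subsequent_uptake <= 1:
            raise ValueError("subsequent-therapy uptake must lie in [0, 1]")
        for c in (
            self.induction_drug_cost,
            self.maintenance_drug_cost,
            self.followup_cost,
            self.bsc_cost,
        ):
            if c < 0:
                raise ValueError("costs must be >= 0")

    def subsequent_lump_cost(self):
        """Expected lump cost of subsequent therapy per uptaking progressor."""
        total = 0.0
        for comp in self.subsequent_components:
            duration_cycles = comp.duration_months * TIME_UNIT_DAYS["months"] / REF_CYCLE_DAYS
            total += comp.share * comp.cost_per_cycle * duration_cycles
        return total

    def ae_expected_cost(self):
        return sum(ae.incidence * ae.cost for ae in self.ae_profile)

    def ae_expected_disutility(self):
        return sum(ae.incidence * abs(ae.disutility) for ae in self.ae_profile)


@dataclass
class OccupancyTrace:
    """Per-cycle state occupancy evaluated at the cycle evaluation times."""

    time_years: np.ndarray
    pf: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    new_pd: np.ndarray
    discount: np.ndarray
    cycle_years: float

    def __len__(self):
        return len(self.pf)

    @property
    def alive(self):
        return self.pf + self.pd

    def to_frame(self):
        return pd.DataFrame(
            {
                "time_years": self.time_years,
                "pf": self.pf,
                "pd": self.pd,
                "dead": self.dead,
                "new_pd": self.new_pd,
                "discount": self.discount,
            }
        )


def build_trace(
    pfs: ParametricSurvival,
    os: ParametricSurvival,
    bg: BackgroundMortality | None,
    settings: ModelSettings,
) -> OccupancyTrace:
    """Evaluate three-state occupancy cycle by cycle.

    The all-cause cumulative hazard accumulates per cycle as the maximum of
    the disease-specific OS hazard increment and the background-mortality
    increment, so the adjusted OS curve never crosses above the
    general-population survival curve.  PFS exceeding adjusted OS is
    permitted in the inputs but clamped (and logged) in the occupancy.
    """
    bg = bg or BackgroundMortality.zero()
    n = settings.n_cycles
    offset = 0.5 if settings.evaluation == "midpoint" else 0.0
    t_days = (np.arange(n) + offset) * settings.cycle_days
    t_years = t_days / 365.25

    def cumhaz(dist, days):
        return dist.cumhaz(days / TIME_UNIT_DAYS[dist.time_unit])

    H_os = cumhaz(os, t_days)
    # background cumulative hazard on the same segment grid
    seg_edges = np.concatenate([[0.0], t_years])
    seg_len = np.diff(seg_edges)
    seg_mid_age = settings.start_age + (seg_edges[:-1] + seg_edges[1:]) / 2.0
    dH_bg = bg.annual_hazard(seg_mid_age) * seg_len
    dH_os = np.diff(np.concatenate([[0.0], H_os]))
    H_adj = np.cumsum(np.maximum(dH_os, dH_bg))
    S_adj = np.exp(-H_adj)

    S_pfs = pfs.survival(t_days / TIME_UNIT_DAYS[pfs.time_unit])
    violation = float(np.max(S_pfs - S_adj, initial=0.0))
    if violation > 1e-9:
        log.info("build_trace: PFS exceeds adjusted OS by up to %.4g; clamped", violation)

    pf = np.minimum(S_pfs, S_adj)
    pd_ = S_adj - pf
    dead = 1.0 - S_adj

    pf_prev = np.concatenate([[1.0], pf[:-1]])
    dead_prev = np.concatenate([[0.0], dead[:-1]])
    alive_prev = 1.0 - dead_prev
    d_dead = dead - dead_prev
    with np.errstate(invalid="ignore", divide="ignore"):
        death_from_pf = np.where(alive_prev > 0, d_dead * pf_prev / alive_prev, 0.0)
    new_pd = np.maximum(0.0, pf_prev - pf - death_from_pf)

    if np.any(pd_ < -1e-12) or np.any(pf < -1e-12):
        raise RuntimeError("negative state occupancy after clamping (invariant breach)")

    discount = (1.0 + settings.discount_annual) ** (-t_years)
    return OccupancyTrace(
        time_years=t_years,
        pf=pf,
        pd=pd_,
        dead=dead,
        new_pd=new_pd,
        discount=discount,
        cycle_years=settings.cycle_years,
    )


def cost_stream(s: StrategySpec, trace: OccupancyTrace, settings: ModelSettings):
    """Undiscounted expected cost per cycle, with a component breakdown.

    Returns ``(total_per_cycle, breakdown_frame)``.
    """
    n = len(trace)
    i = np.arange(n)
    # per-cycle rates are stated per 21-day reference cycle; rescale to the
    # evaluation grid so totals are invariant to the discretization
    scale = settings.cycle_days / REF_CYCLE_DAYS
    # fraction of each cycle lying inside the induction window / treatment cap;
    # boundary cycles are charged pro rata so totals do not depend on the grid
    ind_days = s.n_induction_cycles * REF_CYCLE_DAYS
    cap_days = s.maintenance_cap_years * 365.25
    f_ind = np.clip(ind_days / settings.cycle_days - i, 0.0, 1.0)
    f_cap = np.clip(cap_days / settings.cycle_days - i, 0.0, 1.0)
    drug_rate = s.induction_drug_cost * f_ind + s.maintenance_drug_cost * np.maximum(
        0.0, f_cap - f_ind
    )
    drug = trace.pf * drug_rate * scale
    followup = trace.pf * s.followup_cost * scale
    bsc = trace.pd * (1.0 - s.subsequent_uptake) * s.bsc_cost * scale
    subsequent = trace.new_pd * s.subsequent_uptake * s.subsequent_lump_cost()
    ae = np.zeros(n)
    ae[0] = s.ae_expected_cost()
    breakdown = pd.DataFrame(
        {"drug": drug, "followup": followup, "bsc": bsc, "subsequent": subsequent, "ae": ae}
    )
    return drug + followup + bsc + subsequent + ae, breakdown


def qaly_stream(s: StrategySpec, trace: OccupancyTrace, utilities: Utilities):
    """Undiscounted expected QALYs per cycle.

    State time is weighted by its utility; adverse-event disutilities are a
    one-time decrement applied in the first cycle (the cycle of occurrence
    for first-line toxicity), scaled by the cycle length in years.
    """
    q = (trace.pf * utilities.pfs + trace.pd * utilities.pd) * trace.cycle_years
    q = q.copy()
    q[0] -= s.ae_expected_disutility() * trace.cycle_years
    return q


def cycle_cost(i, s: StrategySpec, trace: OccupancyTrace, settings: ModelSettings):
    """Expected undiscounted cost in cycle ``i`` (0-based)."""
    total, _ = cost_stream(s, trace, settings)
    return float(total[i])


def cycle_qaly(i, s: StrategySpec, trace: OccupancyTrace, utilities: Utilities):
    """Expected undiscounted QALYs accrued in cycle ``i`` (0-based)."""
    return float(qaly_stream(s, trace, utilities)[i])


def discounted_total(stream, times_years, annual_rate):
    """Present value of a cash/QALY stream at a discrete annual discount rate."""
    stream = np.asarray(stream, dtype=float)
    times_years = np.asarray(times_years, dtype=float)
    return float(np.sum(stream / (1.0 + annual_rate) ** times_years))


@dataclass
class StrategyResult:
    name: str
    cost: float
    qaly: float
    life_years: float
    trace: OccupancyTrace | None = None
    ledger: pd.DataFrame | None = None


def run_strategy(
    s: StrategySpec,
    settings: ModelSettings,
    bg: BackgroundMortality | None = None,
    utilities: Utilities | None = None,
    keep_trace=True,
) -> StrategyResult:
    """Full single-arm evaluation: trace, cost, QALY and life-year totals."""
    utilities = utilities or Utilities()
    trace = build_trace(s.pfs, s.os, bg, settings)
    costs, breakdown = cost_stream(s, trace, settings)
    qalys = qaly_stream(s, trace, utilities)
    r = settings.discount_annual
    result = StrategyResult(
        name=s.name,
        cost=discounted_total(costs, trace.time_years, r),
        qaly=discounted_total(qalys, trace.time_years, r),
        life_years=float(np.sum(trace.alive) * trace.cycle_years),
    )
    if keep_trace:
        ledger = trace.to_frame()
        ledger[["cost_" + c for c in breakdown.columns]] = breakdown
        ledger["cost_total"] = costs
        ledger["qaly"] = qalys
        result.trace = trace
        result.ledger = ledger
    return result


@dataclass
class CEResult:
    """Two-arm cost-effectiveness comparison."""

    intervention: StrategyResult
    comparator: StrategyResult
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str | None

    def to_dict(self):
        return {
            "intervention": {
                "name": self.intervention.name,
                "cost": self.intervention.cost,
                "qaly": self.intervention.qaly,
                "life_years": self.intervention.life_years,
            },
            "comparator": {
                "name": self.comparator.name,
                "cost": self.comparator.cost,
                "qaly": self.comparator.qaly,
                "life_years": self.comparator.life_years,
            },
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
        }

    def to_json(self, path=None, **kw):
        s = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def icer(intervention: StrategyResult, comparator: StrategyResult) -> CEResult:
    """Incremental cost-effectiveness ratio with dominance flags.

    The ratio is undefined (None) when the QALY increment is zero; strict
    dominance is labelled when the intervention is cheaper and more
    effective (or dearer and less effective).
    """
    dc = intervention.cost - comparator.cost
    dq = intervention.qaly - comparator.qaly
    ratio = dc / dq if dq != 0 else None
    dominance = None
    if dc < 0 and dq > 0:
        dominance = "intervention_dominates"
    elif dc > 0 and dq < 0:
        dominance = "comparator_dominates"
    return CEResult(intervention, comparator, dc, dq, ratio, dominance)


def run_base_case(population="overall", config=None, keep_trace=True) -> CEResult:
    """Run the packaged two-arm base case for one population.

    ``population`` is one of overall / dmmr / pmmr; a pre-loaded
    :class:`psmkit.io_cli.ModelConfig` can be passed instead.
    """
    from . import io_cli  # local import: io_cli builds on this module

    cfg = config if config is not None else io_cli.load_packaged_config(population)
    arms = cfg.build_strategies()
    utilities = cfg.build_utilities()
    bg = cfg.background_mortality
    res = {
        name: run_strategy(spec, cfg.settings, bg, utilities, keep_trace=keep_trace)
        for name, spec in arms.items()
    }
    return icer(res[cfg.intervention], res[cfg.comparator])
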