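"""The partitioned-survival engine: occupancy, costing, discounting, ICER."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from psmkit.io_cli import load_packaged_config
from psmkit.psm_core import (
    AdverseEvent,
    BackgroundMortality,
    ModelSettings,
    StrategySpec,
    StrategyResult,
    SubsequentComponent,
    Utilities,
    build_trace,
    cycle_cost,
    cycle_qaly,
    discounted_total,
    icer,
    run_base_case,
    run_strategy,
)
from psmkit.survdist import ParametricSurvival

EXP = lambda r: ParametricSurvival("exponential", (r,), "months")


def test_identical_curves_give_zero_pd():
    s = ModelSettings(horizon_years=5.0)
    tr = build_trace(EXP(0.05), EXP(0.05), None, s)
    assert np.allclose(tr.pd, 0.0, atol=1e-15)
    assert np.allclose(tr.pf + tr.dead, 1.0, atol=1e-12)


def test_death_matches_exponential_closed_form():
    s = ModelSettings(horizon_years=16.0)
    tr = build_trace(EXP(0.0153), EXP(0.0153), None, s)
    t_months = tr.time_years * 12
    assert np.allclose(tr.dead, 1 - np.exp(-0.0153 * t_months), atol=1e-10)
    # at one year the cumulative mortality is ~1 - e^{-0.1836}
    i = np.argmin(np.abs(tr.time_years - 1.0))
    assert tr.dead[i] == pytest.approx(1 - math.exp(-0.1836), abs=5e-3)


def test_background_hazard_dominates_when_larger():
    """With background mortality far above disease mortality, survival follows it."""
    s = ModelSettings(horizon_years=10.0)
    bg = BackgroundMortality([0.0], [0.5])
    tr = build_trace(EXP(1e-5), EXP(1e-5), bg, s)
    expected = np.exp(-0.5 * tr.time_years)
    assert np.allclose(1 - tr.dead, expected, rtol=1e-6)


def test_background_blend_never_raises_survival():
    s = ModelSettings(horizon_years=10.0)
    bg = BackgroundMortality([60, 70, 80], [0.01, 0.03, 0.08])
    tr_bg = build_trace(EXP(0.03), EXP(0.02), bg, s)
    tr_0 = build_trace(EXP(0.03), EXP(0.02), None, s)
    assert np.all(tr_bg.dead >= tr_0.dead - 1e-12)


def test_occupancy_invariants_on_packaged_configs():
    for pop in ("overall", "dmmr", "pmmr"):
        cfg = load_packaged_config(pop)
        for spec in cfg.build_strategies().values():
            tr = build_trace(spec.pfs, spec.os, None, cfg.settings)
            assert np.max(np.abs(tr.pf + tr.pd + tr.dead - 1.0)) < 1e-12
            assert np.all(np.diff(tr.pf) <= 1e-12)
            assert np.all(np.diff(tr.pf + tr.pd) <= 1e-12)
            assert np.all(np.diff(tr.dead) >= -1e-12)
            assert np.all((tr.pf >= 0) & (tr.pd >= 0) & (tr.dead >= 0))
            assert np.all(tr.new_pd >= 0)


def test_discounting_rules():
    assert discounted_total([1.0, 2.0, 3.0], [0.5, 1.0, 1.5], 0.0) == pytest.approx(6.0)
    assert discounted_total([100.0], [1.0], 0.03) == pytest.approx(100 / 1.03)
    stream = np.ones(10)
    t = np.linspace(0.1, 5, 10)
    assert discounted_total(stream, t, 0.03) < stream.sum()


def _toy_strategy(**kw):
    base = dict(
        name="x",
        pfs=EXP(0.05),
        os=EXP(0.03),
        induction_drug_cost=1000.0,
        n_induction_cycles=4,
        maintenance_drug_cost=1000.0,
        maintenance_cap_years=1.0,
        followup_cost=100.0,
        bsc_cost=150.0,
        ae_profile=(
            AdverseEvent("a", 0.10, 500.0, -0.08),
            AdverseEvent("b", 0.05, 800.0, -0.05),
        ),
        subsequent_uptake=0.5,
        subsequent_components=(SubsequentComponent(1.0, 400.0, 2.0),),
    )
    base.update(kw)
    return StrategySpec(**base)


def test_zero_costs_give_zero_total():
    s = _toy_strategy(
        induction_drug_cost=0.0,
        maintenance_drug_cost=0.0,
        followup_cost=0.0,
        bsc_cost=0.0,
        ae_profile=(),
        subsequent_components=(),
    )
    res = run_strategy(s, ModelSettings(horizon_years=3.0), None, Utilities(0.8, 0.6))
    assert res.cost == 0.0
    assert res.qaly > 0


def test_cost_linearity_under_doubling():
    settings = ModelSettings(horizon_years=3.0)
    s1 = _toy_strategy()
    s2 = _toy_strategy(
        induction_drug_cost=2000.0,
        maintenance_drug_cost=2000.0,
        followup_cost=200.0,
        bsc_cost=300.0,
        ae_profile=(
            AdverseEvent("a", 0.10, 1000.0, -0.08),
            AdverseEvent("b", 0.05, 1600.0, -0.05),
        ),
        subsequent_components=(SubsequentComponent(1.0, 800.0, 2.0),),
    )
    r1 = run_strategy(s1, settings, None, Utilities(0.8, 0.6))
    r2 = run_strategy(s2, settings, None, Utilities(0.8, 0.6))
    assert r2.cost == pytest.approx(2 * r1.cost, rel=1e-12)
    assert r2.qaly == pytest.approx(r1.qaly, rel=1e-12)


def test_engine_matches_brute_force_cycle_sum():
    """Spreadsheet-style independent re-computation of the toy arm to 1e-9."""
    settings = ModelSettings(cycle_days=21.0, horizon_years=3.0, discount_annual=0.03)
    spec = _toy_strategy()
    util = Utilities(0.8, 0.6)
    res = run_strategy(spec, settings, None, util)

    mpd = 365.25 / 12
    n_cycles = int(3 * 365.25 // 21)
    cap_days = 365.25  # one-year treatment cap, boundary cycle charged pro rata
    sub_lump = 0.5 * 400.0 * (2.0 * mpd / 21.0)  # uptake x cost x duration-cycles
    cost_total = 0.0
    qaly_total = 0.0
    ly_total = 0.0
    pf_prev, dead_prev = 1.0, 0.0
    for i in range(n_cycles):
        td = (i + 0.5) * 21.0
        tm, ty = td / mpd, td / 365.25
        sp, so = math.exp(-0.05 * tm), math.exp(-0.03 * tm)
        pf = min(sp, so)
        pdd = so - pf
        dead = 1 - so
        dfp = (dead - dead_prev) * pf_prev / (1 - dead_prev)
        newpd = max(0.0, pf_prev - pf - dfp)
        drug = 1000.0 * min(1.0, max(0.0, cap_days / 21.0 - i))
        cost = pf * drug + pf * 100.0 + pdd * 0.5 * 150.0 + newpd * sub_lump
        if i == 0:
            cost += 0.10 * 500.0 + 0.05 * 800.0
        qaly = (pf * 0.8 + pdd * 0.6) * (21.0 / 365.25)
        if i == 0:
            qaly -= (0.10 * 0.08 + 0.05 * 0.05) * (21.0 / 365.25)
        disc = 1.03 ** (-ty)
        cost_total += cost * disc
        qaly_total += qaly * disc
        ly_total += (pf + pdd) * (21.0 / 365.25)
        pf_prev, dead_prev = pf, dead

    assert res.cost == pytest.approx(cost_total, abs=1e-9)
    assert res.qaly == pytest.approx(qaly_total, abs=1e-9)
    assert res.life_years == pytest.approx(ly_total, abs=1e-9)


def test_cycle_cost_and_qaly_index_the_streams():
    settings = ModelSettings(horizon_years=3.0)
    spec = _toy_strategy()
    tr = build_trace(spec.pfs, spec.os, None, settings)
    c0 = cycle_cost(0, spec, tr, settings)
    # first cycle: drug + follow-up on PF, AE lump, small PD/subsequent terms
    assert c0 > 0.10 * 500 + 0.05 * 800
    assert cycle_qaly(5, spec, tr, Utilities(1.0, 1.0)) == pytest.approx(
        (tr.pf[5] + tr.pd[5]) * tr.cycle_years
    )


def test_equal_utilities_collapse_to_discounted_life_years():
    settings = ModelSettings(horizon_years=3.0)
    spec = _toy_strategy(ae_profile=())
    res = run_strategy(spec, settings, None, Utilities(0.7, 0.7))
    tr = res.trace
    disc_ly = discounted_total(
        (tr.pf + tr.pd) * tr.cycle_years, tr.time_years, 0.03
    )
    assert res.qaly == pytest.approx(0.7 * disc_ly, rel=1e-12)


def test_long_horizon_exponential_matches_continuous_limit():
    """Utilities 1, zero bg: discounted QALYs approach the continuous integral."""
    r = 0.05  # per month
    settings = ModelSettings(horizon_years=40.0, discount_annual=0.03)
    spec = _toy_strategy(
        pfs=EXP(r), os=EXP(r), ae_profile=(), subsequent_components=()
    )
    res = run_strategy(spec, settings, None, Utilities(1.0, 1.0))
    integral, _ = quad(
        lambda ty: math.exp(-r * 12 * ty) * 1.03 ** (-ty), 0, 40.0, limit=400
    )
    assert res.qaly == pytest.approx(integral, rel=2e-3)


def test_icer_arithmetic_and_flags():
    a = StrategyResult("a", cost=100.0, qaly=2.0, life_years=2.0)
    b = StrategyResult("b", cost=0.0, qaly=1.0, life_years=1.0)
    r = icer(a, b)
    assert r.icer == pytest.approx(100.0)
    assert r.dominance is None

    same = icer(a, a)
    assert same.icer is None
    assert same.delta_cost == 0.0

    dom = icer(StrategyResult("c", 50.0, 3.0, 3.0), StrategyResult("d", 80.0, 1.0, 1.0))
    assert dom.dominance == "intervention_dominates"


def test_icer_matches_rounded_table_arithmetic():
    """ICER from rounded two-arm totals: 144,717 / 1.55 ~ 93,366 $/QALY."""
    r = icer(
        StrategyResult("dsr", 309_419.0, 4.62, 5.0),
        StrategyResult("pbo", 164_702.0, 3.07, 3.5),
    )
    assert r.delta_cost == pytest.approx(144_717.0)
    assert r.delta_qaly == pytest.approx(1.55)
    assert r.icer == pytest.approx(93_366, abs=2.0)


def test_cycle_length_discretization_stability(toy_config):
    """Shrinking the cycle from 21 to 7 days moves totals by well under 1%."""
    from dataclasses import replace

    res21 = run_base_case(config=toy_config, keep_trace=False)
    cfg7 = load_toy_with_cycle(toy_config, 7.0)
    res7 = run_base_case(config=cfg7, keep_trace=False)
    for a, b in (
        (res21.intervention.cost, res7.intervention.cost),
        (res21.intervention.qaly, res7.intervention.qaly),
        (res21.comparator.cost, res7.comparator.cost),
        (res21.comparator.qaly, res7.comparator.qaly),
    ):
        assert abs(a - b) / abs(b) < 0.01


def load_toy_with_cycle(cfg, cycle_days):
    from dataclasses import replace as dc_replace
    import copy

    new = copy.copy(cfg)
    new.settings = dc_replace(cfg.settings, cycle_days=cycle_days)
    return new


def test_start_of_cycle_evaluation_is_configurable():
    s_mid = ModelSettings(horizon_years=3.0, evaluation="midpoint")
    s_start = ModelSettings(horizon_years=3.0, evaluation="start")
    spec = _toy_strategy()
    r_mid = run_strategy(spec, s_mid, None, Utilities(0.8, 0.6))
    r_start = run_strategy(spec, s_start, None, Utilities(0.8, 0.6))
    # start-of-cycle counts everyone alive at t=0, so it accrues more
    assert r_start.qaly > r_mid.qaly


def test_run_base_case_populations_and_icer_ordering():
    results = {p: run_base_case(p, keep_trace=False) for p in ("overall", "dmmr", "pmmr")}
    for r in results.values():
        assert r.delta_cost > 0 and r.delta_qaly > 0  # more costly, more effective
        assert r.icer is not None and r.icer > 0
        for arm in (r.intervention, r.comparator):
            assert 0 < arm.qaly <= arm.life_years <= 16.0
    assert results["dmmr"].icer < results["overall"].icer < results["pmmr"].icer


def test_run_base_case_emits_per_cycle_ledger():
    r = run_base_case("overall")
    led = r.intervention.ledger
    assert {"pf", "pd", "dead", "cost_drug", "cost_total", "qaly"}.issubset(led.columns)
    assert len(led) == ModelSettings().n_cycles


def test_settings_validation():
    with pytest.raises(ValueError):
        ModelSettings(discount_annual=1.5)
    with pytest.raises(ValueError):
        ModelSettings(horizon_years=0.01)  # shorter than one cycle
    with pytest.raises(ValueError):
        ModelSettings(evaluation="end")
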