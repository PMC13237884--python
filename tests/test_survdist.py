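"""Closed-form survival mathematics and PSA distribution construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from psmkit.survdist import (
    ParametricSurvival,
    PertSpec,
    UncertainParam,
    pert_from_three_points,
    psa_dist_from_range,
)

# representative, well-conditioned parameter sets per family
CASES = [
    ("exponential", (0.1,)),
    ("weibull", (21.4562, 1.0189)),
    ("gompertz", (0.05, 0.02)),
    ("gompertz", (0.0008, 0.0153)),
    ("loglogistic", (8.0441, 1.9689)),
    ("lognormal", (2.2501, 0.9401)),
    ("gengamma", (3.8011, 1.4753, 0.6576)),
    ("gengamma", (2.8385, 0.8319, -0.5)),
]


@pytest.mark.parametrize("family,params", CASES)
def test_survival_basics(family, params):
    d = ParametricSurvival(family, params)
    t = np.linspace(0, 120, 400)
    s = d.survival(t)
    assert s[0] == 1.0
    assert np.all(np.diff(s) <= 1e-12)
    assert np.all((s >= 0) & (s <= 1))


@pytest.mark.parametrize("family,params", CASES)
def test_quantile_survival_identity(family, params):
    d = ParametricSurvival(family, params)
    p = np.array([0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99])
    q = d.quantile(p)
    assert np.allclose(d.survival(q), 1 - p, atol=1e-6)


@pytest.mark.parametrize("family,params", CASES)
def test_hazard_integral_matches_cumhaz(family, params):
    """Numerical integral of h equals -ln S (oracle equivalence)."""
    d = ParametricSurvival(family, params)
    for t in (5.0, 15.0, 40.0):
        integral, _ = quad(lambda u: float(d.hazard(u)), 0, t, limit=400)
        assert abs(integral - float(d.cumhaz(t))) < 1e-4


def test_weibull_unit_shape_is_exponential():
    lam = 21.4562
    w = ParametricSurvival("weibull", (lam, 1.0))
    e = ParametricSurvival("exponential", (1 / lam,))
    t = np.linspace(0.1, 100, 200)
    assert np.allclose(w.survival(t), e.survival(t), atol=1e-12)
    assert np.allclose(w.hazard(t), 1 / lam)


def test_gompertz_small_shape_approaches_exponential():
    d = ParametricSurvival("gompertz", (0.0008, 0.0153))
    assert abs(float(d.survival(12.0)) - math.exp(-0.1836)) < 1e-3
    integral, _ = quad(lambda u: float(d.hazard(u)), 0, 12.0, limit=200)
    assert abs(integral - float(d.cumhaz(12.0))) < 1e-6


def test_gompertz_hazard_at_zero_is_rate():
    d = ParametricSurvival("gompertz", (0.0008, 0.0153))
    assert float(d.hazard(0.0)) == pytest.approx(0.0153)


def test_lognormal_median():
    d = ParametricSurvival("lognormal", (2.2501, 0.9401))
    med = math.exp(2.2501)
    assert float(d.survival(med)) == pytest.approx(0.5, abs=1e-12)
    assert float(d.quantile(0.5)) == pytest.approx(med, rel=1e-10)


def test_weibull_median_closed_form():
    d = ParametricSurvival("weibull", (21.4562, 1.0189))
    med = 21.4562 * math.log(2) ** (1 / 1.0189)
    assert float(d.quantile(0.5)) == pytest.approx(med, rel=1e-10)
    assert med == pytest.approx(14.974, abs=1e-3)


def test_loglogistic_median_is_scale():
    d = ParametricSurvival("loglogistic", (8.0441, 1.9689))
    assert float(d.quantile(0.5)) == pytest.approx(8.0441, rel=1e-12)


def test_gengamma_lognormal_limit():
    """|Q| below the series switch reproduces the lognormal exactly."""
    gg = ParametricSurvival("gengamma", (2.0, 0.8, 1e-7))
    ln = ParametricSurvival("lognormal", (2.0, 0.8))
    t = np.linspace(0.5, 60, 100)
    assert np.allclose(gg.survival(t), ln.survival(t), atol=1e-10)


def test_gengamma_weibull_special_case():
    """Q = 1 collapses the generalized gamma to a Weibull."""
    mu, sigma = math.log(20.0), 1 / 1.2
    gg = ParametricSurvival("gengamma", (mu, sigma, 1.0))
    w = ParametricSurvival("weibull", (20.0, 1.2))
    t = np.linspace(0.5, 80, 100)
    assert np.allclose(gg.survival(t), w.survival(t), atol=1e-10)


@pytest.mark.parametrize("family,params", CASES)
def test_time_unit_conversion_preserves_survival(family, params):
    d = ParametricSurvival(family, params, "months")
    w = d.to_unit("weeks")
    t_months = np.array([1.0, 6.0, 24.0])
    t_weeks = t_months * (365.25 / 12) / 7
    assert np.allclose(d.survival(t_months), w.survival(t_weeks), rtol=1e-12)


@given(
    lam=st.floats(1.0, 100.0),
    k=st.floats(0.3, 4.0),
    p=st.floats(0.01, 0.99),
)
@settings(max_examples=60, deadline=None)
def test_weibull_quantile_roundtrip_property(lam, k, p):
    d = ParametricSurvival("weibull", (lam, k))
    assert float(d.survival(d.quantile(p))) == pytest.approx(1 - p, abs=1e-9)


@pytest.mark.parametrize(
    "family,params",
    [
        ("exponential", (-0.1,)),
        ("weibull", (0.0, 1.0)),
        ("weibull", (1.0,)),
        ("lognormal", (0.0, -1.0)),
        ("gompertz", (0.1, 0.0)),
        ("loglogistic", (-1.0, 2.0)),
        ("gengamma", (0.0, 0.0, 1.0)),
    ],
)
def test_invalid_parameters_rejected_at_construction(family, params):
    with pytest.raises(ValueError):
        ParametricSurvival(family, params)


def test_domain_errors():
    d = ParametricSurvival("exponential", (0.1,))
    with pytest.raises(ValueError):
        d.survival(-1.0)
    with pytest.raises(ValueError):
        d.quantile(0.0)
    with pytest.raises(ValueError):
        d.quantile(1.0)
    with pytest.raises(ValueError):
        ParametricSurvival("gamma", (1.0, 1.0))


def test_sampling_deterministic_and_calibrated():
    d = ParametricSurvival("exponential", (0.1,))
    assert d.sample(1, seed=7)[0] == d.sample(1, seed=7)[0]
    x = d.sample(100_000, seed=3)
    se = 10.0 / math.sqrt(len(x))
    assert abs(x.mean() - 10.0) < 3 * se


def test_weibull_sample_ks_against_analytic_cdf():
    d = ParametricSurvival("weibull", (20.0, 1.3))
    x = d.sample(100_000, seed=5)
    ks = stats.kstest(x, lambda v: 1 - np.asarray(d.survival(v))).statistic
    assert ks < 0.01


# -- beta-PERT ---------------------------------------------------------------


def test_pert_symmetric_unit_case():
    p = pert_from_three_points(0.0, 0.5, 1.0)
    assert p.alpha == pytest.approx(3.0)
    assert p.beta == pytest.approx(3.0)
    assert p.mean == pytest.approx(0.5)


def test_pert_mean_identity_on_cost_triples():
    # a skewed supportive-care triple whose PERT mean equals its mode
    assert pert_from_three_points(1030, 2200, 3370).mean == pytest.approx(2200.0)
    # symmetric triple: mean = mode
    assert pert_from_three_points(708.15, 1371.15, 2034.15).mean == pytest.approx(1371.15)


def test_pert_variance_matches_beta_moments():
    p = pert_from_three_points(10.0, 30.0, 90.0)
    rng = np.random.default_rng(0)
    x = p.rvs(rng, size=200_000)
    assert x.mean() == pytest.approx(p.mean, rel=0.01)
    assert x.var() == pytest.approx(p.var, rel=0.05)


def test_pert_degenerate_is_point_mass():
    p = pert_from_three_points(5.0, 5.0, 5.0)
    assert p.degenerate
    assert np.all(p.rvs(np.random.default_rng(0), size=10) == 5.0)


def test_pert_ordering_violation_rejected():
    with pytest.raises(ValueError):
        pert_from_three_points(3.0, 2.0, 4.0)


# -- PSA samplers ------------------------------------------------------------


def test_beta_psa_sampler_mean_calibration():
    p = UncertainParam("u_pfs", 0.817, 0.6536, 0.9804, "beta", "utility")
    d = psa_dist_from_range(p)
    x = d.rvs(np.random.default_rng(1), size=100_000)
    assert abs(x.mean() - 0.817) / 0.817 < 0.01
    assert np.all((x > 0) & (x < 1))


def test_fixed_param_is_point_mass():
    p = UncertainParam("x", 5.0, 5.0, 5.0, "fixed", "cost")
    d = psa_dist_from_range(p)
    assert np.all(d.rvs(np.random.default_rng(0), size=8) == 5.0)


def test_gamma_psa_sampler_moment_match():
    base = 7460.19
    p = UncertainParam("c", base, 0.7 * base, 1.3 * base, "gamma", "cost")
    d = psa_dist_from_range(p)
    x = d.rvs(np.random.default_rng(2), size=200_000)
    assert np.all(x > 0)
    target_sd = 0.6 * base / (2 * 1.96)
    assert x.std() == pytest.approx(target_sd, rel=0.02)
    assert x.mean() == pytest.approx(base, rel=0.005)


def test_disutility_sampled_on_magnitude_scale():
    p = UncertainParam("dis", -0.073, -0.0584, -0.0876, "beta", "disutility")
    d = psa_dist_from_range(p)
    x = d.rvs(np.random.default_rng(3), size=50_000)
    assert np.all(x < 0)
    assert x.mean() == pytest.approx(-0.073, rel=0.02)


def test_beta_infeasible_sd_is_shrunk_with_warning():
    p = UncertainParam("p", 0.5, -3.0, 4.0, "beta", "probability")
    with pytest.warns(UserWarning, match="shrunk"):
        d = psa_dist_from_range(p)
    x = d.rvs(np.random.default_rng(4), size=10_000)
    assert np.all((x >= 0) & (x <= 1))
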