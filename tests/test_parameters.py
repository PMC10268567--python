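"""Input containers, probability conversions and distribution building."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from stricture_econ import (
    DAYS_PER_MONTH,
    ParameterValidationError,
    build_distribution,
    episode_cost,
    exit_probability_to_median,
    load_parameters,
    median_to_exit_probability,
    probability_to_rate,
    rate_to_probability,
    weighted_adverse_event_cost,
)
from stricture_econ.parameters import build_default_distributions


# ---------------------------------------------------------------------------
# cumulative risk <-> per-cycle probability
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "risk, months, expected, places",
    [
        (0.881, 12, 0.163, 3),  # endoscopic arm, 12-month recurrence
        (0.269, 12, 0.026, 3),  # Optilume arm
        (0.0, 24, 0.0, 12),
        (0.42, 1, 0.42, 12),  # identity at one cycle
    ],
)
def test_rate_to_probability_examples(risk, months, expected, places):
    assert rate_to_probability(risk, months) == pytest.approx(
        expected, abs=0.5 * 10**-places
    )


@pytest.mark.parametrize("bad_risk", [1.0, -0.1, 1.5])
def test_rate_to_probability_rejects_out_of_range(bad_risk):
    with pytest.raises(ParameterValidationError):
        rate_to_probability(bad_risk, 12)


def test_probability_to_rate_checks_urethroplasty_input():
    # 0.9%/month over the 24-month trial window implies a ~19.5% risk
    assert probability_to_rate(0.009, 24) == pytest.approx(0.195, abs=5e-4)
    assert probability_to_rate(0.0, 12) == 0.0


@given(
    risk=st.floats(0.0, 0.999),
    months=st.integers(1, 120),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_conversion_round_trip(risk, months):
    p = rate_to_probability(risk, months)
    assert 0.0 <= p <= risk + 1e-12
    assert probability_to_rate(p, months) == pytest.approx(risk, abs=1e-12)


def test_rate_to_probability_monotone_grid():
    risks = np.linspace(0.01, 0.95, 20)
    horizons = [1, 3, 12, 24, 60]
    for months in horizons:
        vals = [rate_to_probability(r, months) for r in risks]
        assert np.all(np.diff(vals) > 0), "increasing in cumulative risk"
    for r in risks:
        vals = [rate_to_probability(r, m) for m in horizons]
        assert np.all(np.diff(vals) < 0), "decreasing in horizon"


# ---------------------------------------------------------------------------
# median waiting time -> exit probability
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "median_days, expected",
    [(DAYS_PER_MONTH, 0.5), (47.5, 0.359), (90, 0.209)],
)
def test_median_to_exit_probability_examples(median_days, expected):
    assert median_to_exit_probability(median_days) == pytest.approx(
        expected, abs=5e-4
    )


@pytest.mark.parametrize("median_days", [5.0, 30.4375, 47.5, 90.0, 400.0])
def test_median_exit_probability_matches_root_finding(median_days):
    # independent oracle: solve (1-p)^(median/month) = 0.5 numerically
    f = lambda p: (1 - p) ** (median_days / DAYS_PER_MONTH) - 0.5
    oracle = brentq(f, 1e-12, 1 - 1e-12, xtol=1e-15)
    p = median_to_exit_probability(median_days)
    assert p == pytest.approx(oracle, abs=1e-9)
    assert exit_probability_to_median(p) == pytest.approx(median_days, rel=1e-12)


def test_median_to_exit_probability_rejects_nonpositive():
    with pytest.raises(ParameterValidationError):
        median_to_exit_probability(0.0)
    with pytest.raises(ParameterValidationError):
        median_to_exit_probability(47.5, days_per_month=-1)


# ---------------------------------------------------------------------------
# episode and adverse-event costs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "base, ae, printed",
    [(1986, 15.16, 2001), (1196, 63.40, 1259), (4761, 17.46, 4779)],
)
def test_episode_cost_matches_printed_initial_rows(base, ae, printed):
    assert episode_cost(base, ae) == pytest.approx(printed, abs=1.0)


def test_episode_cost_validates_components():
    assert episode_cost(0, 0) == 0
    assert episode_cost(100, 10, extras=[20.36]) == pytest.approx(130.36)
    with pytest.raises(ParameterValidationError):
        episode_cost(100, -1)


def test_weighted_adverse_event_cost():
    assert weighted_adverse_event_cost([]) == 0
    assert weighted_adverse_event_cost([(0.1, 100)]) == pytest.approx(10.0)
    assert weighted_adverse_event_cost(
        [(0.05, 200), (0.02, 317)]
    ) == pytest.approx(16.34)
    with pytest.raises(ParameterValidationError):
        weighted_adverse_event_cost([(1.2, 50)])


# ---------------------------------------------------------------------------
# sampling distributions
# ---------------------------------------------------------------------------

def test_build_distribution_gamma_for_costs():
    spec = build_distribution("cost_endo", 1196, "cost")
    assert spec.family == "gamma"
    assert spec.se == pytest.approx(299.0)
    k, theta = spec.shape
    assert k * theta == pytest.approx(1196, abs=1e-9)  # mean
    assert math.sqrt(k) * theta == pytest.approx(299, abs=1e-9)  # sd


def test_build_distribution_beta_moment_match():
    spec = build_distribution("p", 0.5, "probability")
    assert spec.family == "beta"
    assert spec.shape == pytest.approx((7.5, 7.5), abs=1e-9)


def test_build_distribution_degenerate_and_errors():
    assert build_distribution("zero", 0, "cost").family == "fixed"
    with pytest.raises(ParameterValidationError):
        build_distribution("p", 1.5, "probability")


@pytest.mark.parametrize(
    "mean, kind", [(0.163, "probability"), (1196.0, "cost")]
)
def test_distribution_sampling_recovers_moments(mean, kind):
    spec = build_distribution("x", mean, kind)
    rng = np.random.default_rng(20_240_101)
    n = 1_000_000
    draws = spec.sample(rng, n)
    mc_se_mean = spec.se / math.sqrt(n)
    assert draws.mean() == pytest.approx(mean, abs=3 * mc_se_mean)
    # sd of the sample sd is ~ se / sqrt(2n) for near-normal shapes; use a
    # generous kurtosis allowance
    assert draws.std() == pytest.approx(spec.se, rel=0.01)


def test_distribution_ci_overrides_default_se():
    spec = build_distribution("p", 0.5, "probability", ci=(0.4, 0.6))
    assert spec.se == pytest.approx(0.1 / 1.959963984540054, rel=1e-9)


# ---------------------------------------------------------------------------
# config loading and validation
# ---------------------------------------------------------------------------

def test_packaged_defaults_reproduce_model_inputs(params):
    assert params.transitions.monthly_p_recur_endo == pytest.approx(0.163)
    assert params.transitions.monthly_p_recur_optilume == pytest.approx(0.026)
    assert params.costs.cost_optilume_incl_device == pytest.approx(1986)
    assert params.engine.horizon_cycles == 60
    assert params.engine.annual_discount_rate_costs == pytest.approx(0.035)
    names = {s.parameter_name for s in params.distributions}
    assert "monthly_p_recur_endo" in names
    assert "annual_discount_rate_costs" in names  # held fixed


def test_load_parameters_names_every_bad_split(params):
    cfg = {
        s.name: getattr(section, s.name)
        for section in (params.transitions, params.costs, params.engine)
        for s in section.__dataclass_fields__.values()
    }
    cfg["split_urethroplasty_after_endo_or_optilume"] = 0.7
    cfg["split_repeat_endo_or_optilume"] = 0.4
    with pytest.raises(ParameterValidationError) as exc:
        load_parameters(cfg)
    msg = str(exc.value)
    assert "split_urethroplasty_after_endo_or_optilume" in msg
    assert "split_repeat_endo_or_optilume" in msg


def test_load_parameters_empty_config_lists_required_fields():
    with pytest.raises(ParameterValidationError) as exc:
        load_parameters({})
    msg = str(exc.value)
    assert "monthly_p_recur_endo" in msg
    assert "cost_endo_procedure" in msg
    assert "monthly_cost_recurrence" in msg


def test_load_parameters_rejects_unknown_keys(params):
    with pytest.raises(ParameterValidationError) as exc:
        load_parameters({"monthly_p_recur_endoo": 0.1})
    assert "unknown config key" in str(exc.value)


def test_se_scale_shrinks_distributions(params):
    narrow = build_default_distributions(params, se_scale=0.1)
    wide = {s.parameter_name: s for s in params.distributions}
    for spec in narrow:
        if spec.family == "fixed":
            continue
        assert spec.se == pytest.approx(wide[spec.parameter_name].se * 0.1, rel=1e-9)
        assert spec.mean == pytest.approx(wide[spec.parameter_name].mean, rel=1e-12)
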