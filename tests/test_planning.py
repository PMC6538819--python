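"""Evidence classification, fixed-N summaries, and critical sample sizes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bfda import (
    DecisionBoundaries,
    DesignPrior,
    EvidenceScale,
    InsufficientGridError,
    PlanningConfig,
    SimulationConfig,
    classify_bf,
    critical_n,
    prob_exceed_boundary,
    run_fixed_n,
    summarize_fixed_n,
    summarize_sequential,
)
from bfda.fixed_n import FixedNResult
from bfda.sequential import SequentialConfig, SequentialResult


# -- evidence scale --------------------------------------------------------


@pytest.mark.parametrize(
    "bf,label",
    [
        (6.0, "Moderate evidence for H1"),
        (1.0, "No evidence"),
        (1 / 45, "Very strong evidence for H0"),
        (150.0, "Extreme evidence for H1"),
        (0.005, "Extreme evidence for H0"),
        (2.0, "Anecdotal evidence for H1"),
        (0.5, "Anecdotal evidence for H0"),
        # threshold values go to the stronger-evidence side
        (3.0, "Moderate evidence for H1"),
        (1 / 3, "Moderate evidence for H0"),
        (10.0, "Strong evidence for H1"),
    ],
)
def test_classification_table(bf, label):
    assert classify_bf(bf) == label


def test_classification_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_bf(0.0)
    with pytest.raises(ValueError):
        classify_bf(-2.0)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(log_bf=st.floats(-12, 12))
def test_classification_partitions_positive_reals(log_bf):
    """Every positive BF maps to exactly one category."""
    label = classify_bf(float(np.exp(log_bf)))
    scale = EvidenceScale()
    assert label in set(scale.labels) | {scale.no_evidence_label}


def test_invalid_scale_rejected():
    with pytest.raises(ValueError):
        EvidenceScale(thresholds=(1, 3, 2), labels=("a", "b", "c", "d"))


# -- fixed-N summaries -----------------------------------------------------


def _result_from_logbfs(log_bfs, default_prior):
    m = len(log_bfs)
    return FixedNResult(
        np.asarray(log_bfs, float),
        np.zeros(m),
        np.zeros(m),
        DesignPrior.point(0.0),
        default_prior,
        SimulationConfig(m=m, seed=0, n_per_group=20),
    )


def test_summary_of_constant_bfs(default_prior):
    res = _result_from_logbfs(np.full(50, np.log(2.0)), default_prior)
    s = summarize_fixed_n(res, DecisionBoundaries.symmetric(10))
    assert s.rate_inconclusive == 1.0
    assert s.median_bf == pytest.approx(2.0)
    assert s.expected_bf == pytest.approx(2.0)


def test_outcome_rates_sum_to_one_exactly(default_prior):
    rng = np.random.default_rng(1)
    res = _result_from_logbfs(rng.normal(0, 3, size=999), default_prior)
    s = summarize_fixed_n(res, DecisionBoundaries.symmetric(3))
    assert s.rate_upper + s.rate_lower + s.rate_inconclusive == 1.0
    assert s.rate_upper > 0 and s.rate_lower > 0


def test_quantiles_match_linear_interpolation(default_prior):
    rng = np.random.default_rng(2)
    lbs = rng.normal(size=101)
    s = summarize_fixed_n(
        _result_from_logbfs(lbs, default_prior), DecisionBoundaries.symmetric(3)
    )
    assert s.quantiles[0.25] == pytest.approx(np.quantile(np.exp(lbs), 0.25))


def test_small_n_under_null_is_mostly_inconclusive(default_prior):
    """n=10 per group cannot produce strong evidence either way."""
    res = run_fixed_n(
        DesignPrior.point(0.0),
        default_prior,
        SimulationConfig(m=2000, seed=31, n_per_group=10),
    )
    s = summarize_fixed_n(res, DecisionBoundaries.symmetric(10))
    assert s.rate_inconclusive > 0.99


# -- boundary-crossing probabilities and critical N ------------------------


def test_prob_exceed_matches_monte_carlo(default_prior):
    """Semi-analytic tail probability vs simulation rate (delta=0, lower 1/10)."""
    res = run_fixed_n(
        DesignPrior.point(0.0),
        default_prior,
        SimulationConfig(m=20_000, seed=41, n_per_group=20),
    )
    rate = float(np.mean(res.bfs < 1 / 10))
    p = prob_exceed_boundary(0.0, default_prior, 20, 1 / 10, "lower")
    se = np.sqrt(p * (1 - p) / 20_000)
    assert abs(rate - p) < 3 * se


def test_prob_exceed_matches_monte_carlo_upper(informed_prior):
    res = run_fixed_n(
        DesignPrior.point(0.5),
        informed_prior,
        SimulationConfig(m=20_000, seed=43, n_per_group=40),
    )
    rate = float(np.mean(res.bfs > 6.0))
    p = prob_exceed_boundary(0.5, informed_prior, 40, 6.0, "upper")
    se = np.sqrt(p * (1 - p) / 20_000)
    assert abs(rate - p) < 3 * se


def test_prob_exceed_unattainable_boundary(default_prior):
    # at n=3 a BF below 0.2 is impossible under a directional prior
    assert prob_exceed_boundary(0.0, default_prior, 3, 0.2, "lower") == 0.0


def test_prob_exceed_nondecreasing_in_n(default_prior):
    probs = [
        prob_exceed_boundary(0.35, default_prior, n, 5.0, "upper")
        for n in (50, 100, 200, 400)
    ]
    assert np.all(np.diff(probs) > 0)


def test_critical_n_nonincreasing_in_delta(default_prior):
    """Larger true effects need smaller samples at a fixed boundary."""
    plan = PlanningConfig(boundary=5.0, n_grid=range(2, 1201))
    ns = [
        critical_n(d, default_prior, plan) for d in (0.2, 0.35, 0.5, 0.8)
    ]
    assert np.all(np.diff(ns) < 0)


def test_critical_n_mc_agrees_with_analytic(default_prior):
    plan = PlanningConfig(boundary=5.0, n_grid=range(2, 101))
    analytic = critical_n(0.8, default_prior, plan)
    mc = critical_n(0.8, default_prior, plan, method="mc", m_mc=2000, seed=4)
    assert abs(mc - analytic) <= 2 * plan.mc_step


def test_critical_n_insufficient_grid(default_prior):
    plan = PlanningConfig(boundary=5.0, n_grid=range(2, 30))
    with pytest.raises(InsufficientGridError, match="29"):
        critical_n(0.2, default_prior, plan)


# -- sequential summaries --------------------------------------------------


def _seq_result(final_ns, sides, prior):
    m = len(final_ns)
    return SequentialResult(
        np.asarray(final_ns, int),
        np.asarray(sides, dtype=object),
        np.zeros(m),
        DesignPrior.point(0.2),
        prior,
        DecisionBoundaries.symmetric(6),
        SequentialConfig(m=m, seed=0, n_max=5000),
    )


def test_sequential_summary_degenerate(default_prior):
    res = _seq_result([10] * 8, ["upper"] * 8, default_prior)
    s = summarize_sequential(res)
    assert all(v == 10 for v in s["quantiles"].values())
    assert s["counts"]["upper"] == 8


def test_sequential_quantiles_nondecreasing(default_prior):
    rng = np.random.default_rng(3)
    fn = rng.integers(10, 400, size=500)
    res = _seq_result(fn, ["upper"] * 500, default_prior)
    s = summarize_sequential(res)
    levels = sorted(s["quantiles"])
    vals = [s["quantiles"][q] for q in levels]
    assert np.all(np.diff(vals) >= 0)


def test_sequential_summary_empty_raises(default_prior):
    with pytest.raises(ValueError):
        summarize_sequential(_seq_result([], [], default_prior))
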