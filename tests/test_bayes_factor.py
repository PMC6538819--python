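"""Bayes factor computation: likelihoods, quadrature, critical values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from bfda import (
    PriorSpec,
    SufficientStats,
    bf10,
    critical_t,
    critical_t_profile,
    get_prior,
    likelihood_h0,
    likelihood_h1_given_delta,
    log_bf10,
)
from bfda.noncentral import log_noncentral_t_pdf
from bfda.priors import prior_density


# -- likelihoods -----------------------------------------------------------


def test_likelihood_h0_closed_form_at_zero():
    # central-t density at 0: Gamma((df+1)/2) / (sqrt(df*pi) * Gamma(df/2))
    s = SufficientStats(0.0, 20, 20)
    df = 38
    expect = math.gamma((df + 1) / 2) / (
        math.sqrt(df * math.pi) * math.gamma(df / 2)
    )
    assert likelihood_h0(s) == pytest.approx(expect, rel=1e-12)


def test_likelihood_h0_textbook_formula_and_symmetry():
    df = 38
    t = 2.0
    expect = (
        math.gamma((df + 1) / 2)
        / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        * (1 + t * t / df) ** (-(df + 1) / 2)
    )
    assert likelihood_h0(SufficientStats(t, 20, 20)) == pytest.approx(expect, rel=1e-12)
    assert likelihood_h0(SufficientStats(-t, 20, 20)) == pytest.approx(
        likelihood_h0(SufficientStats(t, 20, 20))
    )


def test_likelihood_h1_at_zero_delta_equals_h0():
    s = SufficientStats(1.7, 14, 14)
    assert likelihood_h1_given_delta(s, 0.0) == pytest.approx(
        likelihood_h0(s), rel=1e-10
    )


def test_likelihood_h1_matches_simulation_oracle():
    """Density at t=2 under delta=0.5, n=20 vs 1e6 raw two-group studies."""
    rng = np.random.default_rng(123)
    m, n, delta = 1_000_000, 20, 0.5
    g1 = delta + rng.standard_normal((m, n))
    g2 = rng.standard_normal((m, n))
    sp2 = (g1.var(axis=1, ddof=1) + g2.var(axis=1, ddof=1)) / 2
    ts = (g1.mean(axis=1) - g2.mean(axis=1)) / np.sqrt(sp2 * 2 / n)
    lo, hi = 1.9, 2.1
    emp = np.mean((ts > lo) & (ts < hi))
    s = SufficientStats(2.0, n, n)
    model, _ = integrate.quad(
        lambda t: likelihood_h1_given_delta(SufficientStats(t, n, n), delta), lo, hi
    )
    se = math.sqrt(emp * (1 - emp) / m)
    assert abs(emp - model) < 4 * se


def test_likelihood_h1_normalizes_over_t():
    s_maker = lambda t: SufficientStats(t, 20, 20)
    total, _ = integrate.quad(
        lambda t: likelihood_h1_given_delta(s_maker(t), 0.5), -np.inf, np.inf,
        limit=200,
    )
    assert total == pytest.approx(1.0, abs=1e-5)


# -- Bayes factors ---------------------------------------------------------


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    t=st.floats(-10, 10),
    n1=st.integers(2, 200),
    n2=st.integers(2, 200),
)
def test_point_null_alternative_gives_unit_bf(t, n1, n2):
    """A point prior at delta=0 makes H1 identical to H0, so BF10 = 1."""
    res = bf10(SufficientStats(t, n1, n2), PriorSpec("point", 0.0))
    assert res.bf10 == pytest.approx(1.0, rel=1e-10)


def test_point_prior_closed_form_density_ratio():
    s = SufficientStats(2.0, 20, 20)
    res = bf10(s, PriorSpec("point", 0.5))
    ncp = 0.5 * math.sqrt(10)
    expect = float(
        np.exp(log_noncentral_t_pdf(2.0, 38.0, ncp)) / stats.t.pdf(2.0, 38)
    )
    assert res.bf10 == pytest.approx(expect, rel=1e-9)
    assert res.bf10 == pytest.approx(math.exp(res.log_bf10))


def test_default_prior_bf_matches_prior_sampling_monte_carlo():
    """Quadrature equals a brute-force mean over prior draws (t=0, n=20)."""
    rng = np.random.default_rng(99)
    deltas = np.abs(stats.cauchy(0, math.sqrt(2) / 2).rvs(1_000_000, random_state=rng))
    ratios = np.exp(
        log_noncentral_t_pdf(0.0, 38.0, deltas * math.sqrt(10))
        - stats.t.logpdf(0.0, 38)
    )
    mc = ratios.mean()
    se = ratios.std(ddof=1) / math.sqrt(ratios.size)
    res = bf10(SufficientStats(0.0, 20, 20), get_prior("default"))
    assert abs(res.bf10 - mc) < 3 * se


@pytest.mark.parametrize("prior_name", ["default", "informed"])
def test_quadrature_matches_adaptive_oracle(prior_name):
    """Panel rule vs adaptive Gauss-Kronrod on a (t, n) grid."""
    prior = get_prior(prior_name)
    base = prior.base_dist()
    mass = 1.0 - base.cdf(0.0)
    for t in (-3.0, -1.0, 0.0, 0.5, 2.0, 5.0, 10.0):
        for n in (5, 20, 200):
            df = 2 * n - 2
            a = math.sqrt(n / 2)
            num, _ = integrate.quad(
                lambda d: math.exp(log_noncentral_t_pdf(t, df, d * a))
                * base.pdf(d)
                / mass,
                0,
                np.inf,
                epsrel=1e-11,
                epsabs=1e-300,
                limit=400,
            )
            expect = num / stats.t.pdf(t, df)
            got = bf10(SufficientStats(t, n, n), prior).bf10
            assert got == pytest.approx(expect, rel=1e-7), (t, n)


@pytest.mark.parametrize("prior_name", ["default", "informed"])
@pytest.mark.parametrize("n", [5, 20, 100])
def test_bf_monotone_in_t(prior_name, n):
    grid = np.linspace(-50, 50, 1000)
    lb = log_bf10(grid, n, n, get_prior(prior_name))
    assert np.all(np.diff(lb) > 0)


def test_evidence_grows_with_n_under_true_effect():
    """At the expected t for delta=0.5, log BF increases with n; under
    delta=0 (t at its median, 0) it decreases."""
    prior = get_prior("default")
    lbs = []
    lbs0 = []
    for n in (10, 50, 100, 500):
        df = 2 * n - 2
        ncp = 0.5 * math.sqrt(n / 2)
        mean_t = ncp * math.sqrt(df / 2) * math.exp(
            math.lgamma((df - 1) / 2) - math.lgamma(df / 2)
        )
        lbs.append(float(np.asarray(log_bf10(mean_t, n, n, prior))))
        lbs0.append(float(np.asarray(log_bf10(0.0, n, n, prior))))
    assert np.all(np.diff(lbs) > 0)
    assert np.all(np.diff(lbs0) < 0)


@pytest.mark.parametrize("prior_name", ["default", "informed"])
def test_batch_spline_path_matches_direct_quadrature(prior_name):
    """The large-batch spline evaluation agrees with the panel rule to 1e-6."""
    from bfda.bayes_factor import log_bf10_batch

    rng = np.random.default_rng(4)
    ts = np.concatenate([rng.standard_t(18, 2000) * 2, [-45.0, 0.0, 45.0, 60.0]])
    prior = get_prior(prior_name)
    fast = log_bf10_batch(ts, 10, prior)
    exact = np.asarray(log_bf10(ts[::5], 10, 10, prior))
    assert np.max(np.abs(fast[::5] - exact)) < 1e-6


# -- critical t ------------------------------------------------------------


def test_critical_t_round_trip(default_prior):
    target = bf10(SufficientStats(1.7, 20, 20), default_prior).bf10
    assert critical_t(20, 20, default_prior, target) == pytest.approx(1.7, abs=1e-7)


def test_critical_t_brackets_target(informed_prior):
    t_star = critical_t(20, 20, informed_prior, 0.1)
    below = bf10(SufficientStats(t_star - 0.01, 20, 20), informed_prior).bf10
    above = bf10(SufficientStats(t_star + 0.01, 20, 20), informed_prior).bf10
    assert below < 0.1 < above


def test_critical_t_unattainable_target_raises(default_prior):
    with pytest.raises(ValueError, match="attainable"):
        critical_t(3, 3, default_prior, 1e-12)


def test_critical_t_profile_matches_scalar(default_prior):
    ns = np.array([10, 17, 40, 80, 160])
    prof = critical_t_profile(ns, default_prior, 6.0)
    for n, tv in zip(ns, prof):
        assert tv == pytest.approx(
            critical_t(int(n), int(n), default_prior, 6.0), abs=1e-7
        )
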