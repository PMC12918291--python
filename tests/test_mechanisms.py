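"""Laplace mechanism: sampler correctness, clamping, composition, suppression.

The independent oracle for the sampler is scipy's Laplace quantile function:
our inverse-CDF draw from a uniform u on (-1/2, 1/2) must equal
``scipy.stats.laplace.ppf(u + 1/2, scale=b)`` exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from dpqc import (
    CheckResult,
    DPParams,
    laplace_sample,
    noisy_count,
    noisy_percentage,
    split_stratum_budget,
    stratified_noisy_rates,
    suppress_low_count,
)


def make_result(c: int, n: int, check_id: str = "completeness-1",
                stratum: str | None = None) -> CheckResult:
    return CheckResult(check_id, c, n, round(100 * c / n, 2), stratum)


# --- sampler ---------------------------------------------------------------


def test_sampler_matches_scipy_quantile_oracle():
    for seed in range(20):
        u = np.random.default_rng(seed).uniform(-0.5, 0.5)
        draw = laplace_sample(3.7, np.random.default_rng(seed))
        assert draw == pytest.approx(stats.laplace.ppf(u + 0.5, scale=3.7),
                                     rel=1e-12)


def test_sampler_moments():
    rng = np.random.default_rng(2024)
    b = 2.5
    draws = np.array([laplace_sample(b, rng) for _ in range(100_000)])
    se_mean = math.sqrt(2 * b * b / len(draws))
    assert abs(draws.mean()) < 3 * se_mean
    assert draws.var() == pytest.approx(2 * b * b, rel=0.05)


def test_sampler_determinism_and_divergence():
    a = laplace_sample(1.0, np.random.default_rng(5))
    b = laplace_sample(1.0, np.random.default_rng(5))
    c = laplace_sample(1.0, np.random.default_rng(6))
    assert a == b and a != c


def test_nonpositive_scale_rejected():
    with pytest.raises(ValueError):
        laplace_sample(0.0, np.random.default_rng(0))


# --- noisy count ------------------------------------------------------------


def test_noisy_count_matches_independent_recomputation():
    params = DPParams(epsilon=0.2, sensitivity=1)
    got = noisy_count(37, params, np.random.default_rng(123))
    u = np.random.default_rng(123).uniform(-0.5, 0.5)
    expected = 37 + stats.laplace.ppf(u + 0.5, scale=1 / 0.2)
    assert got.dp_value == pytest.approx(max(0.0, expected), rel=1e-12)
    assert got.epsilon_spent == 0.2
    assert got.noise_scale == 5.0


def test_noisy_count_huge_epsilon_limit():
    got = noisy_count(100, DPParams(epsilon=1e6), np.random.default_rng(1))
    assert abs(got.dp_value - 100) < 1e-3


def test_noisy_count_clamped_at_zero():
    # find a seed whose draw is negative, then check the clamp
    for seed in range(50):
        rng = np.random.default_rng(seed)
        if laplace_sample(10.0, rng) < -0.5:
            got = noisy_count(0, DPParams(epsilon=0.1), np.random.default_rng(seed))
            assert got.dp_value == 0.0
            return
    pytest.fail("no negative draw found in 50 seeds")


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        DPParams(epsilon=0.0)
    with pytest.raises(ValueError):
        DPParams(epsilon=1.0, delta=1e-5)  # only pure epsilon-DP


# --- noisy percentage -------------------------------------------------------


def test_noisy_percentage_matches_oracle_recomputation():
    got = noisy_percentage(make_result(37, 1000), DPParams(epsilon=0.2),
                           np.random.default_rng(7))
    rng = np.random.default_rng(7)
    b = 1 / (0.2 / 2)
    u1, u2 = rng.uniform(-0.5, 0.5), rng.uniform(-0.5, 0.5)
    c = 37 + stats.laplace.ppf(u1 + 0.5, scale=b)
    n = max(1.0, 1000 + stats.laplace.ppf(u2 + 0.5, scale=b))
    c = min(max(0.0, c), n)
    assert got.dp_percent == round(100 * c / n, 2)
    assert got.epsilon_spent == 0.2


def test_noisy_percentage_huge_epsilon_returns_raw():
    got = noisy_percentage(make_result(37, 1000), DPParams(epsilon=1e9),
                           np.random.default_rng(0))
    assert got.dp_percent == 3.70


def test_noisy_percentage_always_in_range():
    rng = np.random.default_rng(99)
    for _ in range(500):
        got = noisy_percentage(make_result(1, 5), DPParams(epsilon=0.05), rng)
        assert 0.0 <= got.dp_percent <= 100.0
        assert 0.0 <= got.noisy_numerator <= got.noisy_denominator


def test_zero_denominator_is_an_error():
    with pytest.raises(ValueError, match="population"):
        noisy_percentage(CheckResult("x", 0, 0, 0.0), DPParams(epsilon=1),
                         np.random.default_rng(0))


def test_numerator_only_mode_keeps_denominator_exact():
    got = noisy_percentage(make_result(500, 1000), DPParams(epsilon=1.0),
                           np.random.default_rng(3), noise_denominator=False)
    assert got.noisy_denominator == 1000.0


# --- stratification ---------------------------------------------------------


def test_stratum_budget_split():
    assert split_stratum_budget(0.3, 2) == [0.15, 0.15]
    assert split_stratum_budget(0.7, 1) == [0.7]


@pytest.mark.parametrize("eps,k", [(0.3, 2), (1.0, 3), (2.0, 7), (0.17, 5)])
def test_stratum_shares_conserve_total(eps, k):
    shares = split_stratum_budget(eps, k)
    assert len(shares) == k
    assert math.fsum(shares) == pytest.approx(eps, abs=1e-15)


def test_split_k_zero_rejected():
    with pytest.raises(ValueError):
        split_stratum_budget(1.0, 0)


def test_single_stratum_reduces_to_plain_percentage():
    res = make_result(40, 200, stratum="female")
    a = stratified_noisy_rates([res], 0.3, 1, np.random.default_rng(8))
    b = noisy_percentage(res, DPParams(0.3), np.random.default_rng(8))
    assert a[0].dp_percent == b.dp_percent


def test_stratified_total_budget_is_conserved():
    results = [make_result(40, 200, stratum="female"),
               make_result(50, 210, stratum="male")]
    noisy = stratified_noisy_rates(results, 0.3, 1, np.random.default_rng(8))
    assert math.fsum(r.epsilon_spent for r in noisy) == pytest.approx(0.3)


def test_empty_strata_rejected():
    with pytest.raises(ValueError):
        stratified_noisy_rates([], 0.3, 1, np.random.default_rng(0))


def test_stratified_noise_variance_matches_printed_law():
    """Per-stratum noise variance ≈ 2(Δf·k/ε_total)² (numerator-only noising)."""
    eps_total, k, c, n = 0.5, 2, 5000, 10000
    results = [make_result(c, n, stratum=s) for s in ("female", "male")]
    rng = np.random.default_rng(31)
    noise = [
        stratified_noisy_rates(results, eps_total, 1, rng,
                               noise_denominator=False)[0].noisy_numerator - c
        for _ in range(10_000)
    ]
    expected_var = 2 * (1 * k / eps_total) ** 2
    assert np.var(noise) == pytest.approx(expected_var, rel=0.1)


def test_variance_grows_quadratically_in_k():
    rng = np.random.default_rng(17)
    eps_total, c, n = 1.0, 5000, 10000

    def empirical_var(k: int) -> float:
        results = [make_result(c, n, stratum=str(i)) for i in range(k)]
        return float(np.var([
            stratified_noisy_rates(results, eps_total, 1, rng,
                                   noise_denominator=False)[0].noisy_numerator - c
            for _ in range(8000)
        ]))

    ratio = empirical_var(3) / empirical_var(1)
    assert ratio == pytest.approx(9.0, rel=0.2)


# --- suppression ------------------------------------------------------------


def test_low_count_suppression():
    noisy = noisy_percentage(make_result(3, 100), DPParams(epsilon=0.2),
                             np.random.default_rng(0))
    out = suppress_low_count(noisy, raw_numerator=3, threshold=10)
    assert out.dp_percent == 0.0 and out.suppressed


def test_suppression_disabled_and_boundary():
    noisy = noisy_percentage(make_result(10, 100), DPParams(epsilon=0.2),
                             np.random.default_rng(0))
    assert suppress_low_count(noisy, 10, 0) is noisy       # disabled
    assert suppress_low_count(noisy, 10, 10) is noisy      # strict less-than
    assert suppress_low_count(noisy, 9, 10).suppressed


# --- empirical DP -----------------------------------------------------------


def test_neighbouring_counts_histogram_ratio_bounded_by_exp_epsilon():
    """Small-grid empirical check of the ε-DP guarantee on noisy counts."""
    eps, n_draws = 1.0, 60_000
    rng = np.random.default_rng(404)
    params = DPParams(epsilon=eps)
    a = np.array([noisy_count(5, params, rng).dp_value for _ in range(n_draws)])
    b = np.array([noisy_count(6, params, rng).dp_value for _ in range(n_draws)])
    bins = np.arange(0.0, 12.0, 1.0)
    pa, _ = np.histogram(a, bins=bins)
    pb, _ = np.histogram(b, bins=bins)
    mask = (pa > 500) & (pb > 500)  # ignore sparsely populated bins
    ratios = pa[mask] / pb[mask]
    bound = math.exp(eps) * 1.15  # sampling slack
    assert np.all(ratios < bound)
    assert np.all(1.0 / ratios < bound)
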