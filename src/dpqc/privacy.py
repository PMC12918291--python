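"""Closed-form utility and disclosure-risk forecasting for Laplace releases.

Utility side: for a ratio ``q = k/n`` released by adding ``Lap(1/ε)`` noise
to the numerator, ``SD[q̃] = √2/(nε)`` — at n = 10 and ε = 1 that is ≈ 0.141,
large enough to make the released metric useless, which motivates the
minimum-cohort release gate (default n ≥ 30).  Stratifying a check over k
strata at fixed total budget inflates per-stratum noise variance to
``2(Δf·k/ε_total)²``, quadratic in k.

Risk side: an adversary holding a prior inclusion certainty ``P_in`` about a
specific record can update it after observing one ε-DP release by at most
the likelihood-ratio bound e^ε (Bayes' rule):

    P_out = e^ε·P_in / (e^ε·P_in + 1 − P_in)

so e.g. a 0.1 prior becomes ≈ 0.45 after a single ε = 2 query.  The band
between the e^ε and e^(−ε) updates, over a grid of priors, visualises how
much certainty one release can leak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

DEFAULT_MIN_N = 30


@dataclass(frozen=True)
class CertaintyPoint:
    p_in: float
    epsilon: float
    p_out: float


@dataclass(frozen=True)
class UtilityForecast:
    n: int
    epsilon: float
    sd_ratio: float
    ok_to_release: bool
    min_n: int
    advisory: str = ""


def ratio_sd(n: int, epsilon: float) -> float:
    """Standard deviation √2/(n·ε) of a numerator-noised ratio release."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return math.sqrt(2.0) / (n * epsilon)


def stratification_variance(sensitivity: int, k: int, epsilon_total: float) -> float:
    """Per-stratum Laplace noise variance 2·(Δf·k/ε_total)² under a k-way split."""
    if sensitivity < 1 or k < 1:
        raise ValueError("sensitivity and k must be >= 1")
    if epsilon_total <= 0:
        raise ValueError("epsilon_total must be positive")
    return 2.0 * (sensitivity * k / epsilon_total) ** 2


def posterior_certainty(p_in: float, epsilon: float) -> float:
    """Worst-case posterior inclusion certainty after one ε-DP release."""
    if not 0.0 <= p_in <= 1.0:
        raise ValueError("p_in must be a probability")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if p_in in (0.0, 1.0):
        return p_in
    ratio = math.exp(epsilon)
    return ratio * p_in / (ratio * p_in + (1.0 - p_in))


def certainty_band(p_in_grid: list[float],
                   epsilon: float) -> list[tuple[CertaintyPoint, CertaintyPoint]]:
    """Upper/lower posterior-certainty band over a grid of priors.

    The upper bound uses likelihood ratio e^ε, the lower e^(−ε); at ε = 0
    both collapse onto the diagonal.
    """
    band = []
    for p in p_in_grid:
        upper = posterior_certainty(p, epsilon)
        if p in (0.0, 1.0):
            lower = p
        else:
            r = math.exp(-epsilon)
            lower = r * p / (r * p + (1.0 - p))
        band.append((
            CertaintyPoint(p, epsilon, upper),
            CertaintyPoint(p, epsilon, lower),
        ))
    return band


def release_gate(n: int, min_n: int = DEFAULT_MIN_N) -> tuple[bool, str]:
    """Decide (inclusively) whether a cohort is large enough to release.

    Below the gate, noise swamps the signal; the advisory suggests the
    standard remedies rather than weakening the privacy parameters.
    """
    if n >= min_n:
        return True, ""
    return False, (
        f"cohort size {n} is below the minimum of {min_n}; released metrics "
        "would be dominated by noise. Consider aggregating results across "
        "sites or reporting periods to reach the minimum before releasing."
    )


def forecast(n: int, epsilon: float, min_n: int = DEFAULT_MIN_N) -> UtilityForecast:
    """Utility forecast for releasing one ratio from a cohort of size n."""
    ok, advisory = release_gate(n, min_n)
    return UtilityForecast(
        n=n,
        epsilon=epsilon,
        sd_ratio=ratio_sd(n, epsilon),
        ok_to_release=ok,
        min_n=min_n,
        advisory=advisory,
    )


def plot_certainty_band(epsilons: list[float], path: str,
                        grid_size: int = 201) -> str:
    """Render the prior-vs-posterior certainty bands to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = [i / (grid_size - 1) for i in range(grid_size)]
    fig, ax = plt.subplots(figsize=(6, 5))
    for eps in sorted(epsilons, reverse=True):
        band = certainty_band(grid, eps)
        upper = [pt[0].p_out for pt in band]
        lower = [pt[1].p_out for pt in band]
        ax.fill_between(grid, lower, upper, alpha=0.35,
                        label=f"$\\varepsilon$ = {eps:g}")
    ax.plot(grid, grid, "k--", linewidth=1, label="no update")
    ax.set_xlabel("initial inclusion certainty $P_{in}$")
    ax.set_ylabel("updated inclusion certainty $P_{out}$")
    ax.set_title("Certainty gained from one differentially private release")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
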