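"""The Laplace mechanism applied to quality-check counts and percentages.

A counting query ``f`` with sensitivity ``Δf`` is released as
``f'(D) = f(D) + Lap(Δf/ε)``, which satisfies pure ε-differential privacy
(δ = 0 throughout).  For a percentage, numerator and denominator receive
independent draws and the released value is ``(c̃/ñ)·100``; by default the
check's ε is split evenly between the two (each draw at scale ``Δf/(ε/2)``),
the conservative self-contained accounting.  Passing
``noise_denominator=False`` spends the full ε on the numerator and leaves the
denominator exact, which reproduces the textbook ratio-noise law
``SD[q̃] = √2/(nε)``.

Stratified results compose sequentially: a check budget ``ε_total`` over
``k`` strata gives each stratum ``ε_i = ε_total/k``, so per-stratum noise
scales like ``Δf·k/ε_total`` and its variance grows quadratically in ``k``.

Clamping (counts to ≥ 0, percentages to [0, 100]) is post-processing of the
noised value and never touches the raw statistic, so it preserves the
guarantee.  Sampling uses the inverse-CDF transform of a single uniform draw
for cross-platform reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .checks import CheckResult


@dataclass(frozen=True)
class DPParams:
    """Privacy parameters of one release: ε > 0, Δf ≥ 1, δ fixed at 0."""

    epsilon: float
    sensitivity: int = 1
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.sensitivity < 1:
            raise ValueError("sensitivity must be >= 1")
        if self.delta != 0.0:
            raise ValueError("only pure epsilon-DP (delta = 0) is supported")


@dataclass(frozen=True)
class NoisyResult:
    """A perturbed scalar: raw value (local-only), released value, accounting."""

    raw_value: float
    dp_value: float
    epsilon_spent: float
    noise_scale: float
    seed_tag: str = ""


@dataclass(frozen=True)
class NoisyRatio:
    """A perturbed percentage: noisy numerator/denominator and the released %."""

    check_id: str
    noisy_numerator: float
    noisy_denominator: float
    dp_percent: float
    epsilon_spent: float
    stratum: str | None = None
    suppressed: bool = False


def laplace_sample(scale: float, rng: np.random.Generator) -> float:
    """One draw from Laplace(0, scale) via the inverse-CDF transform.

    ``x = -b·sgn(u)·ln(1-2|u|)`` with ``u`` uniform on (-1/2, 1/2).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    u = rng.uniform(-0.5, 0.5)
    return -scale * math.copysign(1.0, u) * math.log1p(-2.0 * abs(u))


def noisy_count(count: int, params: DPParams, rng: np.random.Generator) -> NoisyResult:
    """Release a count with Laplace noise at scale Δf/ε, clamped to ≥ 0."""
    if count < 0:
        raise ValueError("count must be non-negative")
    scale = params.sensitivity / params.epsilon
    noised = count + laplace_sample(scale, rng)
    return NoisyResult(
        raw_value=float(count),
        dp_value=max(0.0, noised),
        epsilon_spent=params.epsilon,
        noise_scale=scale,
    )


def noisy_percentage(
    result: CheckResult,
    params: DPParams,
    rng: np.random.Generator,
    noise_denominator: bool = True,
) -> NoisyRatio:
    """Release a check percentage as ``(c̃/ñ)·100``.

    With ``noise_denominator`` (default), ε is split evenly between the two
    draws; otherwise the full ε goes to the numerator and ñ = n.  The noisy
    denominator is clamped to ≥ 1 and the numerator to [0, ñ], so the
    percentage stays in [0, 100]; it is rounded to 2 decimals.
    """
    if result.denominator <= 0:
        raise ValueError("insufficient population: denominator must be positive")
    eps = params.epsilon
    if noise_denominator:
        scale = params.sensitivity / (eps / 2.0)
        c_tilde = result.numerator + laplace_sample(scale, rng)
        n_tilde = result.denominator + laplace_sample(scale, rng)
    else:
        scale = params.sensitivity / eps
        c_tilde = result.numerator + laplace_sample(scale, rng)
        n_tilde = float(result.denominator)
    n_tilde = max(1.0, n_tilde)
    c_tilde = min(max(0.0, c_tilde), n_tilde)
    return NoisyRatio(
        check_id=result.check_id,
        noisy_numerator=c_tilde,
        noisy_denominator=n_tilde,
        dp_percent=round(100.0 * c_tilde / n_tilde, 2),
        epsilon_spent=eps,
        stratum=result.stratum,
    )


def split_stratum_budget(epsilon_total: float, k: int) -> list[float]:
    """Split a check budget into k equal shares summing exactly to the total."""
    if epsilon_total <= 0:
        raise ValueError("epsilon_total must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    share = epsilon_total / k
    shares = [share] * k
    shares[-1] = epsilon_total - share * (k - 1)  # force exact conservation
    return shares


def stratified_noisy_rates(
    results: list[CheckResult],
    epsilon_total: float,
    sensitivity: int,
    rng: np.random.Generator,
    noise_denominator: bool = True,
) -> list[NoisyRatio]:
    """Perturb one result per stratum under sequential composition.

    Each stratum spends ε_i = ε_total/k; the reported ``epsilon_spent`` per
    stratum is its share, and the shares sum exactly to ``epsilon_total``.
    """
    if not results:
        raise ValueError("no stratum results to perturb")
    shares = split_stratum_budget(epsilon_total, len(results))
    return [
        noisy_percentage(res, DPParams(eps_i, sensitivity), rng,
                         noise_denominator=noise_denominator)
        for res, eps_i in zip(results, shares)
    ]


def suppress_low_count(noisy: NoisyRatio, raw_numerator: int,
                       threshold: int) -> NoisyRatio:
    """Zero the released percentage when the raw numerator is below threshold.

    Suppression is post-processing on the release decision; the boundary is a
    strict less-than, and threshold 0 disables it.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if raw_numerator < threshold:
        return replace(noisy, dp_percent=0.0, suppressed=True)
    return noisy
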