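"""Privacy-budget accounting under sequential composition.

Running k ε_i-DP mechanisms on the same dataset is (Σ ε_i)-DP, so a report's
total privacy loss is the exact sum of its per-check charges.  The ledger
enforces a hard cap fail-closed: a charge that would exceed the cap is
refused atomically (the ledger is unchanged and the check must not run).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Absolute float tolerance when comparing a prospective total to the cap, so
#: that charges summing exactly to the cap are not refused over float dust.
_CAP_SLACK = 1e-9


class BudgetExhaustedError(RuntimeError):
    """A charge would push consumption over the cap; nothing was charged."""


@dataclass
class BudgetLedger:
    """Ordered record of per-check ε charges against a fixed cap."""

    cap: float
    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cap <= 0:
            raise ValueError("cap must be positive")

    @property
    def consumed(self) -> float:
        return math.fsum(eps for _, eps in self.entries)

    @property
    def remaining(self) -> float:
        return self.cap - self.consumed

    def can_afford(self, epsilon: float) -> bool:
        return self.consumed + epsilon <= self.cap + _CAP_SLACK

    def charge(self, check_id: str, epsilon: float) -> "BudgetLedger":
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not self.can_afford(epsilon):
            raise BudgetExhaustedError(
                f"budget exhausted: charging {epsilon} for {check_id!r} would "
                f"exceed cap {self.cap} (consumed {self.consumed:.4f})"
            )
        self.entries.append((check_id, epsilon))
        return self

    def to_dict(self) -> dict:
        return {
            "cap": self.cap,
            "entries": [{"check_id": c, "epsilon": e} for c, e in self.entries],
            "consumed": self.consumed,
            "remaining": self.remaining,
        }


def open_ledger(cap: float) -> BudgetLedger:
    """A fresh ledger: nothing consumed, everything remaining."""
    return BudgetLedger(cap=cap)


def charge(ledger: BudgetLedger, check_id: str, epsilon: float) -> BudgetLedger:
    """Functional-style wrapper around :meth:`BudgetLedger.charge`."""
    return ledger.charge(check_id, epsilon)


def allocation_plan(
    definitions,
    cap: float,
    overrides: dict[str, float] | None = None,
    default_epsilon: float | None = None,
) -> dict[str, float]:
    """Plan per-check ε allocations under the cap.

    Overridden checks take their stated ε; the remaining checks either take
    ``default_epsilon`` or share the leftover budget uniformly.  The plan
    total must not exceed the cap.
    """
    overrides = dict(overrides or {})
    ids = [d.check_id for d in definitions]
    unknown = set(overrides) - set(ids)
    if unknown:
        raise ValueError(f"overrides for unknown checks: {sorted(unknown)}")
    override_sum = math.fsum(overrides.values())
    if override_sum > cap + _CAP_SLACK:
        raise ValueError(f"overrides alone ({override_sum}) exceed cap {cap}")
    rest = [i for i in ids if i not in overrides]
    plan = dict(overrides)
    if rest:
        if default_epsilon is not None:
            share = default_epsilon
        else:
            share = (cap - override_sum) / len(rest)
        for i in rest:
            plan[i] = share
    total = math.fsum(plan.values())
    if total > cap + _CAP_SLACK:
        raise ValueError(f"plan total {total} exceeds cap {cap}")
    return {i: plan[i] for i in ids}
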