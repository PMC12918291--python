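"""Quality reports and the simulated agent/server federation.

A node-local agent builds a :class:`QualityReport` by, for every check:
charging its ε against the budget ledger (fail-closed — an unpaid check never
runs), executing the counting query, perturbing the result with the Laplace
mechanism, and mapping the released percentage to an ok/warning/error status.
The report exists in two views: the *local* view keeps raw counts and the
noise seed for on-site troubleshooting; the *public* view carries only the
differentially private values and the budget accounting, and is the only
artifact that ever leaves the node.

The federation is simulated over the filesystem: each node writes its public
report JSON, and the server-side aggregation reads exclusively those public
files to build a cross-node comparison table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .budget import BudgetExhaustedError, BudgetLedger
from .checks import (
    CheckDefinition,
    InsufficientPopulationError,
    run_check,
)
from .fhir_io import Dataset
from .mechanisms import (
    DPParams,
    noisy_percentage,
    stratified_noisy_rates,
    suppress_low_count,
)
from .privacy import DEFAULT_MIN_N, release_gate

STATUS_OK = "ok"
STATUS_WARNING = "warning"
STATUS_ERROR = "error"


@dataclass
class ReportConfig:
    """Disclosure policy for one report: budget plan, thresholds, gates."""

    cap: float
    default_epsilon: float = 0.2
    epsilon_overrides: dict[str, float] = field(
        default_factory=lambda: {"accuracy-3": 0.3}
    )
    warn_threshold: float = 10.0
    error_threshold: float = 30.0
    suppress_below: int = 0       # 0 disables low-count suppression
    min_n: int = DEFAULT_MIN_N    # minimum cohort size to release at all
    noise_denominator: bool = True

    def __post_init__(self) -> None:
        if self.cap <= 0:
            raise ValueError("cap must be positive")
        if self.warn_threshold > self.error_threshold:
            raise ValueError("warn_threshold must not exceed error_threshold")

    @classmethod
    def from_file(cls, path: str | Path) -> "ReportConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cap" not in raw:
            raise ValueError("config must state a total privacy budget cap")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ReportEntry:
    check_id: str
    dimension: str
    description: str
    dp_percent: float | None
    epsilon_spent: float
    status: str
    suppressed: bool = False
    stratum: str | None = None
    reason: str | None = None
    # local-only fields, stripped from the public view
    raw_percent: float | None = None
    numerator: int | None = None
    denominator: int | None = None


@dataclass
class QualityReport:
    node_id: str
    created_at: datetime
    entries: list[ReportEntry]
    budget_cap: float
    budget_consumed: float
    seed_tag: str = ""


def status_for(dp_percent: float, warn: float, error: float) -> str:
    """ok when ≤ warn, warning when ≤ error, error above that."""
    if warn > error:
        raise ValueError("warn threshold must not exceed error threshold")
    if dp_percent <= warn:
        return STATUS_OK
    if dp_percent <= error:
        return STATUS_WARNING
    return STATUS_ERROR


def build_report(
    dataset: Dataset,
    definitions: Sequence[CheckDefinition],
    ledger: BudgetLedger,
    config: ReportConfig,
    rng: np.random.Generator,
    node_id: str = "node-1",
    created_at: datetime | None = None,
    seed_tag: str = "",
) -> QualityReport:
    """Run the battery under the ledger and noise every disclosed value.

    Statuses are computed on the DP values — the quantity a public consumer
    can actually recompute.  A check the ledger refuses appears as an error
    entry with reason "budget exhausted" and discloses nothing.
    """
    if not dataset.patients:
        raise ValueError("cannot report on an empty dataset")
    ok, advisory = release_gate(len(dataset.patients), config.min_n)
    if not ok:
        raise ValueError(f"release refused: {advisory}")
    if created_at is None:
        created_at = datetime.now(timezone.utc)

    # the ledger, not the plan, enforces the cap: checks it cannot afford are
    # refused one by one (fail-closed), which a whole-plan validation would
    # turn into an all-or-nothing error instead
    entries: list[ReportEntry] = []
    for defn in definitions:
        eps = config.epsilon_overrides.get(defn.check_id, config.default_epsilon)
        try:
            ledger.charge(defn.check_id, eps)
        except BudgetExhaustedError:
            entries.append(ReportEntry(
                check_id=defn.check_id, dimension=defn.dimension,
                description=defn.description, dp_percent=None,
                epsilon_spent=0.0, status=STATUS_ERROR,
                reason="budget exhausted",
            ))
            continue
        try:
            results = run_check(defn, dataset)
        except InsufficientPopulationError as exc:
            entries.append(ReportEntry(
                check_id=defn.check_id, dimension=defn.dimension,
                description=defn.description, dp_percent=None,
                epsilon_spent=eps, status=STATUS_ERROR,
                reason=f"insufficient population: {exc}",
            ))
            continue
        if defn.strata:
            noisy_list = stratified_noisy_rates(
                results, eps, defn.sensitivity, rng,
                noise_denominator=config.noise_denominator)
        else:
            noisy_list = [noisy_percentage(
                results[0], DPParams(eps, defn.sensitivity), rng,
                noise_denominator=config.noise_denominator)]
        for res, noisy in zip(results, noisy_list):
            if config.suppress_below:
                noisy = suppress_low_count(noisy, res.numerator,
                                           config.suppress_below)
            entries.append(ReportEntry(
                check_id=defn.check_id, dimension=defn.dimension,
                description=defn.description,
                dp_percent=noisy.dp_percent,
                epsilon_spent=noisy.epsilon_spent,
                status=status_for(noisy.dp_percent, defn.warn_threshold,
                                  defn.error_threshold),
                suppressed=noisy.suppressed,
                stratum=res.stratum,
                raw_percent=res.raw_percent,
                numerator=res.numerator,
                denominator=res.denominator,
            ))
    return QualityReport(
        node_id=node_id,
        created_at=created_at,
        entries=entries,
        budget_cap=ledger.cap,
        budget_consumed=ledger.consumed,
        seed_tag=seed_tag,
    )


# ---------------------------------------------------------------------------
# serialisation

_PUBLIC_ENTRY_FIELDS = (
    "check_id", "dimension", "description", "dp_percent", "epsilon_spent",
    "status", "suppressed", "stratum", "reason",
)


def _public_entry(e: ReportEntry) -> dict:
    return {f: getattr(e, f) for f in _PUBLIC_ENTRY_FIELDS}


def _local_entry(e: ReportEntry) -> dict:
    d = _public_entry(e)
    d.update(raw_percent=e.raw_percent, numerator=e.numerator,
             denominator=e.denominator)
    return d


def public_view(report: QualityReport) -> dict:
    """Public dict: DP values and budget accounting only.

    Raw percentages, counts and seed material never appear; the timestamp is
    truncated to the day to shrink the linkage surface.
    """
    return {
        "node_id": report.node_id,
        "created_at": report.created_at.date().isoformat(),
        "cap": report.budget_cap,
        "consumed": report.budget_consumed,
        "entries": [_public_entry(e) for e in report.entries],
    }


def local_view(report: QualityReport) -> dict:
    """Local dict: the public content plus raw values and the seed tag."""
    return {
        "node_id": report.node_id,
        "created_at": report.created_at.isoformat(),
        "cap": report.budget_cap,
        "consumed": report.budget_consumed,
        "seed_tag": report.seed_tag,
        "entries": [_local_entry(e) for e in report.entries],
    }


def export_public(report: QualityReport, path: str | Path) -> Path:
    """Write the public JSON view; stable key order makes re-export identical."""
    path = Path(path)
    path.write_text(json.dumps(public_view(report), indent=2, sort_keys=True) + "\n")
    return path


def export_local(report: QualityReport, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(local_view(report), indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# federation (server side)

#: Keys that must never occur in a public report; their presence marks a file
#: as local (or tampered) and the aggregator refuses to read it.
_FORBIDDEN_PUBLIC_KEYS = {"raw_percent", "numerator", "denominator", "seed_tag"}


@dataclass
class FederationView:
    """Server-side cross-node view, built exclusively from public reports."""

    reports: dict[str, dict]
    table: pd.DataFrame        # dp_percent, rows (check_id, stratum) x node
    status_table: pd.DataFrame
    errors: list[str] = field(default_factory=list)


def _validate_public_schema(doc: dict, path: str) -> None:
    def walk(obj) -> None:
        if isinstance(obj, dict):
            bad = _FORBIDDEN_PUBLIC_KEYS & set(obj)
            if bad:
                raise ValueError(
                    f"{path}: refusing non-public report (found {sorted(bad)})")
            for v in obj.values():
                walk(v)
        elif isinstance(obj, list):
            for v in obj:
                walk(v)

    for key in ("node_id", "entries"):
        if key not in doc:
            raise ValueError(f"{path}: missing required key {key!r}")
    walk(doc)


def aggregate_nodes(public_report_paths: Sequence[str | Path]) -> FederationView:
    """Aggregate public report files into a per-check cross-node table.

    Malformed or non-public files are skipped with a recorded error; a node
    missing a check appears as NaN (absent), never as zero.
    """
    if not public_report_paths:
        raise ValueError("no public reports to aggregate")
    reports: dict[str, dict] = {}
    errors: list[str] = []
    for p in public_report_paths:
        p = Path(p)
        try:
            doc = json.loads(p.read_text())
            _validate_public_schema(doc, str(p))
        except (OSError, json.JSONDecodeError, ValueError) as exc:
            errors.append(str(exc))
            continue
        reports[doc["node_id"]] = doc
    if not reports:
        raise ValueError(f"no valid public reports among {len(errors)} files")

    rows: dict[tuple[str, str], dict[str, float]] = {}
    statuses: dict[tuple[str, str], dict[str, str]] = {}
    for node_id, doc in reports.items():
        for e in doc["entries"]:
            key = (e["check_id"], e.get("stratum") or "")
            rows.setdefault(key, {})[node_id] = e.get("dp_percent")
            statuses.setdefault(key, {})[node_id] = e.get("status")
    index = pd.MultiIndex.from_tuples(sorted(rows), names=["check_id", "stratum"])
    node_ids = sorted(reports)
    table = pd.DataFrame(
        [[rows[k].get(nid, math.nan) for nid in node_ids] for k in index],
        index=index, columns=node_ids, dtype=float,
    )
    status_table = pd.DataFrame(
        [[statuses[k].get(nid) for nid in node_ids] for k in index],
        index=index, columns=node_ids,
    )
    return FederationView(reports=reports, table=table,
                          status_table=status_table, errors=errors)
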