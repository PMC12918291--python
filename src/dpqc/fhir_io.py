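"""Minimal FHIR R4 reader/writer for the resource subset the quality checks inspect.

Only three resource types are touched — ``Patient``, ``Condition`` and
``Specimen`` — and of those only the elements the check engine needs:
``Patient.gender``, ``Patient.birthDate``, ``Patient.deceasedBoolean`` /
``deceasedDateTime``, ``meta.lastUpdated``, ``Condition.subject.reference``,
``Condition.code.coding[0]``, ``Specimen.subject.reference``,
``Specimen.type.coding[0].code`` and ``Specimen.collection.collectedDateTime``.

Two serialisations are supported: a FHIR JSON Bundle (``type: collection``)
and NDJSON (one resource per line).  Reading is deliberately non-normalising:
gender tokens, codes and ids are kept verbatim, duplicate ids are retained,
and partial dates (``YYYY`` or ``YYYY-MM``) are compared by their earliest
instant — flagging oddities is the check engine's job, not the parser's.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterator, Literal

log = logging.getLogger(__name__)

Format = Literal["bundle", "ndjson"]

SUPPORTED_RESOURCE_TYPES = ("Patient", "Condition", "Specimen")

_PARTIAL_DATE_RE = re.compile(r"^(\d{4})(?:-(\d{2}))?(?:-(\d{2}))?$")


class FhirParseError(ValueError):
    """Raised when a file or resource cannot be interpreted as the FHIR subset."""


def parse_fhir_date(value: str) -> date:
    """Parse a full or partial FHIR date to its earliest instant.

    ``"1987"`` -> 1987-01-01, ``"1987-05"`` -> 1987-05-01.
    """
    m = _PARTIAL_DATE_RE.match(value.strip())
    if not m:
        raise FhirParseError(f"not a FHIR date: {value!r}")
    year, month, day = m.group(1), m.group(2) or "01", m.group(3) or "01"
    return date(int(year), int(month), int(day))


def parse_fhir_instant(value: str) -> datetime:
    """Parse a FHIR instant (ISO-8601 with zone) to an aware UTC datetime."""
    try:
        dt = datetime.fromisoformat(value.replace("Z", "+00:00"))
    except ValueError as exc:
        raise FhirParseError(f"not a FHIR instant: {value!r}") from exc
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def _format_instant(dt: datetime) -> str:
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc).isoformat().replace("+00:00", "Z")


def strip_reference(ref: str) -> str:
    """``"Patient/p1"`` and ``"p1"`` both resolve to the bare id ``"p1"``."""
    return ref.split("/", 1)[1] if ref.startswith("Patient/") else ref


@dataclass
class PatientRecord:
    id: str
    gender: str | None = None
    birth_date: date | None = None
    deceased: bool | None = None
    last_updated: datetime | None = None


@dataclass
class ConditionRecord:
    id: str
    patient_ref: str
    code: str | None = None
    coding_system: str | None = None


@dataclass
class SpecimenRecord:
    id: str
    patient_ref: str
    type_code: str | None = None
    collected: date | None = None


@dataclass
class Dataset:
    """In-memory cohort: ordered record collections plus the evaluation date.

    ``reference_date`` stands in for "now" in every time-relative check so
    that results are reproducible; the wall clock is never consulted.
    """

    patients: list[PatientRecord] = field(default_factory=list)
    conditions: list[ConditionRecord] = field(default_factory=list)
    specimens: list[SpecimenRecord] = field(default_factory=list)
    reference_date: date = date(2025, 1, 1)


@dataclass(frozen=True)
class ReferenceViolation:
    resource_type: str
    resource_id: str
    patient_ref: str


# ---------------------------------------------------------------------------
# resource <-> record mapping


def _patient_from_resource(res: dict) -> PatientRecord:
    deceased: bool | None = None
    if "deceasedBoolean" in res:
        deceased = bool(res["deceasedBoolean"])
    elif "deceasedDateTime" in res:
        deceased = True
    last_updated = None
    meta = res.get("meta") or {}
    if meta.get("lastUpdated"):
        last_updated = parse_fhir_instant(meta["lastUpdated"])
    birth = res.get("birthDate")
    return PatientRecord(
        id=str(res.get("id", "")),
        gender=res.get("gender"),
        birth_date=parse_fhir_date(birth) if birth else None,
        deceased=deceased,
        last_updated=last_updated,
    )


def _condition_from_resource(res: dict) -> ConditionRecord:
    subject = (res.get("subject") or {}).get("reference", "")
    coding = ((res.get("code") or {}).get("coding") or [{}])[0]
    return ConditionRecord(
        id=str(res.get("id", "")),
        patient_ref=strip_reference(subject),
        code=coding.get("code"),
        coding_system=coding.get("system"),
    )


def _specimen_from_resource(res: dict) -> SpecimenRecord:
    subject = (res.get("subject") or {}).get("reference", "")
    coding = ((res.get("type") or {}).get("coding") or [{}])[0]
    collected = (res.get("collection") or {}).get("collectedDateTime")
    return SpecimenRecord(
        id=str(res.get("id", "")),
        patient_ref=strip_reference(subject),
        type_code=coding.get("code"),
        collected=parse_fhir_date(collected) if collected else None,
    )


def _patient_to_resource(p: PatientRecord) -> dict:
    res: dict = {"resourceType": "Patient", "id": p.id}
    if p.gender is not None:
        res["gender"] = p.gender
    if p.birth_date is not None:
        res["birthDate"] = p.birth_date.isoformat()
    if p.deceased is not None:
        res["deceasedBoolean"] = p.deceased
    if p.last_updated is not None:
        res["meta"] = {"lastUpdated": _format_instant(p.last_updated)}
    return res


def _condition_to_resource(c: ConditionRecord) -> dict:
    res: dict = {
        "resourceType": "Condition",
        "id": c.id,
        "subject": {"reference": f"Patient/{c.patient_ref}"},
    }
    if c.code is not None or c.coding_system is not None:
        coding: dict = {}
        if c.coding_system is not None:
            coding["system"] = c.coding_system
        if c.code is not None:
            coding["code"] = c.code
        res["code"] = {"coding": [coding]}
    return res


def _specimen_to_resource(s: SpecimenRecord) -> dict:
    res: dict = {
        "resourceType": "Specimen",
        "id": s.id,
        "subject": {"reference": f"Patient/{s.patient_ref}"},
    }
    if s.type_code is not None:
        res["type"] = {"coding": [{"code": s.type_code}]}
    if s.collected is not None:
        res["collection"] = {"collectedDateTime": s.collected.isoformat()}
    return res


# ---------------------------------------------------------------------------
# file IO


def _iter_resources(path: Path, format: Format) -> Iterator[dict]:
    if format == "bundle":
        try:
            bundle = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FhirParseError(f"unparsable bundle {path}: {exc}") from exc
        if not isinstance(bundle, dict) or bundle.get("resourceType") != "Bundle":
            raise FhirParseError(f"{path} is not a FHIR Bundle")
        for entry in bundle.get("entry", []):
            yield entry.get("resource", {})
    elif format == "ndjson":
        for lineno, line in enumerate(path.read_text().splitlines()):
            if not line.strip():
                continue
            try:
                yield json.loads(line)
            except json.JSONDecodeError as exc:
                raise FhirParseError(
                    f"unparsable NDJSON line {lineno + 1} in {path}: {exc}"
                ) from exc
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown format {format!r}")


def read_dataset(path: str | Path, format: Format, reference_date: date) -> Dataset:
    """Read every Patient/Condition/Specimen resource from ``path``.

    Unknown resource types are skipped (a count is logged).  Duplicate ids are
    preserved: uniqueness is a quality check, not a cleaning step.
    """
    path = Path(path)
    ds = Dataset(reference_date=reference_date)
    skipped = 0
    for index, res in enumerate(_iter_resources(path, format)):
        rtype = res.get("resourceType")
        if rtype is None:
            raise FhirParseError(f"resource at index {index} has no resourceType")
        if rtype == "Patient":
            ds.patients.append(_patient_from_resource(res))
        elif rtype == "Condition":
            ds.conditions.append(_condition_from_resource(res))
        elif rtype == "Specimen":
            ds.specimens.append(_specimen_from_resource(res))
        else:
            skipped += 1
    if skipped:
        log.info("skipped %d resources of unsupported types in %s", skipped, path)
    return ds


def write_dataset(dataset: Dataset, path: str | Path, format: Format) -> Path:
    """Serialise ``dataset``; ``read_dataset`` on the result round-trips it."""
    path = Path(path)
    resources = (
        [_patient_to_resource(p) for p in dataset.patients]
        + [_condition_to_resource(c) for c in dataset.conditions]
        + [_specimen_to_resource(s) for s in dataset.specimens]
    )
    if format == "bundle":
        bundle = {
            "resourceType": "Bundle",
            "type": "collection",
            "entry": [{"resource": r} for r in resources],
        }
        path.write_text(json.dumps(bundle, indent=2) + "\n")
    elif format == "ndjson":
        path.write_text("".join(json.dumps(r) + "\n" for r in resources))
    else:  # pragma: no cover
        raise ValueError(f"unknown format {format!r}")
    return path


def validate_references(dataset: Dataset) -> list[ReferenceViolation]:
    """One violation per Condition/Specimen whose patient_ref resolves nowhere."""
    known = {p.id for p in dataset.patients}
    violations: list[ReferenceViolation] = []
    for c in dataset.conditions:
        if c.patient_ref not in known:
            violations.append(ReferenceViolation("Condition", c.id, c.patient_ref))
    for s in dataset.specimens:
        if s.patient_ref not in known:
            violations.append(ReferenceViolation("Specimen", s.id, s.patient_ref))
    return violations
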