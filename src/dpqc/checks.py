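"""The built-in quality-check battery: counting queries over a FHIR dataset.

Each check is a pure counting rule returning a numerator ``c``, a denominator
``n`` and the raw percentage ``100*c/n`` — optionally per stratum.  Checks are
deterministic and never touch randomness; differential privacy is applied
downstream by the noise mechanisms.

Check semantics
---------------
* The denominator is the total number of patient *records*, duplicates
  included, except for stratified checks where it is the stratum size.
* A missing gender (absent element or empty string) is a completeness
  failure; a present non-empty token outside the FHIR AdministrativeGender
  set {male, female, other, unknown} is a consistency failure.  The two
  numerators are disjoint.
* Condition-linked checks resolve by patient id: a record "has" the
  conditions its id resolves to.
* Duplicates: numerator = total records − distinct ids (surplus records).
* Timeliness: records never updated are counted stale (worst case).
* Survival: share of stratum records whose deceased flag is not true.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Callable, Collection, Sequence

from .fhir_io import Dataset, PatientRecord
from .icd import DEFAULT_INCOMPATIBILITY, is_incompatible, is_valid_icd10

SUPPORTED_GENDERS = frozenset({"male", "female", "other", "unknown"})

#: Days after which a record without a fresher ``meta.lastUpdated`` is stale.
STALE_AFTER_DAYS = 365

DOB_FLOOR = date(1900, 1, 1)


class InsufficientPopulationError(ValueError):
    """A check's denominator population is empty — distinct from a 0% result."""


@dataclass(frozen=True)
class CheckResult:
    check_id: str
    numerator: int
    denominator: int
    raw_percent: float
    stratum: str | None = None


@dataclass(frozen=True)
class CheckDefinition:
    """A named counting rule plus its privacy/report metadata."""

    check_id: str
    dimension: str
    description: str
    predicate: Callable[["CheckDefinition", Dataset], list[CheckResult]]
    sensitivity: int = 1
    strata: tuple[str, ...] | None = None
    warn_threshold: float = 10.0
    error_threshold: float = 30.0
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sensitivity < 1:
            raise ValueError("sensitivity must be >= 1")
        if self.warn_threshold > self.error_threshold:
            raise ValueError("warn_threshold must not exceed error_threshold")

    def run(self, dataset: Dataset) -> list[CheckResult]:
        return self.predicate(self, dataset)


def _result(defn: CheckDefinition, numerator: int, denominator: int,
            stratum: str | None = None) -> CheckResult:
    if denominator <= 0:
        raise InsufficientPopulationError(
            f"{defn.check_id}: empty denominator population"
            + (f" (stratum {stratum})" if stratum else "")
        )
    return CheckResult(
        check_id=defn.check_id,
        numerator=numerator,
        denominator=denominator,
        raw_percent=round(100.0 * numerator / denominator, 2),
        stratum=stratum,
    )


def _patients(dataset: Dataset) -> list[PatientRecord]:
    if not dataset.patients:
        raise InsufficientPopulationError("dataset has no patient records")
    return dataset.patients


def _conditions_by_patient(dataset: Dataset) -> dict[str, list]:
    index: dict[str, list] = {}
    for c in dataset.conditions:
        index.setdefault(c.patient_ref, []).append(c)
    return index


def _count(defn: CheckDefinition, dataset: Dataset,
           pred: Callable[[PatientRecord], bool]) -> list[CheckResult]:
    pats = _patients(dataset)
    return [_result(defn, sum(1 for p in pats if pred(p)), len(pats))]


def gender_missing(p: PatientRecord) -> bool:
    return p.gender is None or p.gender == ""


def gender_unsupported(p: PatientRecord) -> bool:
    return not gender_missing(p) and p.gender not in SUPPORTED_GENDERS


# --- predicates -------------------------------------------------------------


def _check_incompatible_diagnosis(defn: CheckDefinition, dataset: Dataset) -> list[CheckResult]:
    conds = _conditions_by_patient(dataset)
    table = getattr(defn, "_incompatibility", None) or DEFAULT_INCOMPATIBILITY
    return _count(
        defn, dataset,
        lambda p: any(is_incompatible(p.gender, c.code, table) for c in conds.get(p.id, ())),
    )


def _check_dob_anomaly(defn: CheckDefinition, dataset: Dataset) -> list[CheckResult]:
    ref = dataset.reference_date
    return _count(
        defn, dataset,
        lambda p: p.birth_date is not None and (p.birth_date < DOB_FLOOR or p.birth_date > ref),
    )


def _check_missing_gender(defn: CheckDefinition, dataset: Dataset) -> list[CheckResult]:
    return _count(defn, dataset, gender_missing)


def _check_missing_condition(defn: CheckDefinition, dataset: Dataset) -> list[CheckResult]:
    conds = _conditions_by_patient(dataset)
    return _count(defn, dataset, lambda p: p.id not in conds)


def _check_unsupported_gender(defn: CheckDefinition, dataset: Dataset) -> list[CheckResult]:
    return _count(defn, dataset, gender_unsupported)


def _check_stale_update(defn: CheckDefinition, dataset: Dataset) -> list[CheckResult]:
    ref = dataset.reference_date

    def stale(p: PatientRecord) -> bool:
        if p.last_updated is None:
            return True
        return (ref - p.last_updated.date()).days > STALE_AFTER_DAYS

    return _count(defn, dataset, stale)


def _check_invalid_icd10(defn: CheckDefinition, dataset: Dataset) -> list[CheckResult]:
    conds = _conditions_by_patient(dataset)
    code_list: Collection[str] | None = getattr(defn, "_code_list", None)
    return _count(
        defn, dataset,
        lambda p: any(not is_valid_icd10(c.code, code_list) for c in conds.get(p.id, ())),
    )


def _check_duplicate_ids(defn: CheckDefinition, dataset: Dataset) -> list[CheckResult]:
    pats = _patients(dataset)
    surplus = len(pats) - len({p.id for p in pats})
    return [_result(defn, surplus, len(pats))]


def _check_survival(defn: CheckDefinition, dataset: Dataset) -> list[CheckResult]:
    pats = _patients(dataset)
    results = []
    for stratum in defn.strata or ():
        members = [p for p in pats if p.gender == stratum]
        alive = sum(1 for p in members if p.deceased is not True)
        results.append(_result(defn, alive, len(members), stratum=stratum))
    return results


def builtin_checks(
    incompatibility: dict[str, frozenset[str]] | None = None,
    icd10_code_list: Collection[str] | None = None,
) -> list[CheckDefinition]:
    """The nine built-in checks, in report order, all with sensitivity 1.

    ``incompatibility`` overrides the gender/diagnosis exclusion table;
    ``icd10_code_list`` switches ICD-10 validity from the structural pattern
    to terminology membership.
    """
    defs = [
        CheckDefinition(
            "accuracy-1", "Accuracy",
            "How many patients have an incompatible Diagnosis (e.g. Prostate Cancer for Female)",
            _check_incompatible_diagnosis,
        ),
        CheckDefinition(
            "accuracy-2", "Accuracy",
            "Date of Birth before 1900 or in the future",
            _check_dob_anomaly,
        ),
        CheckDefinition(
            "completeness-1", "Completeness",
            "How many patients have missing gender info",
            _check_missing_gender, aliases=("completness-1",),
        ),
        CheckDefinition(
            "completeness-2", "Completeness",
            "How many patients do not have a condition",
            _check_missing_condition, aliases=("completness-2",),
        ),
        CheckDefinition(
            "consistency-1", "Consistency",
            "How many patients do not have a supported gender value",
            _check_unsupported_gender,
        ),
        CheckDefinition(
            "timeliness-1", "Timeliness",
            "How many patients were last updated more than a year ago",
            _check_stale_update,
        ),
        CheckDefinition(
            "validity-1", "Validity",
            "How many patients have conditions with invalid ICD-10 codes",
            _check_invalid_icd10,
        ),
        CheckDefinition(
            "uniqueness-1", "Uniqueness",
            "How many patients are duplicated in the dataset based on IDs",
            _check_duplicate_ids, aliases=("uniqness-1",),
        ),
        CheckDefinition(
            "accuracy-3", "Accuracy",
            "Survival rate by gender",
            _check_survival, strata=("female", "male"),
        ),
    ]
    if incompatibility is not None or icd10_code_list is not None:
        for d in defs:
            if incompatibility is not None and d.check_id == "accuracy-1":
                object.__setattr__(d, "_incompatibility", incompatibility)
            if icd10_code_list is not None and d.check_id == "validity-1":
                object.__setattr__(d, "_code_list", icd10_code_list)
    return defs


def sample_sensitivity(dataset: Dataset) -> int:
    """Δf for specimen-level counting queries.

    Patient-level checks have sensitivity 1 (one patient changes a count by
    at most one), but a query counting specimens can change by as many
    records as one patient contributes; the Laplace scale must be calibrated
    to that maximum.
    """
    if not dataset.specimens:
        return 1
    per_patient: dict[str, int] = {}
    for s in dataset.specimens:
        per_patient[s.patient_ref] = per_patient.get(s.patient_ref, 0) + 1
    return max(per_patient.values())


def find_check(registry: Sequence[CheckDefinition], check_id: str) -> CheckDefinition:
    """Look a check up by canonical id or alias (legacy spellings accepted)."""
    for d in registry:
        if d.check_id == check_id or check_id in d.aliases:
            return d
    raise KeyError(check_id)


def register_check(definition: CheckDefinition,
                   registry: Sequence[CheckDefinition]) -> list[CheckDefinition]:
    """Return ``registry`` extended with ``definition``; ids must stay unique."""
    taken = {d.check_id for d in registry} | {a for d in registry for a in d.aliases}
    if definition.check_id in taken or any(a in taken for a in definition.aliases):
        raise ValueError(f"check id {definition.check_id!r} already registered")
    return list(registry) + [definition]


def run_check(definition: CheckDefinition, dataset: Dataset) -> list[CheckResult]:
    """Execute one check; one result per stratum (singleton when unstratified)."""
    return definition.run(dataset)


def run_battery(definitions: Sequence[CheckDefinition], dataset: Dataset,
                raise_errors: bool = False) -> list[CheckResult]:
    """Run every check in definition order.

    A failing check (e.g. an empty stratum) is skipped with a log message
    rather than aborting the battery, unless ``raise_errors`` is set.
    """
    if not definitions:
        raise ValueError("no check definitions given")
    results: list[CheckResult] = []
    for defn in definitions:
        try:
            results.extend(defn.run(dataset))
        except InsufficientPopulationError:
            if raise_errors:
                raise
            import logging

            logging.getLogger(__name__).warning(
                "check %s skipped: insufficient population", defn.check_id
            )
    return results
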