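"""Synthetic FHIR cohort generator with purposeful quality-error injection.

Emulates the kind of test data used to validate federated quality reporting:
a general patient cohort (plus specimens) into which each class of data
quality error — missing or unsupported gender tokens, absent conditions,
structurally invalid ICD-10 codes, sex-incompatible diagnoses, implausible
birth dates, stale update timestamps, duplicated patient ids — is injected at
a configurable rate.  The generator is the ground truth against which the
check engine is validated: every injected defect is recoverable by exactly
one check.

Injection semantics
-------------------
* Record-level classes (gender state, birth-date anomaly, staleness,
  deceased flag) are drawn independently per patient record.
* Condition-linked classes (missing condition, invalid code, incompatible
  diagnosis) are drawn per unique patient id, because conditions resolve by
  id; a duplicate record shares the conditions of the id it reuses.
* The invalid-ICD-10 rate is *conditional on having at least one condition*
  (a patient without conditions cannot carry a code), and the incompatible-
  diagnosis rate is additionally conditional on a recorded binary gender.
  ``expected_rates`` converts profile rates into the rates the checks are
  expected to observe.
* Duplicates are freshly drawn records that reuse an existing id; their
  count is ``ceil(rate * n_patients)`` (or an explicit override), appended
  after the base population, so the duplicated share is surplus/total.
* ``exact_counts=True`` replaces each Bernoulli draw with a uniformly random
  subset of exactly ``round(rate * total_records)`` records, for fixtures
  that must reproduce published prevalences digit-for-digit.

All randomness flows through one seeded ``numpy`` generator with a fixed
draw order (class by class), so a spec is reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta, timezone

import numpy as np
import pandas as pd

from . import icd
from .checks import SUPPORTED_GENDERS, STALE_AFTER_DAYS, DOB_FLOOR
from .fhir_io import ConditionRecord, Dataset, PatientRecord, SpecimenRecord

ICD10_SYSTEM = "http://hl7.org/fhir/sid/icd-10"

#: Tokens outside the FHIR AdministrativeGender value set, as seen in the wild.
UNSUPPORTED_GENDER_POOL = ("F", "M", "MALE", "FEMALE", "x", "n/a")

SPECIMEN_TYPE_POOL = ("blood-plasma", "blood-serum", "dna", "urine", "tissue-ffpe")

#: Codes used when injecting a sex-incompatible diagnosis.
MALE_ONLY_CODES = ("C61", "C62.9", "C60.9")
FEMALE_ONLY_CODES = ("C53.9", "C56.9", "C54.1")

#: Days of inactivity injected for stale vs fresh records.  Fresh records sit
#: comfortably inside the one-year timeliness window, stale ones outside it.
STALE_AGE_DAYS = 400
FRESH_AGE_DAYS = 30


@dataclass
class ErrorProfile:
    """Per-class injection rates; defaults mirror a realistic demo cohort.

    ``rate_invalid_icd10`` and ``rate_incompatible_diagnosis`` are conditional
    rates (see module docstring); everything else is an unconditional
    per-record probability.  ``survival_rate_by_gender`` is the probability of
    the deceased flag being absent/false per gender stratum.
    """

    rate_missing_gender: float = 0.037
    rate_unsupported_gender: float = 0.096
    rate_missing_condition: float = 0.200
    rate_invalid_icd10: float = 0.969
    rate_duplicate_id: float = 0.097
    rate_dob_anomaly: float = 0.056
    rate_incompatible_diagnosis: float = 0.001
    rate_stale_update: float = 0.0
    survival_rate_by_gender: dict[str, float] = field(
        default_factory=lambda: {"female": 0.276, "male": 0.309}
    )

    def __post_init__(self) -> None:
        for name, value in self.rates().items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.rate_missing_gender + self.rate_unsupported_gender > 1.0:
            raise ValueError("missing + unsupported gender rates exceed 1")
        unknown = set(self.survival_rate_by_gender) - SUPPORTED_GENDERS
        if unknown:
            raise ValueError(f"survival strata outside supported genders: {unknown}")

    def rates(self) -> dict[str, float]:
        flat = {
            k: v for k, v in self.__dict__.items()
            if k.startswith("rate_")
        }
        for stratum, rate in self.survival_rate_by_gender.items():
            flat[f"survival_{stratum}"] = rate
        return flat


def default_profile() -> ErrorProfile:
    """The default injection profile (module-level rates above)."""
    return ErrorProfile()


def zero_profile() -> ErrorProfile:
    """A profile injecting no errors at all (everyone survives)."""
    return ErrorProfile(
        rate_missing_gender=0.0, rate_unsupported_gender=0.0,
        rate_missing_condition=0.0, rate_invalid_icd10=0.0,
        rate_duplicate_id=0.0, rate_dob_anomaly=0.0,
        rate_incompatible_diagnosis=0.0, rate_stale_update=0.0,
        survival_rate_by_gender={"female": 1.0, "male": 1.0},
    )


@dataclass
class CohortSpec:
    n_patients: int
    n_specimens: int = 0
    seed: int = 0
    profile: ErrorProfile = field(default_factory=default_profile)
    reference_date: date = date(2025, 1, 1)
    exact_counts: bool = False
    n_duplicates: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_specimens < 0:
            raise ValueError("n_specimens must be >= 0")


def reference_cohort_spec(seed: int = 0) -> CohortSpec:
    """A synthetic stand-in for the deposited 1,000-patient demo dataset.

    Synthetic: generated by this module, not downloaded.  903 unique base
    records plus 97 id-duplicates give 1,000 patient records in which the
    headline prevalences are injected as exact counts — 3.70% missing gender,
    9.60% unsupported gender, 20.00% without conditions, 9.70% duplicated —
    alongside 10,000 specimens.
    """
    return CohortSpec(
        n_patients=903,
        n_specimens=10_000,
        seed=seed,
        profile=default_profile(),
        exact_counts=True,
        n_duplicates=97,
    )


# ---------------------------------------------------------------------------
# flag machinery


def _record_flags(rng: np.random.Generator, size: int, rate: float,
                  exact: bool) -> np.ndarray:
    """Boolean vector: Bernoulli(rate), or exactly round(rate*size) Trues."""
    flags = np.zeros(size, dtype=bool)
    if exact:
        k = int(round(rate * size))
        if k > 0:
            flags[rng.choice(size, size=min(k, size), replace=False)] = True
    else:
        flags = rng.random(size) < rate
    return flags


def _select_ids_by_weight(rng: np.random.Generator, weights: np.ndarray,
                          target: int) -> np.ndarray:
    """Greedy exact-count selection of ids whose record multiplicities sum to target.

    Iterates ids in random order, taking an id whenever its multiplicity still
    fits.  With unit multiplicities present this always lands exactly.
    """
    chosen = np.zeros(len(weights), dtype=bool)
    remaining = target
    for i in rng.permutation(len(weights)):
        if remaining <= 0:
            break
        if weights[i] <= remaining:
            chosen[i] = True
            remaining -= int(weights[i])
    return chosen


def _invalid_code(rng: np.random.Generator) -> str:
    # 'U' prefix and an over-long suffix both fail the structural pattern.
    return f"U{rng.integers(0, 10)}{rng.integers(0, 10)}.{rng.integers(10000, 99999)}"


def generate_cohort(spec: CohortSpec) -> Dataset:
    """Generate a cohort per ``spec``; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    prof = spec.profile
    n = spec.n_patients
    exact = spec.exact_counts
    ref = spec.reference_date

    # 1. duplicates: ids reused from the base population
    if spec.n_duplicates is not None:
        d = spec.n_duplicates
    else:
        d = math.ceil(prof.rate_duplicate_id * n)
    total = n + d
    base_ids = [f"pat-{i:05d}" for i in range(n)]
    dup_sources = rng.integers(0, n, size=d) if d else np.array([], dtype=int)
    ids = base_ids + [base_ids[s] for s in dup_sources]
    # record index -> index of the base record owning the id
    owner = np.concatenate([np.arange(n), dup_sources]).astype(int)

    # 2. gender state: missing / unsupported / valid (mutually exclusive)
    if exact:
        perm = rng.permutation(total)
        k_missing = int(round(prof.rate_missing_gender * total))
        k_unsup = int(round(prof.rate_unsupported_gender * total))
        missing = np.zeros(total, dtype=bool)
        unsupported = np.zeros(total, dtype=bool)
        missing[perm[:k_missing]] = True
        unsupported[perm[k_missing:k_missing + k_unsup]] = True
    else:
        u = rng.random(total)
        missing = u < prof.rate_missing_gender
        unsupported = (~missing) & (u < prof.rate_missing_gender + prof.rate_unsupported_gender)
    unsupported_tokens = rng.choice(UNSUPPORTED_GENDER_POOL, size=total)

    # 3. underlying sex (drives survival and incompatible-diagnosis injection)
    female = rng.random(total) < 0.5
    sex = np.where(female, "female", "male")

    # 4. deceased flag per underlying sex
    death_rate = np.where(
        female,
        1.0 - prof.survival_rate_by_gender.get("female", 1.0),
        1.0 - prof.survival_rate_by_gender.get("male", 1.0),
    )
    deceased = rng.random(total) < death_rate

    # 5. birth dates: normal ages 18-90y; anomalies half pre-1900, half future
    dob_flag = _record_flags(rng, total, prof.rate_dob_anomaly, exact)
    dob_future = rng.random(total) < 0.5
    age_days = rng.integers(18 * 365, 90 * 365, size=total)
    past_years = rng.integers(DOB_FLOOR.year - 50, DOB_FLOOR.year, size=total)
    future_days = rng.integers(1, 366, size=total)
    birth_dates: list[date] = []
    for i in range(total):
        if dob_flag[i]:
            if dob_future[i]:
                birth_dates.append(ref + timedelta(days=int(future_days[i])))
            else:
                birth_dates.append(date(int(past_years[i]), 1, 1)
                                   + timedelta(days=int(age_days[i]) % 365))
        else:
            birth_dates.append(ref - timedelta(days=int(age_days[i])))

    # 6. staleness
    stale = _record_flags(rng, total, prof.rate_stale_update, exact)
    updated = [
        datetime.combine(
            ref - timedelta(days=STALE_AGE_DAYS if stale[i] else FRESH_AGE_DAYS),
            time(12, 0), tzinfo=timezone.utc,
        )
        for i in range(total)
    ]

    # 7. condition-linked classes, drawn per unique id (i.e. per base record)
    multiplicity = np.bincount(owner, minlength=n)  # records per base id
    if exact:
        target = int(round(prof.rate_missing_condition * total))
        no_condition = _select_ids_by_weight(rng, multiplicity, target)
    else:
        no_condition = rng.random(n) < prof.rate_missing_condition
    has_condition = ~no_condition

    with_cond_idx = np.flatnonzero(has_condition)
    if exact:
        rec_with_cond = int(multiplicity[with_cond_idx].sum())
        target_inv = int(round(prof.rate_invalid_icd10 * rec_with_cond))
        inv_sel = _select_ids_by_weight(
            rng, multiplicity[with_cond_idx], target_inv)
    else:
        inv_sel = rng.random(len(with_cond_idx)) < prof.rate_invalid_icd10
    invalid_flag = np.zeros(n, dtype=bool)
    invalid_flag[with_cond_idx[inv_sel]] = True

    # incompatible diagnosis: needs conditions and a recorded binary gender
    recorded_binary = ~(missing[:n] | unsupported[:n])
    eligible = np.flatnonzero(has_condition & recorded_binary)
    if exact:
        k_inc = min(int(round(prof.rate_incompatible_diagnosis * total)), len(eligible))
        inc_sel = rng.choice(len(eligible), size=k_inc, replace=False) if k_inc else []
        incompatible_flag = np.zeros(n, dtype=bool)
        incompatible_flag[eligible[list(inc_sel)]] = True
    else:
        incompatible_flag = np.zeros(n, dtype=bool)
        incompatible_flag[eligible] = (
            rng.random(len(eligible)) < prof.rate_incompatible_diagnosis
        )

    n_conditions = rng.integers(1, 4, size=n)

    # 8. assemble patient records
    patients: list[PatientRecord] = []
    for i in range(total):
        if missing[i]:
            gender: str | None = None
        elif unsupported[i]:
            gender = str(unsupported_tokens[i])
        else:
            gender = str(sex[i])
        patients.append(PatientRecord(
            id=ids[i],
            gender=gender,
            birth_date=birth_dates[i],
            deceased=True if deceased[i] else None,
            last_updated=updated[i],
        ))

    # 9. conditions, one batch per with-condition base id
    conditions: list[ConditionRecord] = []
    cond_no = 0
    for i in range(n):
        if not has_condition[i]:
            continue
        codes = list(rng.choice(icd.VALID_CODE_POOL, size=int(n_conditions[i])))
        if invalid_flag[i]:
            codes[0] = _invalid_code(rng)
        if incompatible_flag[i]:
            # the recorded gender of the base record decides the wrong-sex code
            pool = MALE_ONLY_CODES if sex[i] == "female" else FEMALE_ONLY_CODES
            codes.append(str(rng.choice(pool)))
        for code in codes:
            conditions.append(ConditionRecord(
                id=f"cond-{cond_no:06d}",
                patient_ref=base_ids[i],
                code=str(code),
                coding_system=ICD10_SYSTEM,
            ))
            cond_no += 1

    # 10. specimens spread over records (multinomial), so one patient can
    # contribute many samples (the sensitivity > 1 scenario)
    specimens: list[SpecimenRecord] = []
    if spec.n_specimens:
        counts = rng.multinomial(spec.n_specimens, np.full(total, 1.0 / total))
        spec_types = rng.choice(SPECIMEN_TYPE_POOL, size=spec.n_specimens)
        spec_ages = rng.integers(0, 5 * 365, size=spec.n_specimens)
        j = 0
        for i in range(total):
            for _ in range(int(counts[i])):
                specimens.append(SpecimenRecord(
                    id=f"spec-{j:06d}",
                    patient_ref=ids[i],
                    type_code=str(spec_types[j]),
                    collected=ref - timedelta(days=int(spec_ages[j])),
                ))
                j += 1

    return Dataset(
        patients=patients,
        conditions=conditions,
        specimens=specimens,
        reference_date=ref,
    )


# ---------------------------------------------------------------------------
# description / expectations


def describe_cohort(dataset: Dataset) -> pd.DataFrame:
    """Recount the injected error classes, independently of the check engine.

    Vectorised pandas recount over the dataset, giving per-class counts and
    denominators for generator-vs-engine cross-validation.
    """
    pats = pd.DataFrame({
        "id": [p.id for p in dataset.patients],
        "gender": [p.gender for p in dataset.patients],
        "birth_date": [p.birth_date for p in dataset.patients],
        "deceased": [p.deceased is True for p in dataset.patients],
        "last_updated": [
            p.last_updated.date() if p.last_updated else None
            for p in dataset.patients
        ],
    })
    total = len(pats)
    ref = dataset.reference_date

    conds = pd.DataFrame({
        "patient_ref": [c.patient_ref for c in dataset.conditions],
        "code": [c.code for c in dataset.conditions],
    })
    ids_with_cond = set(conds["patient_ref"]) if len(conds) else set()

    missing = pats["gender"].isna() | (pats["gender"] == "")
    unsupported = ~missing & ~pats["gender"].isin(sorted(SUPPORTED_GENDERS))
    no_condition = ~pats["id"].isin(ids_with_cond)

    if len(conds):
        conds["valid"] = conds["code"].map(icd.is_valid_icd10)
        invalid_ids = set(conds.loc[~conds["valid"], "patient_ref"])
    else:
        invalid_ids = set()
    invalid = pats["id"].isin(invalid_ids)

    def _record_incompatible(row: pd.Series) -> bool:
        if row["id"] not in ids_with_cond:
            return False
        codes = conds.loc[conds["patient_ref"] == row["id"], "code"]
        return any(icd.is_incompatible(row["gender"], c) for c in codes)

    incompatible = pats.apply(_record_incompatible, axis=1) if len(conds) else (
        pd.Series(False, index=pats.index)
    )

    dob_anomaly = pats["birth_date"].map(
        lambda b: b is not None and (b < DOB_FLOOR or b > ref)
    )
    stale = pats["last_updated"].map(
        lambda u: u is None or (ref - u).days > STALE_AFTER_DAYS
    )
    duplicates = total - pats["id"].nunique()

    rows = {
        "missing_gender": (int(missing.sum()), total),
        "unsupported_gender": (int(unsupported.sum()), total),
        "missing_condition": (int(no_condition.sum()), total),
        "invalid_icd10": (int(invalid.sum()), total),
        "incompatible_diagnosis": (int(incompatible.sum()), total),
        "dob_anomaly": (int(dob_anomaly.sum()), total),
        "stale_update": (int(stale.sum()), total),
        "duplicate_records": (duplicates, total),
    }
    for stratum in ("female", "male"):
        members = pats[pats["gender"] == stratum]
        rows[f"alive_{stratum}"] = (int((~members["deceased"]).sum()), len(members))

    df = pd.DataFrame.from_dict(rows, orient="index", columns=["count", "population"])
    df["rate"] = df["count"] / df["population"].where(df["population"] > 0)
    return df


#: Maps describe_cohort row labels to (check_id, stratum) of the check engine.
CLASS_TO_CHECK = {
    "incompatible_diagnosis": ("accuracy-1", None),
    "dob_anomaly": ("accuracy-2", None),
    "missing_gender": ("completeness-1", None),
    "missing_condition": ("completeness-2", None),
    "unsupported_gender": ("consistency-1", None),
    "stale_update": ("timeliness-1", None),
    "invalid_icd10": ("validity-1", None),
    "duplicate_records": ("uniqueness-1", None),
    "alive_female": ("accuracy-3", "female"),
    "alive_male": ("accuracy-3", "male"),
}


def expected_rates(profile: ErrorProfile, n_patients: int,
                   n_duplicates: int | None = None) -> dict[str, float]:
    """Expected *observed* raw rate per check under this profile.

    Conditional rates are folded with their conditioning probabilities;
    keys are ``check_id`` or ``check_id/stratum``.
    """
    d = n_duplicates if n_duplicates is not None else math.ceil(
        profile.rate_duplicate_id * n_patients)
    total = n_patients + d
    rm, ru = profile.rate_missing_gender, profile.rate_unsupported_gender
    rnc = profile.rate_missing_condition
    return {
        "completeness-1": rm,
        "consistency-1": ru,
        "completeness-2": rnc,
        "validity-1": profile.rate_invalid_icd10 * (1.0 - rnc),
        "accuracy-1": profile.rate_incompatible_diagnosis * (1.0 - rnc) * (1.0 - rm - ru),
        "accuracy-2": profile.rate_dob_anomaly,
        "timeliness-1": profile.rate_stale_update,
        "uniqueness-1": d / total if total else 0.0,
        "accuracy-3/female": profile.survival_rate_by_gender.get("female", 1.0),
        "accuracy-3/male": profile.survival_rate_by_gender.get("male", 1.0),
    }
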