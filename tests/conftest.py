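from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import pytest

from dpqc import (
    CohortSpec,
    ConditionRecord,
    Dataset,
    PatientRecord,
    default_profile,
    generate_cohort,
)

REF_DATE = date(2025, 1, 1)


def make_patient(pid: str, gender: str | None = "female",
                 birth_date: date | None = date(1980, 6, 15),
                 deceased: bool | None = None,
                 updated_days_ago: int | None = 30) -> PatientRecord:
    last_updated = None
    if updated_days_ago is not None:
        last_updated = datetime.combine(
            REF_DATE, datetime.min.time(), tzinfo=timezone.utc
        ) - timedelta(days=updated_days_ago)
    return PatientRecord(id=pid, gender=gender, birth_date=birth_date,
                         deceased=deceased, last_updated=last_updated)


def make_dataset(patients, conditions=(), specimens=(),
                 reference_date: date = REF_DATE) -> Dataset:
    return Dataset(patients=list(patients), conditions=list(conditions),
                   specimens=list(specimens), reference_date=reference_date)


def condition(cid: str, pid: str, code: str | None) -> ConditionRecord:
    return ConditionRecord(id=cid, patient_ref=pid, code=code,
                           coding_system="http://hl7.org/fhir/sid/icd-10")


@pytest.fixture(scope="session")
def default_cohort() -> Dataset:
    """A 1000-patient cohort with the default error profile, fixed seed."""
    return generate_cohort(CohortSpec(
        n_patients=1000, n_specimens=2000, seed=42, profile=default_profile(),
        reference_date=REF_DATE,
    ))


@pytest.fixture(scope="session")
def clean_cohort() -> Dataset:
    """A small cohort with no injected errors at all."""
    from dpqc import zero_profile

    return generate_cohort(CohortSpec(
        n_patients=60, n_specimens=120, seed=7, profile=zero_profile(),
        reference_date=REF_DATE,
    ))
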