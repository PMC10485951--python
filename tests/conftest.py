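import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from ssi_sentinel.model import (
    AdmissionEpisode,
    CohortData,
    EventStreams,
    ReferenceAnnotation,
    SurgeryRecord,
    SurveillanceWindowConfig,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")

SURGERY_DATE = dt.date(2017, 6, 1)


@pytest.fixture
def window() -> SurveillanceWindowConfig:
    return SurveillanceWindowConfig()


@pytest.fixture
def surgery() -> SurgeryRecord:
    return SurgeryRecord(
        surgery_id="S001",
        patient_id="P001",
        surgery_date=SURGERY_DATE,
        specialty="colorectal_surgery",
        department="colorectal_surgery_solna",
    )


def on_day(day_index: int, surgery_date: dt.date = SURGERY_DATE) -> dt.date:
    """Calendar date for a 1-anchored day index (surgery day = 1)."""
    return surgery_date + dt.timedelta(days=day_index - 1)


@pytest.fixture
def tiny_cohort(surgery) -> CohortData:
    """Three surgeries, one admission each, one annotated deep SSI."""
    surgeries = [surgery]
    for i in (2, 3):
        surgeries.append(
            SurgeryRecord(
                surgery_id=f"S00{i}",
                patient_id=f"P00{i}",
                surgery_date=SURGERY_DATE + dt.timedelta(days=10 * i),
                specialty="colorectal_surgery",
                department="colorectal_surgery_solna",
            )
        )
    admissions = [
        AdmissionEpisode(
            patient_id=s.patient_id,
            admit_date=s.surgery_date - dt.timedelta(days=1),
            discharge_date=s.surgery_date + dt.timedelta(days=5),
            department=s.department,
        )
        for s in surgeries
    ]
    reference = [
        ReferenceAnnotation(surgery_id=s.surgery_id, deep_ssi=(s.surgery_id == "S001"))
        for s in surgeries
    ]
    return CohortData(
        surgeries=surgeries,
        events=EventStreams(admissions=admissions),
        reference=reference,
    )
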