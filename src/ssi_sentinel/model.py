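"""Typed data model for the surveillance pipeline.

All records the pipeline consumes are pydantic models with day-resolution
calendar dates (temporal windows in this surveillance design are expressed
in whole days; within-day ordering is not modelled). Identifiers are opaque
strings.
"""
from __future__ import annotations

import datetime as dt
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Covariates",
    "SurgeryRecord",
    "AdmissionEpisode",
    "ReoperationRecord",
    "RadiologyOrder",
    "AntibioticAdministration",
    "MicrobiologyCulture",
    "ReferenceAnnotation",
    "EventStreams",
    "CohortData",
    "SurveillanceWindowConfig",
    "ValidationIssue",
    "validate_cohort",
    "DEFAULT_RELEVANT_SITES",
]

#: Default mapping of culture body sites considered relevant for deep SSI.
#: Editable: pass your own set to the CSV reader when your lab uses other
#: site labels.
DEFAULT_RELEVANT_SITES: frozenset[str] = frozenset(
    {"abdominal", "pelvic", "wound", "drain", "blood"}
)


class Covariates(BaseModel):
    """Descriptive passthrough fields; never used by any algorithm."""

    age_years: Optional[float] = None
    sex: Optional[str] = None
    bmi: Optional[float] = None
    asa_class: Optional[int] = None
    wound_class: Optional[str] = None
    duration_minutes: Optional[float] = None
    stoma: Optional[bool] = None
    primary: Optional[bool] = None
    open_procedure: Optional[bool] = None
    malignancy: Optional[bool] = None


class SurgeryRecord(BaseModel):
    """Index colorectal surgery anchoring all temporal windows."""

    surgery_id: str
    patient_id: str
    surgery_date: dt.date
    specialty: str
    department: str
    covariates: Covariates = Field(default_factory=Covariates)


class AdmissionEpisode(BaseModel):
    """Hospital admission episode; an open stay has no discharge date.

    In-hospital death is carried here (``died_in_hospital``); the death
    date is the discharge date of the episode in which the patient died.
    """

    patient_id: str
    admit_date: dt.date
    discharge_date: Optional[dt.date] = None
    department: str
    died_in_hospital: bool = False

    @model_validator(mode="after")
    def _discharge_after_admit(self) -> "AdmissionEpisode":
        if self.discharge_date is not None and self.discharge_date < self.admit_date:
            raise ValueError(
                f"discharge_date {self.discharge_date} precedes admit_date {self.admit_date}"
            )
        return self


class ReoperationRecord(BaseModel):
    patient_id: str
    procedure_date: dt.date
    specialty: str


class RadiologyOrder(BaseModel):
    patient_id: str
    order_date: dt.date
    modality: str


class AntibioticAdministration(BaseModel):
    patient_id: str
    administration_date: dt.date
    atc_code: str

    @field_validator("atc_code")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("atc_code must be non-empty")
        return v.strip()


class MicrobiologyCulture(BaseModel):
    patient_id: str
    sample_date: dt.date
    body_site: str
    relevant_site: bool


class ReferenceAnnotation(BaseModel):
    """Reference-standard label: deep/organ-space SSI within 30 days,
    annotated by an infection control practitioner by chart review."""

    surgery_id: str
    deep_ssi: bool
    annotator_id: str = "icp-1"


class EventStreams(BaseModel):
    """Per-cohort event collections, one list per event type."""

    admissions: list[AdmissionEpisode] = Field(default_factory=list)
    reoperations: list[ReoperationRecord] = Field(default_factory=list)
    radiology: list[RadiologyOrder] = Field(default_factory=list)
    antibiotics: list[AntibioticAdministration] = Field(default_factory=list)
    microbiology: list[MicrobiologyCulture] = Field(default_factory=list)


class CohortData(BaseModel):
    surgeries: list[SurgeryRecord] = Field(default_factory=list)
    events: EventStreams = Field(default_factory=EventStreams)
    reference: list[ReferenceAnnotation] = Field(default_factory=list)

    def surgery(self, surgery_id: str) -> SurgeryRecord:
        for s in self.surgeries:
            if s.surgery_id == surgery_id:
                return s
        raise KeyError(surgery_id)


class SurveillanceWindowConfig(BaseModel):
    """Temporal-window parameters of the component definitions.

    The surgery day is day 1. Components are evaluated within the
    follow-up window day 1..fu_days inclusive (default 45 days after
    surgery); the reference-standard SSI window (30 days) is documentation
    only — the manual annotation is an input, never recomputed here.
    """

    fu_days: int = 45
    ssi_window_days: int = 30
    los_threshold_days: int = 14
    abx_min_consecutive_days: int = 3
    abx_earliest_start_day: int = 2
    culture_earliest_day: int = 1
    abx_atc_prefix: str = "J01"
    radiology_modalities: set[str] = Field(default_factory=lambda: {"CT"})
    #: whether length of stay is counted from the surgery date (default)
    #: or from the index admission date
    los_from: Literal["surgery", "admission"] = "surgery"

    @model_validator(mode="after")
    def _check(self) -> "SurveillanceWindowConfig":
        for name in (
            "fu_days",
            "ssi_window_days",
            "los_threshold_days",
            "abx_min_consecutive_days",
            "abx_earliest_start_day",
            "culture_earliest_day",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fu_days < self.ssi_window_days:
            raise ValueError("fu_days must be >= ssi_window_days")
        return self


class ValidationIssue(BaseModel):
    severity: Literal["error", "warning"]
    table: str
    record: str
    message: str


def validate_cohort(cohort: CohortData) -> list[ValidationIssue]:
    """Cross-record integrity checks.

    Returns an empty list iff all invariants hold. Per-record invariants
    (date ordering, non-empty codes) are enforced at construction; this
    checks referential integrity: unique surgery ids, resolvable patient
    ids on every event, resolvable surgery ids on every annotation.
    Deterministic and independent of row order.
    """
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for s in cohort.surgeries:
        if s.surgery_id in seen:
            issues.append(
                ValidationIssue(
                    severity="error",
                    table="surgeries",
                    record=s.surgery_id,
                    message=f"duplicate surgery_id {s.surgery_id!r}",
                )
            )
        seen.add(s.surgery_id)
    patients = {s.patient_id for s in cohort.surgeries}

    streams: list[tuple[str, list]] = [
        ("admissions", cohort.events.admissions),
        ("reoperations", cohort.events.reoperations),
        ("radiology", cohort.events.radiology),
        ("antibiotics", cohort.events.antibiotics),
        ("microbiology", cohort.events.microbiology),
    ]
    for table, records in streams:
        for rec in records:
            if rec.patient_id not in patients:
                issues.append(
                    ValidationIssue(
                        severity="error",
                        table=table,
                        record=rec.patient_id,
                        message=f"{table}: patient_id {rec.patient_id!r} has no surgery in the cohort",
                    )
                )
    for ann in cohort.reference:
        if ann.surgery_id not in seen:
            issues.append(
                ValidationIssue(
                    severity="error",
                    table="reference",
                    record=ann.surgery_id,
                    message=f"reference annotation for unknown surgery_id {ann.surgery_id!r}",
                )
            )
    issues.sort(key=lambda i: (i.table, i.record, i.message))
    return issues
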