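"""Extraction of the five binary surveillance components per surgery.

Day convention: the surgery day is day 1, so ``day_index = (event_date -
surgery_date).days + 1``. "Starting after day 1" means the first day of a
qualifying antibiotic run is day >= 2; "prior to day 1" means strictly
pre-surgery. The follow-up window is day 1..fu_days inclusive (default 45
days after surgery).

The five components:

* admissions    — length of stay >= 14 days, or a readmission to the
                  original department, or in-hospital death, within follow-up
* reoperation   — any reoperation by the original surgery specialty
* radiology     — >= 1 CT order
* antibiotics   — >= 3 consecutive days of systemic antibacterials (ATC J01),
                  the run starting no earlier than day 2
* microbiology  — >= 1 culture from a relevant body site, cultures strictly
                  before the surgery day excluded
"""
from __future__ import annotations

import datetime as dt
import warnings
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, model_validator

from .model import (
    AdmissionEpisode,
    AntibioticAdministration,
    CohortData,
    MicrobiologyCulture,
    RadiologyOrder,
    ReoperationRecord,
    SurgeryRecord,
    SurveillanceWindowConfig,
)

__all__ = [
    "COMPONENT_NAMES",
    "ComponentProfile",
    "SurveillanceWarning",
    "day_index",
    "has_consecutive_run",
    "admissions_component",
    "reoperation_component",
    "radiology_component",
    "antibiotics_component",
    "microbiology_component",
    "extract_profile",
    "extract_profiles",
]

COMPONENT_NAMES: tuple[str, ...] = (
    "admissions",
    "reoperation",
    "radiology",
    "antibiotics",
    "microbiology",
)


class SurveillanceWarning(UserWarning):
    """Non-fatal extraction anomaly (e.g. no index admission found)."""


class ComponentProfile(BaseModel):
    """The five binary components plus their count for one surgery."""

    surgery_id: str
    admissions: bool
    reoperation: bool
    radiology: bool
    antibiotics: bool
    microbiology: bool
    count: int

    @model_validator(mode="after")
    def _count_consistent(self) -> "ComponentProfile":
        total = sum(int(getattr(self, name)) for name in COMPONENT_NAMES)
        if self.count != total:
            raise ValueError(f"count {self.count} != number of true flags {total}")
        return self

    @classmethod
    def from_flags(cls, surgery_id: str, **flags: bool) -> "ComponentProfile":
        return cls(surgery_id=surgery_id, count=sum(map(int, flags.values())), **flags)

    def flags(self) -> dict[str, bool]:
        return {name: bool(getattr(self, name)) for name in COMPONENT_NAMES}


def day_index(event_date: dt.date, surgery_date: dt.date) -> int:
    """Day number of an event relative to surgery; surgery day = 1.

    May be <= 0 for pre-surgery events.
    """
    return (event_date - surgery_date).days + 1


def has_consecutive_run(
    day_indices: Iterable[int], min_len: int, earliest_start: int, latest_day: int
) -> bool:
    """True iff some ``min_len`` consecutive day indices are all present,
    the first >= ``earliest_start`` and the last <= ``latest_day``.

    Equivalently: after restricting to the window, the longest streak of
    consecutive present days reaches ``min_len``. A run straddling the
    window edge is truncated at the edge before the length test. The
    existential (sub-run) reading keeps the decision monotone: adding
    administration days can never disqualify a qualifying course.
    """
    days = sorted({d for d in day_indices if earliest_start <= d <= latest_day})
    streak = 0
    prev: Optional[int] = None
    for d in days:
        streak = streak + 1 if prev is not None and d == prev + 1 else 1
        if streak >= min_len:
            return True
        prev = d
    return min_len <= 0


def _index_admission(
    surgery: SurgeryRecord, episodes: list[AdmissionEpisode]
) -> Optional[AdmissionEpisode]:
    """Earliest episode whose [admit, discharge] interval contains the
    surgery date (open discharge = ongoing)."""
    candidates = [
        ep
        for ep in episodes
        if ep.admit_date <= surgery.surgery_date
        and (ep.discharge_date is None or ep.discharge_date >= surgery.surgery_date)
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda ep: ep.admit_date)


def admissions_component(
    surgery: SurgeryRecord,
    episodes: Iterable[AdmissionEpisode],
    cfg: SurveillanceWindowConfig,
) -> bool:
    """Prolonged stay, same-department readmission, or in-hospital death.

    True iff (a) stay from surgery (or admission, per ``cfg.los_from``) to
    index discharge >= los_threshold_days, with an open or post-window
    discharge counting as prolonged; or (b) a readmission to the original
    department admits on day 1..fu_days; or (c) an in-hospital death falls
    on day 1..fu_days (death date = discharge date of the fatal episode).
    """
    eps = [ep for ep in episodes if ep.patient_id == surgery.patient_id]
    index = _index_admission(surgery, eps)
    if index is None:
        warnings.warn(
            f"surgery {surgery.surgery_id}: no admission episode contains the "
            "surgery date; admissions component evaluated on readmission/"
            "mortality arms only",
            SurveillanceWarning,
            stacklevel=2,
        )
    else:
        if index.discharge_date is None:
            return True
        if day_index(index.discharge_date, surgery.surgery_date) > cfg.fu_days:
            return True
        start = surgery.surgery_date if cfg.los_from == "surgery" else index.admit_date
        if (index.discharge_date - start).days >= cfg.los_threshold_days:
            return True
    for ep in eps:
        if ep is index:
            continue
        if (
            ep.department == surgery.department
            and 1 <= day_index(ep.admit_date, surgery.surgery_date) <= cfg.fu_days
        ):
            return True
    for ep in eps:
        if not ep.died_in_hospital:
            continue
        if ep.discharge_date is None:
            warnings.warn(
                f"surgery {surgery.surgery_id}: episode flagged died_in_hospital "
                "has no discharge (death) date; mortality arm skipped",
                SurveillanceWarning,
                stacklevel=2,
            )
            continue
        if 1 <= day_index(ep.discharge_date, surgery.surgery_date) <= cfg.fu_days:
            return True
    return False


def reoperation_component(
    surgery: SurgeryRecord,
    reoperations: Iterable[ReoperationRecord],
    cfg: SurveillanceWindowConfig,
) -> bool:
    """Any reoperation by the original surgery specialty on day 2..fu_days.

    Day >= 2 excludes the index procedure itself.
    """
    return any(
        r.patient_id == surgery.patient_id
        and r.specialty == surgery.specialty
        and 2 <= day_index(r.procedure_date, surgery.surgery_date) <= cfg.fu_days
        for r in reoperations
    )


def radiology_component(
    surgery: SurgeryRecord,
    orders: Iterable[RadiologyOrder],
    cfg: SurveillanceWindowConfig,
) -> bool:
    """>= 1 order of a surveillance modality (default CT) on day 1..fu_days."""
    return any(
        o.patient_id == surgery.patient_id
        and o.modality in cfg.radiology_modalities
        and 1 <= day_index(o.order_date, surgery.surgery_date) <= cfg.fu_days
        for o in orders
    )


def antibiotics_component(
    surgery: SurgeryRecord,
    administrations: Iterable[AntibioticAdministration],
    cfg: SurveillanceWindowConfig,
) -> bool:
    """>= 3 consecutive distinct days of ATC-J01 administration, run start
    on day >= 2 (a run starting on the surgery day reads as prophylaxis),
    run end <= fu_days. Doses per day and route are ignored."""
    days = {
        day_index(a.administration_date, surgery.surgery_date)
        for a in administrations
        if a.patient_id == surgery.patient_id
        and a.atc_code.startswith(cfg.abx_atc_prefix)
    }
    return has_consecutive_run(
        days, cfg.abx_min_consecutive_days, cfg.abx_earliest_start_day, cfg.fu_days
    )


def microbiology_component(
    surgery: SurgeryRecord,
    cultures: Iterable[MicrobiologyCulture],
    cfg: SurveillanceWindowConfig,
) -> bool:
    """>= 1 relevant-site culture on day culture_earliest_day..fu_days;
    pre-surgery cultures (day <= 0) never count."""
    return any(
        c.patient_id == surgery.patient_id
        and c.relevant_site
        and cfg.culture_earliest_day
        <= day_index(c.sample_date, surgery.surgery_date)
        <= cfg.fu_days
        for c in cultures
    )


def extract_profile(
    surgery: SurgeryRecord,
    cohort: CohortData,
    cfg: Optional[SurveillanceWindowConfig] = None,
) -> ComponentProfile:
    """Assemble the full five-component profile for one surgery."""
    cfg = cfg or SurveillanceWindowConfig()
    ev = cohort.events
    return ComponentProfile.from_flags(
        surgery.surgery_id,
        admissions=admissions_component(surgery, ev.admissions, cfg),
        reoperation=reoperation_component(surgery, ev.reoperations, cfg),
        radiology=radiology_component(surgery, ev.radiology, cfg),
        antibiotics=antibiotics_component(surgery, ev.antibiotics, cfg),
        microbiology=microbiology_component(surgery, ev.microbiology, cfg),
    )


def extract_profiles(
    cohort: CohortData, cfg: Optional[SurveillanceWindowConfig] = None
) -> pd.DataFrame:
    """Profiles for every surgery, as a DataFrame with columns
    surgery_id, the five component flags, and count. Surgery order is
    preserved. Events are pre-grouped by patient for speed."""
    cfg = cfg or SurveillanceWindowConfig()

    def group(records):
        by: dict[str, list] = {}
        for r in records:
            by.setdefault(r.patient_id, []).append(r)
        return by

    ev = cohort.events
    adm, reop = group(ev.admissions), group(ev.reoperations)
    rad, abx, mic = group(ev.radiology), group(ev.antibiotics), group(ev.microbiology)
    rows = []
    for s in cohort.surgeries:
        pid = s.patient_id
        flags = {
            "admissions": admissions_component(s, adm.get(pid, []), cfg),
            "reoperation": reoperation_component(s, reop.get(pid, []), cfg),
            "radiology": radiology_component(s, rad.get(pid, []), cfg),
            "antibiotics": antibiotics_component(s, abx.get(pid, []), cfg),
            "microbiology": microbiology_component(s, mic.get(pid, []), cfg),
        }
        rows.append({"surgery_id": s.surgery_id, **flags, "count": sum(map(int, flags.values()))})
    return pd.DataFrame(
        rows, columns=["surgery_id", *COMPONENT_NAMES, "count"]
    )
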