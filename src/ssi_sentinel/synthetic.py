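"""Synthetic colorectal-surgery cohorts with the statistical structure of
the validation setting: 18.2% deep-SSI prevalence, the observed component
prevalences, and an SSI-component association calibrated so the two
built-in rules behave directionally like the published evaluation.

The generator works in two stages. ``sample_cohort`` draws, per surgery,
the deep-SSI flag (Bernoulli) and the five component indicators,
conditionally independent given SSI status. ``realize_events`` turns each
planted indicator into concrete event rows that satisfy the component
predicate — and, for each *false* indicator, emits only non-qualifying
distractors (day-1 prophylactic antibiotic runs, pre-operative cultures,
non-CT imaging, wrong-specialty reoperations, other-department
readmissions, out-of-window events) — so that component extraction
recovers the planted indicator vector exactly.

Components are modelled conditionally independent given SSI status: only
marginal prevalences are observable from published summaries, and this is
the minimal structure that exercises both algorithms. The conditional
probability table is fully user-overridable.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .components import COMPONENT_NAMES, SurveillanceWindowConfig, has_consecutive_run
from .model import (
    AdmissionEpisode,
    AntibioticAdministration,
    CohortData,
    Covariates,
    EventStreams,
    MicrobiologyCulture,
    RadiologyOrder,
    ReferenceAnnotation,
    ReoperationRecord,
    SurgeryRecord,
)

__all__ = [
    "GeneratorConfig",
    "PlantedCohort",
    "RealizationError",
    "default_generator_config",
    "implied_marginals",
    "sample_cohort",
    "realize_events",
    "generate_cohort",
    "simulate_second_annotator",
]

#: Published marginal component prevalences the defaults are calibrated to.
TARGET_MARGINALS: dict[str, float] = {
    "admissions": 0.387,
    "reoperation": 0.178,
    "radiology": 0.476,
    "antibiotics": 0.413,
    "microbiology": 0.311,
}

#: P(component | deep SSI): deep infections strongly drive CT orders,
#: therapeutic antibiotic courses and prolonged stay/readmission; cultures
#: are taken in most but not all suspected cases; reoperation is the least
#: constant response. Values < 1 everywhere make an occasional
#: zero-component SSI possible, as observed in practice.
DEFAULT_COMPONENT_GIVEN_SSI: dict[str, float] = {
    "admissions": 0.85,
    "reoperation": 0.55,
    "radiology": 0.90,
    "antibiotics": 0.90,
    "microbiology": 0.83,
}

_RELEVANT_SITES = ("abdominal", "pelvic", "wound", "drain", "blood")
_IRRELEVANT_SITES = ("urine", "nasopharynx", "sputum")
_J01_CODES = ("J01CA04", "J01DD04", "J01XD01", "J01MA02", "J01CR02")
_NON_J01_CODES = ("J02AC01", "J04AB02")
_OTHER_MODALITIES = ("MR", "US", "XR")
_DEPARTMENTS = ("colorectal_surgery_solna", "colorectal_surgery_huddinge")
_OTHER_DEPARTMENT = "internal_medicine"
_SPECIALTY = "colorectal_surgery"
_OTHER_SPECIALTY = "orthopaedic_surgery"

# substream ids: adding a stream appends an id, never renumbers, so new
# event types do not perturb existing draws for a given master seed
_STREAMS = {
    "surgeries": 0,
    "ssi": 1,
    "indicators": 2,
    "covariates": 3,
    "admissions": 4,
    "reoperations": 5,
    "radiology": 6,
    "antibiotics": 7,
    "microbiology": 8,
    "annotator": 9,
}


class RealizationError(RuntimeError):
    """Raised when distractor settings would violate a planted indicator."""


class GeneratorConfig(BaseModel):
    n_surgeries: int = 225
    ssi_prevalence: float = 0.182
    component_given_ssi: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_GIVEN_SSI)
    )
    component_given_no_ssi: dict[str, float] = Field(default_factory=dict)
    #: per-surgery emission probabilities of non-qualifying events
    distractor_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "prophylactic_antibiotics": 0.60,
            "short_antibiotic_course": 0.10,
            "non_j01_course": 0.05,
            "preop_culture": 0.15,
            "nonrelevant_culture": 0.10,
            "non_ct_imaging": 0.30,
            "preop_ct": 0.10,
            "other_department_readmission": 0.08,
            "wrong_specialty_reoperation": 0.04,
            "late_reoperation": 0.03,
        }
    )
    annotator_disagreement: float = 0.05
    #: passthrough descriptor distributions (medians/IQRs of the emulated
    #: cohort); none of these feed any algorithm
    covariate_distributions: dict[str, float] = Field(
        default_factory=lambda: {
            "age_median": 66.0,
            "age_iqr_low": 55.0,
            "age_iqr_high": 75.0,
            "female_fraction": 0.489,
            "bmi_median": 25.6,
            "bmi_iqr_low": 22.3,
            "bmi_iqr_high": 29.4,
            "duration_median": 316.0,
            "duration_iqr_low": 206.0,
            "duration_iqr_high": 427.0,
            "asa_ge3_fraction": 0.365,
            "contaminated_wound_fraction": 0.240,
            "stoma_fraction": 0.418,
            "primary_fraction": 0.636,
            "open_fraction": 0.773,
            "malignancy_fraction": 0.769,
        }
    )
    seed: int = 0

    @model_validator(mode="after")
    def _fill_and_check(self) -> "GeneratorConfig":
        if not 0.0 <= self.ssi_prevalence <= 1.0:
            raise ValueError("ssi_prevalence must be in [0, 1]")
        missing = set(COMPONENT_NAMES) - set(self.component_given_ssi)
        if missing:
            raise ValueError(f"component_given_ssi missing {sorted(missing)}")
        if not self.component_given_no_ssi:
            # derive P(c | no SSI) so implied marginals hit the published
            # prevalences exactly: b = (m - p*a) / (1 - p)
            p = self.ssi_prevalence
            self.component_given_no_ssi = {
                c: (TARGET_MARGINALS[c] - p * self.component_given_ssi[c]) / (1.0 - p)
                if p < 1.0
                else 0.0
                for c in COMPONENT_NAMES
            }
        missing = set(COMPONENT_NAMES) - set(self.component_given_no_ssi)
        if missing:
            raise ValueError(f"component_given_no_ssi missing {sorted(missing)}")
        for table in (self.component_given_ssi, self.component_given_no_ssi):
            for c, v in table.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"P({c}) = {v} outside [0, 1]")
        for c in COMPONENT_NAMES:
            m = implied_marginal(self, c)
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"implied marginal for {c} = {m} outside [0, 1]")
        return self


def implied_marginal(cfg: GeneratorConfig, component: str) -> float:
    p = cfg.ssi_prevalence
    return p * cfg.component_given_ssi[component] + (1.0 - p) * cfg.component_given_no_ssi[component]


def implied_marginals(cfg: GeneratorConfig) -> dict[str, float]:
    """Marginal component prevalence implied by the conditional table."""
    return {c: implied_marginal(cfg, c) for c in COMPONENT_NAMES}


def default_generator_config(seed: int = 0) -> GeneratorConfig:
    """Study-condition defaults: n=225, 18.2% deep-SSI prevalence,
    conditionals calibrated so implied marginals equal the published
    component prevalences (38.7, 17.8, 47.6, 41.3, 31.1%)."""
    return GeneratorConfig(seed=seed)


@dataclass
class PlantedCohort:
    """A cohort plus its planted truth: per surgery the deep-SSI flag and
    the five intended component indicators (DataFrame columns surgery_id,
    deep_ssi, admissions, reoperation, radiology, antibiotics,
    microbiology)."""

    cohort: CohortData
    truth: pd.DataFrame


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg_seed, spawn_key=(_STREAMS[stream],))
    )


def _skew_normal_from_quartiles(
    rng: np.random.Generator, n: int, med: float, q1: float, q3: float,
    low: float, high: float,
) -> np.ndarray:
    # normal matched to median and IQR, clipped to a plausible range
    sd = (q3 - q1) / 1.349
    return np.clip(rng.normal(med, sd, size=n), low, high)


def _sample_covariates(cfg: GeneratorConfig, n: int) -> list[Covariates]:
    rng = _rng(cfg.seed, "covariates")
    cd = cfg.covariate_distributions
    age = _skew_normal_from_quartiles(
        rng, n, cd["age_median"], cd["age_iqr_low"], cd["age_iqr_high"], 18, 95
    ).round(0)
    bmi = _skew_normal_from_quartiles(
        rng, n, cd["bmi_median"], cd["bmi_iqr_low"], cd["bmi_iqr_high"], 14, 55
    ).round(1)
    dur = _skew_normal_from_quartiles(
        rng, n, cd["duration_median"], cd["duration_iqr_low"], cd["duration_iqr_high"], 30, 900
    ).round(0)
    female = rng.random(n) < cd["female_fraction"]
    asa_hi = rng.random(n) < cd["asa_ge3_fraction"]
    asa = np.where(asa_hi, rng.integers(3, 5, size=n), rng.integers(1, 3, size=n))
    dirty = rng.random(n) < cd["contaminated_wound_fraction"]
    stoma = rng.random(n) < cd["stoma_fraction"]
    primary = rng.random(n) < cd["primary_fraction"]
    open_ = rng.random(n) < cd["open_fraction"]
    malig = rng.random(n) < cd["malignancy_fraction"]
    return [
        Covariates(
            age_years=float(age[i]),
            sex="F" if female[i] else "M",
            bmi=float(bmi[i]),
            asa_class=int(asa[i]),
            wound_class="contaminated-dirty" if dirty[i] else "clean-contaminated",
            duration_minutes=float(dur[i]),
            stoma=bool(stoma[i]),
            primary=bool(primary[i]),
            open_procedure=bool(open_[i]),
            malignancy=bool(malig[i]),
        )
        for i in range(n)
    ]


def sample_cohort(cfg: Optional[GeneratorConfig] = None) -> PlantedCohort:
    """Draw surgeries, deep-SSI flags and component indicators (no events
    yet). Deep SSI ~ Bernoulli(ssi_prevalence) i.i.d.; components are
    conditionally independent given SSI status. Reproducible by
    ``cfg.seed``; the reference annotation equals the planted SSI flag
    (the chart-review gold standard is taken as truth)."""
    cfg = cfg or default_generator_config()
    n = cfg.n_surgeries
    srng = _rng(cfg.seed, "surgeries")
    base = dt.date(2015, 1, 1)
    offsets = np.sort(srng.integers(0, 2069, size=n))  # Jan 2015 .. Aug 2020
    departments = srng.choice(_DEPARTMENTS, size=n)

    ssi = _rng(cfg.seed, "ssi").random(n) < cfg.ssi_prevalence
    irng = _rng(cfg.seed, "indicators")
    indicators = {}
    for c in COMPONENT_NAMES:
        p = np.where(ssi, cfg.component_given_ssi[c], cfg.component_given_no_ssi[c])
        indicators[c] = irng.random(n) < p

    covs = _sample_covariates(cfg, n)
    width = max(3, len(str(n)))
    surgeries = [
        SurgeryRecord(
            surgery_id=f"S{i + 1:0{width}d}",
            patient_id=f"P{i + 1:0{width}d}",
            surgery_date=base + dt.timedelta(days=int(offsets[i])),
            specialty=_SPECIALTY,
            department=str(departments[i]),
            covariates=covs[i],
        )
        for i in range(n)
    ]
    reference = [
        ReferenceAnnotation(surgery_id=s.surgery_id, deep_ssi=bool(ssi[i]), annotator_id="icp-1")
        for i, s in enumerate(surgeries)
    ]
    truth = pd.DataFrame(
        {
            "surgery_id": [s.surgery_id for s in surgeries],
            "deep_ssi": ssi,
            **{c: indicators[c] for c in COMPONENT_NAMES},
        }
    )
    return PlantedCohort(
        cohort=CohortData(surgeries=surgeries, reference=reference), truth=truth
    )


def _realize_admissions(
    s: SurgeryRecord, wanted: bool, rates: dict[str, float],
    rng: np.random.Generator, w: SurveillanceWindowConfig,
) -> list[AdmissionEpisode]:
    sd = s.surgery_date
    day = dt.timedelta
    admit = sd - day(int(rng.integers(0, 3)))
    eps: list[AdmissionEpisode] = []
    if wanted:
        arm = rng.choice(["los", "readmit", "death"], p=[0.6, 0.3, 0.1])
        if arm == "los":
            if rng.random() < 0.08:
                eps.append(AdmissionEpisode(patient_id=s.patient_id, admit_date=admit,
                                            discharge_date=None, department=s.department))
            else:
                off = int(rng.integers(w.los_threshold_days, 31))
                eps.append(AdmissionEpisode(patient_id=s.patient_id, admit_date=admit,
                                            discharge_date=sd + day(off), department=s.department))
        elif arm == "readmit":
            disc = int(rng.integers(2, min(11, w.los_threshold_days)))
            eps.append(AdmissionEpisode(patient_id=s.patient_id, admit_date=admit,
                                        discharge_date=sd + day(disc), department=s.department))
            re_admit = int(rng.integers(disc + 1, w.fu_days))  # day_index <= fu
            eps.append(AdmissionEpisode(patient_id=s.patient_id, admit_date=sd + day(re_admit),
                                        discharge_date=sd + day(re_admit + int(rng.integers(1, 8))),
                                        department=s.department))
        else:  # in-hospital death within follow-up
            off = int(rng.integers(2, w.fu_days))
            eps.append(AdmissionEpisode(patient_id=s.patient_id, admit_date=admit,
                                        discharge_date=sd + day(off), department=s.department,
                                        died_in_hospital=True))
    else:
        disc = int(rng.integers(2, min(11, w.los_threshold_days)))
        eps.append(AdmissionEpisode(patient_id=s.patient_id, admit_date=admit,
                                    discharge_date=sd + day(disc), department=s.department))
        if rng.random() < rates.get("other_department_readmission", 0.0):
            re_admit = int(rng.integers(disc + 1, w.fu_days))
            eps.append(AdmissionEpisode(patient_id=s.patient_id, admit_date=sd + day(re_admit),
                                        discharge_date=sd + day(re_admit + int(rng.integers(1, 8))),
                                        department=_OTHER_DEPARTMENT))
    return eps


def _realize_antibiotic_days(
    wanted: bool, rates: dict[str, float], rng: np.random.Generator,
    w: SurveillanceWindowConfig,
) -> list[int]:
    """Day indices of J01 administration. For a false indicator every
    distractor pattern is constructed so no qualifying run can arise even
    in union (prophylaxis ends by day 3; post-op distractors start at day
    >= 5 and are single, too short, or gapped)."""
    days: set[int] = set()
    if rng.random() < rates.get("prophylactic_antibiotics", 0.0):
        days.update(range(1, 1 + int(rng.integers(1, w.abx_min_consecutive_days + 1))))
    if wanted:
        length = int(rng.integers(w.abx_min_consecutive_days, w.abx_min_consecutive_days + 6))
        start = int(rng.integers(w.abx_earliest_start_day, w.fu_days - length + 2))
        days.update(range(start, start + length))
    else:
        kind = rng.choice(["none", "short", "gapped"],
                          p=[1 - rates.get("short_antibiotic_course", 0.0) * 2,
                             rates.get("short_antibiotic_course", 0.0),
                             rates.get("short_antibiotic_course", 0.0)])
        if kind == "short":
            start = int(rng.integers(5, w.fu_days - 1))
            days.update(range(start, start + min(2, w.abx_min_consecutive_days - 1)))
        elif kind == "gapped":
            start = int(rng.integers(5, w.fu_days - 4))
            days.update({start, start + 2, start + 4})
    return sorted(days)


def realize_events(
    planted: PlantedCohort,
    cfg: Optional[GeneratorConfig] = None,
    window: Optional[SurveillanceWindowConfig] = None,
) -> CohortData:
    """Emit event rows realizing every planted indicator under the
    component predicates, with non-qualifying distractors at the
    configured rates. The returned cohort carries the same surgeries and
    reference annotations; component extraction on it reproduces the
    planted indicator vectors exactly (violations raise
    ``RealizationError`` — they indicate an inconsistent configuration)."""
    cfg = cfg or default_generator_config()
    w = window or SurveillanceWindowConfig()
    rates = cfg.distractor_rates
    day = dt.timedelta

    a_rng = _rng(cfg.seed, "admissions")
    r_rng = _rng(cfg.seed, "reoperations")
    x_rng = _rng(cfg.seed, "radiology")
    b_rng = _rng(cfg.seed, "antibiotics")
    m_rng = _rng(cfg.seed, "microbiology")

    truth = planted.truth.set_index("surgery_id")
    ev = EventStreams()
    for s in planted.cohort.surgeries:
        want = truth.loc[s.surgery_id]
        sd = s.surgery_date

        ev.admissions.extend(_realize_admissions(s, bool(want["admissions"]), rates, a_rng, w))

        if want["reoperation"]:
            off = int(r_rng.integers(1, w.fu_days))  # day_index 2..fu
            ev.reoperations.append(ReoperationRecord(
                patient_id=s.patient_id, procedure_date=sd + day(off), specialty=s.specialty))
        else:
            if r_rng.random() < rates.get("wrong_specialty_reoperation", 0.0):
                off = int(r_rng.integers(1, w.fu_days))
                ev.reoperations.append(ReoperationRecord(
                    patient_id=s.patient_id, procedure_date=sd + day(off),
                    specialty=_OTHER_SPECIALTY))
            if r_rng.random() < rates.get("late_reoperation", 0.0):
                off = int(r_rng.integers(w.fu_days, w.fu_days + 16))
                ev.reoperations.append(ReoperationRecord(
                    patient_id=s.patient_id, procedure_date=sd + day(off), specialty=s.specialty))

        if want["radiology"]:
            off = int(x_rng.integers(0, w.fu_days))  # day_index 1..fu
            ev.radiology.append(RadiologyOrder(
                patient_id=s.patient_id, order_date=sd + day(off),
                modality=sorted(w.radiology_modalities)[0]))
        else:
            if x_rng.random() < rates.get("non_ct_imaging", 0.0):
                off = int(x_rng.integers(0, w.fu_days))
                ev.radiology.append(RadiologyOrder(
                    patient_id=s.patient_id, order_date=sd + day(off),
                    modality=str(x_rng.choice(_OTHER_MODALITIES))))
            if x_rng.random() < rates.get("preop_ct", 0.0):
                off = -int(x_rng.integers(1, 15))
                ev.radiology.append(RadiologyOrder(
                    patient_id=s.patient_id, order_date=sd + day(off),
                    modality=sorted(w.radiology_modalities)[0]))

        abx_days = _realize_antibiotic_days(bool(want["antibiotics"]), rates, b_rng, w)
        if bool(want["antibiotics"]) != has_consecutive_run(
            abx_days, w.abx_min_consecutive_days, w.abx_earliest_start_day, w.fu_days
        ):
            raise RealizationError(
                f"surgery {s.surgery_id}: antibiotic distractors violate the "
                f"planted indicator (days {abx_days})"
            )
        code = str(b_rng.choice(_J01_CODES))
        for d in abx_days:
            ev.antibiotics.append(AntibioticAdministration(
                patient_id=s.patient_id, administration_date=sd + day(d - 1), atc_code=code))
        if b_rng.random() < rates.get("non_j01_course", 0.0):
            start = int(b_rng.integers(2, w.fu_days - 3))
            non_code = str(b_rng.choice(_NON_J01_CODES))
            for d in range(start, start + 3):
                ev.antibiotics.append(AntibioticAdministration(
                    patient_id=s.patient_id, administration_date=sd + day(d - 1),
                    atc_code=non_code))

        if want["microbiology"]:
            off = int(m_rng.integers(w.culture_earliest_day - 1, w.fu_days))
            ev.microbiology.append(MicrobiologyCulture(
                patient_id=s.patient_id, sample_date=sd + day(off),
                body_site=str(m_rng.choice(_RELEVANT_SITES)), relevant_site=True))
        else:
            if m_rng.random() < rates.get("preop_culture", 0.0):
                off = -int(m_rng.integers(1, 8))
                ev.microbiology.append(MicrobiologyCulture(
                    patient_id=s.patient_id, sample_date=sd + day(off),
                    body_site=str(m_rng.choice(_RELEVANT_SITES)), relevant_site=True))
            if m_rng.random() < rates.get("nonrelevant_culture", 0.0):
                off = int(m_rng.integers(0, w.fu_days))
                ev.microbiology.append(MicrobiologyCulture(
                    patient_id=s.patient_id, sample_date=sd + day(off),
                    body_site=str(m_rng.choice(_IRRELEVANT_SITES)), relevant_site=False))

    return CohortData(
        surgeries=planted.cohort.surgeries,
        events=ev,
        reference=planted.cohort.reference,
    )


def generate_cohort(cfg: Optional[GeneratorConfig] = None) -> PlantedCohort:
    """Sample indicators and realize events in one call."""
    cfg = cfg or default_generator_config()
    planted = sample_cohort(cfg)
    cohort = realize_events(planted, cfg)
    return PlantedCohort(cohort=cohort, truth=planted.truth)


def simulate_second_annotator(
    reference: list[ReferenceAnnotation],
    disagreement: float = 0.05,
    seed: int = 0,
    annotator_id: str = "icp-2",
) -> list[ReferenceAnnotation]:
    """Independent re-annotation: each label flips with probability
    ``disagreement``. Emulates the double-review overlap used to measure
    inter-rater agreement."""
    if not 0.0 <= disagreement <= 1.0:
        raise ValueError("disagreement must be in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS["annotator"],))
    )
    flips = rng.random(len(reference)) < disagreement
    return [
        ReferenceAnnotation(
            surgery_id=ann.surgery_id,
            deep_ssi=bool(ann.deep_ssi ^ bool(flips[i])),
            annotator_id=annotator_id,
        )
        for i, ann in enumerate(reference)
    ]
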