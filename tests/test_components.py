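"""Component extraction: temporal-window semantics, edge days, and the
monotonicity / translation-invariance / brute-force-oracle properties."""
import datetime as dt

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ssi_sentinel.components import (
    COMPONENT_NAMES,
    ComponentProfile,
    SurveillanceWarning,
    antibiotics_component,
    admissions_component,
    day_index,
    extract_profile,
    has_consecutive_run,
    microbiology_component,
    radiology_component,
    reoperation_component,
)
from ssi_sentinel.model import (
    AdmissionEpisode,
    AntibioticAdministration,
    CohortData,
    EventStreams,
    MicrobiologyCulture,
    RadiologyOrder,
    ReoperationRecord,
    SurveillanceWindowConfig,
)
from conftest import SURGERY_DATE, on_day


@pytest.mark.parametrize(
    "offset,expected",
    [(0, 1), (44, 45), (-1, 0), (29, 30)],
)
def test_day_index_anchored_at_surgery_day_one(offset, expected):
    assert day_index(SURGERY_DATE + dt.timedelta(days=offset), SURGERY_DATE) == expected


def _episode(admit_day, discharge_day, department="colorectal_surgery_solna", died=False):
    return AdmissionEpisode(
        patient_id="P001",
        admit_date=on_day(admit_day),
        discharge_date=None if discharge_day is None else on_day(discharge_day),
        department=department,
        died_in_hospital=died,
    )


class TestAdmissionsComponent:
    def test_long_stay_triggers(self, surgery, window):
        # discharge 20 days after surgery, no readmission, alive
        assert admissions_component(surgery, [_episode(0, 21)], window)

    def test_short_stay_alone_does_not(self, surgery, window):
        assert not admissions_component(surgery, [_episode(0, 6)], window)

    def test_open_discharge_counts_as_prolonged(self, surgery, window):
        assert admissions_component(surgery, [_episode(0, None)], window)

    def test_same_department_readmission_triggers(self, surgery, window):
        eps = [_episode(0, 6), _episode(12, 15)]
        assert admissions_component(surgery, eps, window)

    def test_other_department_readmission_does_not(self, surgery, window):
        eps = [_episode(0, 6), _episode(12, 15, department="internal_medicine")]
        assert not admissions_component(surgery, eps, window)

    def test_readmission_after_window_does_not(self, surgery, window):
        eps = [_episode(0, 6), _episode(46, 50)]
        assert not admissions_component(surgery, eps, window)

    def test_death_within_followup_triggers(self, surgery, window):
        assert admissions_component(surgery, [_episode(0, 8, died=True)], window)

    def test_death_after_followup_ignored(self, surgery, window):
        eps = [_episode(0, 6), _episode(50, 80, died=True)]
        assert not admissions_component(surgery, eps, window)

    def test_no_index_admission_warns_but_evaluates_other_arms(self, surgery, window):
        readmit = _episode(12, 15)
        with pytest.warns(SurveillanceWarning):
            assert admissions_component(surgery, [readmit], window)
        with pytest.warns(SurveillanceWarning):
            assert not admissions_component(surgery, [], window)

    def test_los_from_admission_switch(self, surgery):
        cfg = SurveillanceWindowConfig(los_from="admission")
        # admitted day -4, discharged day 12: 15 days in hospital but only
        # 11 days after surgery
        ep = AdmissionEpisode(
            patient_id="P001",
            admit_date=SURGERY_DATE - dt.timedelta(days=4),
            discharge_date=on_day(12),
            department=surgery.department,
        )
        assert admissions_component(surgery, [ep], cfg)
        assert not admissions_component(surgery, [ep], SurveillanceWindowConfig())


def _reop(day, specialty="colorectal_surgery"):
    return ReoperationRecord(patient_id="P001", procedure_date=on_day(day), specialty=specialty)


@pytest.mark.parametrize(
    "day,specialty,expected",
    [
        (9, "colorectal_surgery", True),
        (9, "orthopaedic_surgery", False),
        (46, "colorectal_surgery", False),  # past follow-up
        (1, "colorectal_surgery", False),   # index procedure day never counts
        (2, "colorectal_surgery", True),
        (45, "colorectal_surgery", True),
    ],
)
def test_reoperation_component(surgery, window, day, specialty, expected):
    assert reoperation_component(surgery, [_reop(day, specialty)], window) is expected


@pytest.mark.parametrize(
    "day,modality,expected",
    [
        (3, "CT", True),
        (3, "MR", False),
        (0, "CT", False),   # pre-operative
        (1, "CT", True),
        (45, "CT", True),
        (46, "CT", False),
    ],
)
def test_radiology_component(surgery, window, day, modality, expected):
    orders = [RadiologyOrder(patient_id="P001", order_date=on_day(day), modality=modality)]
    assert radiology_component(surgery, orders, window) is expected


def _abx(days, code="J01CA04"):
    return [
        AntibioticAdministration(
            patient_id="P001", administration_date=on_day(d), atc_code=code
        )
        for d in days
    ]


@pytest.mark.parametrize(
    "days,code,expected",
    [
        ({2, 3, 4}, "J01CA04", True),
        ({1, 2, 3}, "J01CA04", False),   # run starts on the surgery day: prophylaxis
        ({1, 2, 3, 4}, "J01CA04", True), # but days 2-4 qualify on their own
        ({2, 4, 6}, "J01CA04", False),   # gapped
        ({2, 3, 4}, "J02AC01", False),   # not a J01 antibacterial
        ({43, 44, 45}, "J01CA04", True),
        ({44, 45, 46}, "J01CA04", False),  # truncated at the window edge
        ({2, 3}, "J01CA04", False),
    ],
)
def test_antibiotics_component(surgery, window, days, code, expected):
    assert antibiotics_component(surgery, _abx(days, code), window) is expected


def test_antibiotics_run_detection_matches_naive_scan(surgery, window):
    """Brute-force oracle: scan every candidate start day 2..45 and check
    the three following days directly, over 1,000 random day sets."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        days = set(rng.choice(np.arange(-3, 50), size=rng.integers(0, 12), replace=False).tolist())
        naive = any(
            all(d in days for d in range(start, start + 3)) and start + 2 <= 45
            for start in range(2, 46)
        )
        assert has_consecutive_run(days, 3, 2, 45) == naive


def _culture(day, relevant=True, site="abdominal"):
    return MicrobiologyCulture(
        patient_id="P001", sample_date=on_day(day), body_site=site, relevant_site=relevant
    )


@pytest.mark.parametrize(
    "day,relevant,expected",
    [
        (1, True, True),    # surgery day kept: only days prior to day 1 excluded
        (0, True, False),
        (10, False, False),
        (45, True, True),
        (46, True, False),
    ],
)
def test_microbiology_component(surgery, window, day, relevant, expected):
    assert microbiology_component(surgery, [_culture(day, relevant)], window) is expected


def test_extract_profile_no_events_all_false(surgery, window):
    """A patient with no post-surgery events scores zero components —
    the pattern of the one deep SSI missed by both algorithms."""
    cohort = CohortData(surgeries=[surgery], events=EventStreams())
    with pytest.warns(SurveillanceWarning):  # no index admission either
        profile = extract_profile(surgery, cohort, window)
    assert profile.count == 0
    assert not any(profile.flags().values())


def test_extract_profile_count_consistency(surgery, window):
    events = EventStreams(
        admissions=[_episode(0, 21)],
        radiology=[RadiologyOrder(patient_id="P001", order_date=on_day(3), modality="CT")],
        antibiotics=_abx({2, 3, 4}),
    )
    cohort = CohortData(surgeries=[surgery], events=events)
    profile = extract_profile(surgery, cohort, window)
    assert profile.flags() == {
        "admissions": True,
        "reoperation": False,
        "radiology": True,
        "antibiotics": True,
        "microbiology": False,
    }
    assert profile.count == 3


def test_component_profile_count_invariant_enforced():
    with pytest.raises(Exception):
        ComponentProfile(
            surgery_id="S1", admissions=True, reoperation=False, radiology=False,
            antibiotics=False, microbiology=False, count=3,
        )


@given(shift=st.integers(min_value=-3650, max_value=3650),
       days=st.sets(st.integers(min_value=-5, max_value=50), max_size=10),
       reop_day=st.integers(min_value=-5, max_value=50),
       ct_day=st.integers(min_value=-5, max_value=50))
def test_translation_invariance(surgery, window, shift, days, reop_day, ct_day):
    """Shifting surgery and all events by the same offset changes nothing."""
    delta = dt.timedelta(days=shift)
    def build(base_shift):
        s = surgery.model_copy(update={"surgery_date": SURGERY_DATE + base_shift})
        ev = EventStreams(
            admissions=[AdmissionEpisode(
                patient_id="P001", admit_date=on_day(0) + base_shift,
                discharge_date=on_day(6) + base_shift, department=s.department)],
            antibiotics=[AntibioticAdministration(
                patient_id="P001", administration_date=on_day(d) + base_shift,
                atc_code="J01CA04") for d in days],
            reoperations=[ReoperationRecord(
                patient_id="P001", procedure_date=on_day(reop_day) + base_shift,
                specialty=s.specialty)],
            radiology=[RadiologyOrder(
                patient_id="P001", order_date=on_day(ct_day) + base_shift, modality="CT")],
        )
        return extract_profile(s, CohortData(surgeries=[s], events=ev), window)
    assert build(dt.timedelta(0)).flags() == build(delta).flags()


@given(days=st.sets(st.integers(min_value=-5, max_value=50), max_size=10),
       extra=st.integers(min_value=-5, max_value=50))
def test_antibiotics_monotone_in_events(surgery, window, days, extra):
    """Adding an administration day never turns the component false."""
    before = antibiotics_component(surgery, _abx(days), window)
    after = antibiotics_component(surgery, _abx(days | {extra}), window)
    assert after or not before
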