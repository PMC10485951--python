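"""Diagnostic performance statistics: Wilson intervals (against a
quadratic-root oracle and statsmodels), confusion counts, workload
reduction, and Cohen's kappa (against hand computation and sklearn)."""
import math

import numpy as np
import pytest
from scipy import stats

from ssi_sentinel.classifier import Classification
from ssi_sentinel.evaluation import (
    AgreementResult,
    ConfusionCounts,
    cohens_kappa,
    confusion_matrix,
    diagnostic_performance,
    wilson_interval,
    workload_reduction,
)
from ssi_sentinel.model import ReferenceAnnotation
from ssi_sentinel.report import format_percent, round_half_up


def wilson_by_quadratic_roots(k: int, n: int, level: float = 0.95):
    """Independent oracle: the Wilson limits are the roots of
    (p - phat)^2 = z^2 p (1 - p) / n in p."""
    z2 = stats.norm.ppf((1 + level) / 2) ** 2
    phat = k / n
    a = 1 + z2 / n
    b = -(2 * phat + z2 / n)
    c = phat * phat
    disc = math.sqrt(b * b - 4 * a * c)
    return ((-b - disc) / (2 * a), (-b + disc) / (2 * a))


def test_wilson_matches_quadratic_oracle_on_grid():
    for n in (1, 2, 5, 10, 25, 41, 100, 225, 1000, 5000):
        for k in range(0, n + 1, max(1, n // 100)):
            low, high = wilson_interval(k, n)
            olow, ohigh = wilson_by_quadratic_roots(k, n)
            assert abs(low - olow) < 1e-9 and abs(high - ohigh) < 1e-9


def test_wilson_matches_statsmodels():
    from statsmodels.stats.proportion import proportion_confint

    for k, n in [(34, 41), (40, 41), (7, 19), (159, 184), (1, 1000)]:
        low, high = wilson_interval(k, n)
        slow, shigh = proportion_confint(k, n, alpha=0.05, method="wilson")
        assert low == pytest.approx(slow, abs=1e-12)
        assert high == pytest.approx(shigh, abs=1e-12)


def test_wilson_boundary_closure():
    assert wilson_interval(0, 10)[0] == 0.0
    assert wilson_interval(10, 10)[1] == 1.0


def test_wilson_published_sensitivity_intervals():
    assert wilson_interval(34, 41) == (pytest.approx(0.687, abs=5e-4), pytest.approx(0.915, abs=5e-4))
    assert wilson_interval(40, 41) == (pytest.approx(0.874, abs=5e-4), pytest.approx(0.996, abs=5e-4))


def test_wilson_contains_point_and_narrows_with_n():
    prev_width = None
    for n in (10, 40, 160, 640):
        k = int(0.3 * n)
        low, high = wilson_interval(k, n)
        assert 0.0 <= low <= k / n <= high <= 1.0
        width = high - low
        if prev_width is not None:
            assert width < prev_width
        prev_width = width


def test_wilson_rejects_bad_input():
    with pytest.raises(ValueError):
        wilson_interval(1, 0)
    with pytest.raises(ValueError):
        wilson_interval(5, 4)


ORIGINAL = ConfusionCounts(tp=34, fp=25, fn=7, tn=159)
ADAPTED = ConfusionCounts(tp=40, fp=56, fn=1, tn=128)


@pytest.mark.parametrize(
    "counts,expected",
    [
        (ORIGINAL, {"sensitivity": ("82.9", "68.7", "91.5"),
                    "specificity": ("86.4", "80.7", "90.6"),
                    "ppv": ("57.6", "44.9", "69.4"),
                    "npv": ("95.8", "91.6", "97.9")}),
        (ADAPTED, {"sensitivity": ("97.6", "87.4", "99.6"),
                   "specificity": ("69.6", "62.6", "75.8"),
                   "ppv": ("41.7", "32.3", "51.7"),
                   "npv": ("99.2", "95.7", "99.9")}),
    ],
    ids=["original", "adapted"],
)
def test_diagnostic_performance_published_rows(counts, expected):
    report = diagnostic_performance(counts)
    for name, (pt, lo, hi) in expected.items():
        m = report.metrics[name]
        assert format_percent(m.point) == pt
        assert format_percent(m.ci_low) == lo
        assert format_percent(m.ci_high) == hi


def test_workload_reduction_values():
    assert workload_reduction(ADAPTED) == pytest.approx(129 / 225)
    assert format_percent(workload_reduction(ADAPTED)) == "57.3"
    # computed 166/225 = 73.78% renders 73.8; the printed source value
    # 73.7 is a downward rounding -- accept within 0.1 percentage point
    assert workload_reduction(ORIGINAL) == pytest.approx(166 / 225)
    assert abs(100 * workload_reduction(ORIGINAL) - 73.7) <= 0.1
    assert format_percent(workload_reduction(ORIGINAL)) == "73.8"


def test_workload_reduction_complement_identity():
    for counts in (ORIGINAL, ADAPTED, ConfusionCounts(tp=3, fp=0, fn=0, tn=0)):
        assert workload_reduction(counts) + (counts.tp + counts.fp) / counts.n == pytest.approx(1.0)


def test_workload_all_high_is_zero():
    assert workload_reduction(ConfusionCounts(tp=41, fp=184, fn=0, tn=0)) == 0.0


def test_workload_empty_errors():
    with pytest.raises(ValueError):
        workload_reduction(ConfusionCounts(tp=0, fp=0, fn=0, tn=0))


def test_perfect_classifier_metrics_all_one():
    report = diagnostic_performance(ConfusionCounts(tp=5, fp=0, fn=0, tn=12))
    for m in report.metrics.values():
        assert m.point == 1.0 and not m.undefined


def test_undefined_metric_flagged_not_zero():
    report = diagnostic_performance(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
    assert report.metrics["ppv"].undefined and report.metrics["ppv"].point is None
    assert not report.metrics["sensitivity"].undefined


def _classified(mapping):
    return [
        Classification(surgery_id=k, algorithm="a", probability_class="high" if v else "low")
        for k, v in mapping.items()
    ]


def _reference(mapping):
    return [ReferenceAnnotation(surgery_id=k, deep_ssi=v) for k, v in mapping.items()]


def test_confusion_matrix_identity_and_all_high():
    truth = {f"S{i}": i < 41 for i in range(225)}
    perfect = confusion_matrix(_classified(truth), _reference(truth))
    assert (perfect.tp, perfect.fp, perfect.fn, perfect.tn) == (41, 0, 0, 184)
    all_high = confusion_matrix({k: True for k in truth}, truth)
    assert (all_high.tp, all_high.fp, all_high.fn, all_high.tn) == (41, 184, 0, 0)


def test_confusion_matrix_empty():
    c = confusion_matrix({}, {})
    assert c.n == 0


def test_confusion_matrix_mismatch_names_difference():
    with pytest.raises(ValueError, match="S9"):
        confusion_matrix({"S1": True}, {"S1": True, "S9": False})


def test_kappa_hand_computed_table():
    """2x2 table [[5,1],[0,14]]: p_o = 0.95, p_e = 0.60, kappa = 0.875."""
    a = [True] * 6 + [False] * 14
    b = [True] * 5 + [False] * 15
    res = cohens_kappa(a, b)
    assert res.percent_agreement == pytest.approx(0.95, abs=1e-12)
    assert res.kappa == pytest.approx(0.875, abs=1e-12)


def test_kappa_perfect_agreement_mixed_labels():
    a = [True, False, True, False, False]
    res = cohens_kappa(a, list(a))
    assert res.kappa == 1.0 and res.percent_agreement == 1.0


def test_kappa_constant_annotator_on_balanced_truth_is_zero():
    a = [True, True, False, False]
    b = [False, False, False, False]
    assert cohens_kappa(a, b).kappa == pytest.approx(0.0, abs=1e-12)


def test_kappa_undefined_when_both_constant_identical():
    res = cohens_kappa([True, True], [True, True])
    assert res.kappa_undefined and res.kappa is None
    assert res.percent_agreement == 1.0


def test_kappa_matches_sklearn_on_random_labels():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(7)
    for _ in range(20):
        a = rng.random(50) < 0.3
        b = rng.random(50) < 0.4
        if len(set(a)) == 1 and len(set(b)) == 1 and all(a == b):
            continue
        assert cohens_kappa(list(a), list(b)).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )


def test_kappa_mapping_interface_alignment():
    a = {"x": True, "y": False}
    b = {"y": False, "x": True}
    assert cohens_kappa(a, b).percent_agreement == 1.0
    with pytest.raises(ValueError):
        cohens_kappa({"x": True}, {"z": True})


def test_round_half_up_semantics():
    assert round_half_up(73.75, 1) == 73.8
    assert round_half_up(73.74999, 1) == 73.7
    assert round_half_up(0.05, 1) == 0.1
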