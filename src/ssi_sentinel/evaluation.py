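"""Diagnostic performance of a classification against the reference
standard: confusion counts, sensitivity/specificity/PPV/NPV with Wilson
score confidence intervals, workload reduction, and two-rater agreement
(percent agreement and Cohen's kappa).

Positive = classified high probability; truth = deep SSI per the manual
reference standard. Workload reduction is the fraction of records
classified low probability, i.e. exempt from manual review.
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence, Union

from pydantic import BaseModel, model_validator
from scipy import stats

from .classifier import Classification
from .model import ReferenceAnnotation

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "PerformanceReport",
    "AgreementResult",
    "confusion_matrix",
    "wilson_interval",
    "diagnostic_performance",
    "workload_reduction",
    "cohens_kappa",
    "reference_truth",
]


class ConfusionCounts(BaseModel):
    tp: int
    fp: int
    fn: int
    tn: int

    @model_validator(mode="after")
    def _nonneg(self) -> "ConfusionCounts":
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        return self

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class MetricEstimate(BaseModel):
    """Point estimate with Wilson CI; ``undefined`` flags a zero
    denominator (point and CI are then None, never silently 0)."""

    name: str
    point: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    level: float = 0.95
    undefined: bool = False

    @model_validator(mode="after")
    def _ordered(self) -> "MetricEstimate":
        if not self.undefined:
            assert self.point is not None and self.ci_low is not None and self.ci_high is not None
            if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
                raise ValueError("require 0 <= ci_low <= point <= ci_high <= 1")
        return self


class PerformanceReport(BaseModel):
    algorithm: str
    counts: ConfusionCounts
    metrics: dict[str, MetricEstimate]
    workload_reduction: float
    level: float = 0.95


class AgreementResult(BaseModel):
    n_items: int
    percent_agreement: float
    kappa: Optional[float] = None
    kappa_undefined: bool = False


def _truth_map(
    reference: Union[Mapping[str, bool], Iterable[ReferenceAnnotation]]
) -> dict[str, bool]:
    if isinstance(reference, Mapping):
        return {str(k): bool(v) for k, v in reference.items()}
    out: dict[str, bool] = {}
    for ann in reference:
        if ann.surgery_id in out and out[ann.surgery_id] != ann.deep_ssi:
            raise ValueError(
                f"conflicting reference labels for surgery {ann.surgery_id!r}"
            )
        out[ann.surgery_id] = ann.deep_ssi
    return out


def reference_truth(
    reference: Union[Mapping[str, bool], Iterable[ReferenceAnnotation]]
) -> dict[str, bool]:
    """Collapse reference annotations to a surgery_id -> deep_ssi map;
    duplicate rows must agree."""
    return _truth_map(reference)


def confusion_matrix(
    classifications: Union[Mapping[str, bool], Iterable[Classification]],
    reference: Union[Mapping[str, bool], Iterable[ReferenceAnnotation]],
) -> ConfusionCounts:
    """Cross-tabulate high/low classifications against deep-SSI truth.

    Both sides must cover exactly the same surgery set; a mismatch raises
    with the differing ids named.
    """
    if isinstance(classifications, Mapping):
        pred = {str(k): bool(v) for k, v in classifications.items()}
    else:
        pred = {}
        for c in classifications:
            if c.surgery_id in pred:
                raise ValueError(f"duplicate classification for {c.surgery_id!r}")
            pred[c.surgery_id] = c.probability_class == "high"
    truth = _truth_map(reference)
    if set(pred) != set(truth):
        only_pred = sorted(set(pred) - set(truth))[:5]
        only_ref = sorted(set(truth) - set(pred))[:5]
        raise ValueError(
            "classification and reference cover different surgeries; "
            f"only classified: {only_pred}; only referenced: {only_ref}"
        )
    tp = fp = fn = tn = 0
    for sid, high in pred.items():
        ssi = truth[sid]
        if high and ssi:
            tp += 1
        elif high:
            fp += 1
        elif ssi:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def wilson_interval(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion.

    centre (p + z^2/2n) / (1 + z^2/n), half-width
    z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n), with z the standard
    normal quantile at (1+level)/2 in full double precision. The interval
    is closed at the boundaries: successes = 0 gives a lower limit of
    exactly 0 and successes = n an upper limit of exactly 1.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in 0..n")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    low = 0.0 if successes == 0 else max(0.0, centre - half)
    high = 1.0 if successes == n else min(1.0, centre + half)
    return low, high


def _metric(name: str, num: int, den: int, level: float) -> MetricEstimate:
    if den == 0:
        return MetricEstimate(name=name, level=level, undefined=True)
    low, high = wilson_interval(num, den, level)
    return MetricEstimate(
        name=name, point=num / den, ci_low=low, ci_high=high, level=level
    )


def diagnostic_performance(
    counts: ConfusionCounts, level: float = 0.95, algorithm: str = ""
) -> PerformanceReport:
    """Sensitivity, specificity, PPV and NPV with Wilson CIs, each on its
    own denominator, plus workload reduction. A zero denominator flags
    the metric undefined instead of reporting 0 or 1."""
    metrics = {
        "sensitivity": _metric("sensitivity", counts.tp, counts.tp + counts.fn, level),
        "specificity": _metric("specificity", counts.tn, counts.tn + counts.fp, level),
        "ppv": _metric("ppv", counts.tp, counts.tp + counts.fp, level),
        "npv": _metric("npv", counts.tn, counts.tn + counts.fn, level),
    }
    return PerformanceReport(
        algorithm=algorithm,
        counts=counts,
        metrics=metrics,
        workload_reduction=workload_reduction(counts),
        level=level,
    )


def workload_reduction(counts: ConfusionCounts) -> float:
    """Fraction of records classified low probability, hence not sent to
    manual review: (tn + fn) / N."""
    if counts.n == 0:
        raise ValueError("workload reduction undefined on an empty cohort")
    return (counts.tn + counts.fn) / counts.n


def cohens_kappa(
    annotations_a: Union[Mapping[str, bool], Sequence[bool]],
    annotations_b: Union[Mapping[str, bool], Sequence[bool]],
) -> AgreementResult:
    """Two-rater, two-category agreement: percent agreement and Cohen's
    kappa with chance agreement from the raters' marginal label
    frequencies. When both raters are constant and identical the chance
    agreement is 1 and kappa is flagged undefined."""
    if isinstance(annotations_a, Mapping) or isinstance(annotations_b, Mapping):
        if not (isinstance(annotations_a, Mapping) and isinstance(annotations_b, Mapping)):
            raise TypeError("pass both annotation sets as mappings or both as sequences")
        if set(annotations_a) != set(annotations_b):
            raise ValueError("annotators cover different item sets")
        keys = sorted(annotations_a)
        a = [bool(annotations_a[k]) for k in keys]
        b = [bool(annotations_b[k]) for k in keys]
    else:
        if len(annotations_a) != len(annotations_b):
            raise ValueError("annotation sequences differ in length")
        a = [bool(x) for x in annotations_a]
        b = [bool(x) for x in annotations_b]
    n = len(a)
    if n == 0:
        raise ValueError("no items to compare")
    p_o = sum(x == y for x, y in zip(a, b)) / n
    pa = sum(a) / n
    pb = sum(b) / n
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        return AgreementResult(
            n_items=n, percent_agreement=p_o, kappa=None, kappa_undefined=True
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(n_items=n, percent_agreement=p_o, kappa=kappa)
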