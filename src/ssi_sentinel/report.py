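"""Report rendering: a human-readable performance table (one row per
algorithm: TP, FP, FN, TN, the four metrics as "pt (lo-hi)", % workload
reduction) and a full-precision JSON form. Percentages are rounded
half-up to one decimal at render time only; stored values keep full
precision.
"""
from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .evaluation import MetricEstimate, PerformanceReport

__all__ = ["round_half_up", "format_percent", "render_report", "reports_to_json"]

_METRIC_ORDER = ("sensitivity", "specificity", "ppv", "npv")
_METRIC_LABEL = {
    "sensitivity": "Sensitivity",
    "specificity": "Specificity",
    "ppv": "PPV",
    "npv": "NPV",
}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 digit -> 0.1), unlike banker's
    rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(proportion: float, ndigits: int = 1) -> str:
    return f"{round_half_up(100.0 * proportion, ndigits):.{ndigits}f}"


def _metric_cell(m: MetricEstimate) -> str:
    if m.undefined:
        return "undefined"
    return (
        f"{format_percent(m.point)} "
        f"({format_percent(m.ci_low)}–{format_percent(m.ci_high)})"
    )


def render_report(reports: Sequence[PerformanceReport]) -> str:
    """Markdown table mirroring the usual diagnostic-accuracy layout."""
    if not reports:
        raise ValueError("no reports to render")
    level_pct = format_percent(reports[0].level, 0)
    headers = ["Algorithm", "TP", "FP", "FN", "TN"] + [
        f"{_METRIC_LABEL[m]}, % ({level_pct}%CI)" for m in _METRIC_ORDER
    ] + ["% workload reduction"]
    rows = []
    for r in reports:
        c = r.counts
        rows.append(
            [r.algorithm or "-", str(c.tp), str(c.fp), str(c.fn), str(c.tn)]
            + [_metric_cell(r.metrics[m]) for m in _METRIC_ORDER]
            + [format_percent(r.workload_reduction)]
        )
    widths = [max(len(h), *(len(row[i]) for row in rows)) for i, h in enumerate(headers)]
    def line(cells: list[str]) -> str:
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    return "\n".join([line(headers), sep] + [line(r) for r in rows]) + "\n"


def reports_to_json(reports: Sequence[PerformanceReport], indent: Optional[int] = 2) -> str:
    """Full-precision JSON; round-trips losslessly via
    ``PerformanceReport.model_validate``."""
    return json.dumps([r.model_dump() for r in reports], indent=indent, sort_keys=True)
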