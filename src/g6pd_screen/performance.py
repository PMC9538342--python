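"""Confusion matrices and exact-fraction diagnostic metrics.

Sensitivity, specificity, PPV and NPV are kept as integer fractions and
only rounded (half-up, one decimal) at presentation, so printed
percentages like 69.6% (16/23) are reproduced digit-for-digit.  A metric
with a zero denominator is flagged not-available rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .assays import classify_activity, cohort_truths, panel_call
from .cohort import CarrierStatus, CohortTable, DEFAULT_PANEL, PanelDefinition, Sex

__all__ = [
    "ConfusionMatrix",
    "MetricValue",
    "DiagnosticMetrics",
    "confusion",
    "metrics",
    "performance_table",
    "performance_frame",
    "format_performance_text",
    "percent_half_up",
]


def percent_half_up(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100*num/den rounded half-up to ``ndigits`` decimals, as a float."""
    q = Decimal(1).scaleb(-ndigits)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass(frozen=True)
class MetricValue:
    """An exact num/den fraction with a 1-decimal percent presentation."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator:
            raise ValueError("numerator must be nonnegative")
        if self.denominator and self.numerator > self.denominator:
            raise ValueError("numerator cannot exceed denominator")

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def fraction(self) -> Fraction | None:
        return Fraction(self.numerator, self.denominator) if self.defined else None

    @property
    def percent(self) -> float | None:
        if not self.defined:
            return None
        return percent_half_up(self.numerator, self.denominator, 1)

    def __str__(self) -> str:
        if not self.defined:
            return "NA"
        pct = self.percent
        pct_str = f"{pct:g}" if pct == int(pct) else f"{pct:.1f}"
        return f"{pct_str}% ({self.numerator}/{self.denominator})"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue


def confusion(
    calls: Sequence[bool],
    truths: Sequence[CarrierStatus | bool],
    ids: Sequence[str] | None = None,
    truth_ids: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Tally test calls against carrier truths, aligned positionally.

    When both id sequences are given they must match element-wise.
    """
    if len(calls) != len(truths):
        raise ValueError(
            f"calls ({len(calls)}) and truths ({len(truths)}) differ in length"
        )
    if ids is not None and truth_ids is not None:
        mism = [a for a, b in zip(ids, truth_ids) if a != b]
        if mism:
            raise ValueError(f"call/truth id mismatch, e.g. {mism[:3]}")
    tp = fp = fn = tn = 0
    for call, truth in zip(calls, truths):
        is_carrier = (
            truth is True
            if isinstance(truth, bool)
            else truth is CarrierStatus.CARRIER
        )
        if call and is_carrier:
            tp += 1
        elif call and not is_carrier:
            fp += 1
        elif not call and is_carrier:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV as exact fractions."""
    return DiagnosticMetrics(
        sensitivity=MetricValue(cm.tp, cm.tp + cm.fn),
        specificity=MetricValue(cm.tn, cm.tn + cm.fp),
        ppv=MetricValue(cm.tp, cm.tp + cm.fp),
        npv=MetricValue(cm.tn, cm.tn + cm.fn),
    )


ASSAYS = ("enzymatic", "genotyping")


def performance_table(
    cohort: CohortTable,
    cutoff: float = 1.0,
    panel: PanelDefinition = DEFAULT_PANEL,
) -> dict[tuple[Sex, str], tuple[ConfusionMatrix, DiagnosticMetrics]]:
    """Sex-stratified diagnostic performance of both confirmatory assays.

    Returns a (sex, assay) grid where assay is ``enzymatic`` (activity
    ratio below cutoff) or ``genotyping`` (targeted panel positive).
    """
    truths = cohort_truths(cohort)
    out: dict[tuple[Sex, str], tuple[ConfusionMatrix, DiagnosticMetrics]] = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        sub = [r for r in cohort if r.sex is sex]
        sub_truths = [truths[r.id] for r in sub]
        for assay in ASSAYS:
            if assay == "enzymatic":
                calls = [
                    classify_activity(r.activity_ratio, cutoff).deficient for r in sub
                ]
            else:
                calls = [panel_call(r.panel_result, panel).positive for r in sub]
            cm = confusion(calls, sub_truths)
            out[(sex, assay)] = (cm, metrics(cm))
    return out


def performance_frame(
    cohort: CohortTable, cutoff: float = 1.0, panel: PanelDefinition = DEFAULT_PANEL
) -> pd.DataFrame:
    """Long-format DataFrame of the performance grid, one row per metric."""
    rows = []
    for (sex, assay), (cm, m) in performance_table(cohort, cutoff, panel).items():
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            mv: MetricValue = getattr(m, name)
            rows.append(
                {
                    "sex": sex.value,
                    "assay": assay,
                    "metric": name,
                    "numerator": mv.numerator,
                    "denominator": mv.denominator,
                    "percent": mv.percent,
                    "display": str(mv),
                }
            )
    return pd.DataFrame(rows)


def format_performance_text(
    cohort: CohortTable, cutoff: float = 1.0, panel: PanelDefinition = DEFAULT_PANEL
) -> str:
    """Aligned plain-text grid: metrics as rows, sex x assay as columns."""
    grid = performance_table(cohort, cutoff, panel)
    cols = [(sex, assay) for sex in (Sex.MALE, Sex.FEMALE) for assay in ASSAYS]
    headers = ["Metric"] + [f"{sex.value}/{assay}" for sex, assay in cols]
    lines = []
    name_map = {
        "sensitivity": "Sensitivity",
        "specificity": "Specificity",
        "ppv": "Positive predictive value",
        "npv": "Negative predictive value",
    }
    table = [headers]
    for name, label in name_map.items():
        row = [label]
        for col in cols:
            row.append(str(getattr(grid[col][1], name)))
        table.append(row)
    widths = [max(len(r[i]) for r in table) for i in range(len(headers))]
    for r in table:
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip())
    return "\n".join(lines)
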