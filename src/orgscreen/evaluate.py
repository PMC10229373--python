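"""Confusion-matrix metrics for one-vs-rest evaluation of contig classifiers.

Implements the Matthews correlation coefficient, F1, precision, sensitivity
and specificity from raw TP/TN/FP/FN counts, with the standard convention
that MCC is 0 when any marginal factor of its denominator is 0. All values
are kept at full precision; rounding to 2 decimals happens only in the
presentation layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import InputError

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics", "compare", "format_report"]

METRIC_NAMES = ("mcc", "f1", "precision", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    mcc: float
    f1: float
    precision: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(labels: Mapping[str, str], predictions: Mapping[str, str], positive_class: str) -> ConfusionCounts:
    """One-vs-rest confusion counts of predictions against labels."""
    if set(labels) != set(predictions):
        diff = sorted(set(labels) ^ set(predictions))
        raise InputError(f"labels and predictions cover different ids; symmetric difference: {diff[:10]}")
    tp = tn = fp = fn = 0
    for sid, truth in labels.items():
        pos_true = truth == positive_class
        pos_pred = predictions[sid] == positive_class
        if pos_true and pos_pred:
            tp += 1
        elif pos_true:
            fn += 1
        elif pos_pred:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts) -> MetricReport:
    """Derive MCC, F1, precision, sensitivity, specificity from raw counts."""
    if c.total < 1:
        raise InputError("confusion counts are all zero")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    return MetricReport(mcc=mcc, f1=f1, precision=precision, sensitivity=sensitivity, specificity=specificity)


def compare(report_a: MetricReport, report_b: MetricReport) -> dict[str, float]:
    """Per-metric signed differences a - b, in fixed metric order."""
    a, b = report_a.as_dict(), report_b.as_dict()
    return {name: a[name] - b[name] for name in METRIC_NAMES}


def format_report(rows: Mapping[str, tuple[ConfusionCounts, MetricReport]]) -> str:
    """Human-readable table: TP TN FP FN MCC F1 Pre Sen Spe, 2-dp presentation."""
    header = f"{'Row':<24}{'TP':>7}{'TN':>9}{'FP':>7}{'FN':>7}{'MCC':>7}{'F1':>7}{'Pre':>7}{'Sen':>7}{'Spe':>7}"
    lines = [header]
    for name, (c, m) in rows.items():
        lines.append(
            f"{name:<24}{c.tp:>7}{c.tn:>9}{c.fp:>7}{c.fn:>7}"
            f"{m.mcc:>7.2f}{m.f1:>7.2f}{m.precision:>7.2f}{m.sensitivity:>7.2f}{m.specificity:>7.2f}"
        )
    return "\n".join(lines)
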