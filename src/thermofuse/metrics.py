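"""Confusion-matrix metric suite.

Standard binary-classification ratios computed from TP/TN/FP/FN tallies:
accuracy, sensitivity (recall), specificity, precision, false-positive and
false-negative rates, negative predictive value, false discovery rate, F1
and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Ratios with a zero denominator are reported as NaN with a warning rather
than raising.  Multi-class label vectors are reduced one-vs-rest per class
and macro-averaged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "report", "macro_report", "METRIC_COLUMNS"]

# Column order used by the metrics CSV writers.
METRIC_COLUMNS = [
    "Accuracy",
    "Recall",
    "Specificity",
    "Precision",
    "FPR",
    "FNR",
    "NPV",
    "FDR",
    "F1-Score",
    "MCC",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    fpr: float
    fnr: float
    npv: float
    fdr: float
    f1: float
    mcc: float

    def as_row(self) -> dict:
        vals = [
            self.accuracy,
            self.sensitivity,
            self.specificity,
            self.precision,
            self.fpr,
            self.fnr,
            self.npv,
            self.fdr,
            self.f1,
            self.mcc,
        ]
        return dict(zip(METRIC_COLUMNS, vals))

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(pred, truth, positive_class=1) -> ConfusionCounts:
    """Tally TP/TN/FP/FN of predictions against ground truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    p = pred == positive_class
    t = truth == positive_class
    return ConfusionCounts(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", RuntimeWarning, stacklevel=3)
        return math.nan
    return num / den


def report(c: ConfusionCounts) -> MetricReport:
    """Full metric report from one confusion table."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    accuracy = (tp + tn) / c.total
    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    specificity = _ratio(tn, tn + fp, "specificity")
    precision = _ratio(tp, tp + fp, "precision")
    fpr = _ratio(fp, fp + tn, "FPR")
    fnr = _ratio(fn, fn + tp, "FNR")
    npv = _ratio(tn, tn + fn, "NPV")
    fdr = _ratio(fp, tp + fp, "FDR")
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        warnings.warn("F1 undefined", RuntimeWarning, stacklevel=2)
        f1 = math.nan
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        warnings.warn("MCC undefined: zero denominator", RuntimeWarning, stacklevel=2)
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / denom
    return MetricReport(accuracy, sensitivity, specificity, precision, fpr, fnr, npv, fdr, f1, mcc)


def macro_report(pred, truth) -> MetricReport:
    """One-vs-rest per class, macro-averaged over the classes present in truth."""
    truth = np.asarray(truth)
    classes = np.unique(truth)
    reports = [report(confusion(pred, truth, positive_class=c)) for c in classes]
    agg = {
        f.name: float(np.mean([getattr(r, f.name) for r in reports]))
        for f in fields(MetricReport)
    }
    return MetricReport(**agg)
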