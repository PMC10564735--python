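"""Classification metrics: per-class precision/recall/F1 and cost.

Counts are accumulated one-vs-rest per class from single-label
predictions:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * P * R / (P + R)

All three are reported in percent, rounded to two decimals for display;
a class that is never predicted (TP + FP = 0) gets precision 0 and is
flagged as degenerate rather than raising.  Summary values are macro
averages (unweighted class means).  Cost is total prediction wall time
over number of images, Tn / n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["ClassMetrics", "EvalReport", "CostMeasure", "f1_from_pr",
           "F1Result", "compute_metrics"]


@dataclass(frozen=True)
class F1Result:
    value: float      # rounded to 2 decimals, percent
    exact: float      # unrounded, percent
    degenerate: bool = False


def f1_from_pr(precision: float, recall: float) -> F1Result:
    """Harmonic mean of precision and recall, both in percent."""
    if not (0 <= precision <= 100 and 0 <= recall <= 100):
        raise InvalidInputError("precision and recall must lie in [0, 100]")
    if precision == 0 and recall == 0:
        return F1Result(0.0, 0.0, degenerate=True)
    exact = 2.0 * precision * recall / (precision + recall)
    return F1Result(round(exact, 2), exact)


@dataclass
class ClassMetrics:
    label: str
    tp: int
    fp: int
    fn: int
    precision: float   # percent
    recall: float      # percent
    f1: float          # percent
    degenerate: bool = False


@dataclass
class EvalReport:
    per_class: list[ClassMetrics]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_accuracy: float  # sum(TP) / total, percent
    n_images: int

    def to_dict(self) -> dict:
        return {
            "per_class": {m.label: {
                "tp": m.tp, "fp": m.fp, "fn": m.fn,
                "precision": round(m.precision, 2),
                "recall": round(m.recall, 2),
                "f1": round(m.f1, 2),
                "degenerate": m.degenerate,
            } for m in self.per_class},
            "macro_precision": round(self.macro_precision, 2),
            "macro_recall": round(self.macro_recall, 2),
            "macro_f1": round(self.macro_f1, 2),
            "micro_accuracy": round(self.micro_accuracy, 2),
            "n_images": self.n_images,
        }


@dataclass(frozen=True)
class CostMeasure:
    total_time: float  # Tn, seconds
    n: int
    cost: float        # seconds per image, Tn / n


def compute_metrics(y_true, y_pred, class_names) -> EvalReport:
    """Confusion accounting for single-label multiclass predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise InvalidInputError("empty evaluation set")
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("y_true and y_pred lengths differ")
    k = len(class_names)
    if y_true.min() < 0 or y_true.max() >= k:
        raise InvalidInputError("label index outside the model's classes")
    per_class = []
    for c, name in enumerate(class_names):
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        degenerate = (tp + fp) == 0
        p = 0.0 if degenerate else 100.0 * tp / (tp + fp)
        r = 0.0 if (tp + fn) == 0 else 100.0 * tp / (tp + fn)
        f1 = f1_from_pr(p, r)
        per_class.append(ClassMetrics(
            label=str(name), tp=tp, fp=fp, fn=fn, precision=p, recall=r,
            f1=f1.exact, degenerate=degenerate or f1.degenerate))
    return EvalReport(
        per_class=per_class,
        macro_precision=float(np.mean([m.precision for m in per_class])),
        macro_recall=float(np.mean([m.recall for m in per_class])),
        macro_f1=float(np.mean([m.f1 for m in per_class])),
        micro_accuracy=100.0 * sum(m.tp for m in per_class) / y_true.size,
        n_images=int(y_true.size),
    )
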