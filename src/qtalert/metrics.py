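"""Classification performance metrics.

The nine-metric panel used throughout the SAR evaluation: accuracy,
recall, precision, Matthews correlation coefficient, F1, balanced
accuracy, ROC AUC, average precision, sensitivity and specificity.
Threshold metrics are computed from explicit confusion counts by their
closed-form definitions; AUC uses the rank statistic over predicted
probabilities and AP the precision–recall curve.

Degenerate denominators have defined fallbacks: MCC is 0 whenever a
confusion-matrix marginal is zero, precision (and hence F1) is 0 when
nothing is predicted positive, and sensitivity/specificity are 0 when
their class is absent.

``auc_point`` is additionally reported: the one-operating-point
trapezoid AUC through (FPR, TPR), which algebraically equals balanced
accuracy. Some published panels report this quantity under the AUC
heading, so it is kept alongside the proper rank-based AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    recall: float
    precision: float
    mcc: float
    f1: float
    bacc: float
    auc: float
    ap: float
    se: float
    sp: float
    auc_point: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRIC_NAMES = tuple(f.name for f in fields(MetricSet))


def confusion_from_scores(
    y_true: np.ndarray, proba: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Threshold predicted positive-class probabilities (strictly above
    the threshold counts as positive) into confusion counts."""
    y_true = np.asarray(y_true).astype(int)
    pred = (np.asarray(proba, dtype=float) > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    return ConfusionCounts(tp, tn, fp, fn)


def compute_metrics(
    counts: ConfusionCounts,
    y_true: np.ndarray | None = None,
    proba: np.ndarray | None = None,
) -> MetricSet:
    """Full metric panel from confusion counts, plus AUC/AP from the
    per-sample probabilities when supplied (both 0.5 as a neutral
    placeholder otherwise)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.n
    if n == 0:
        raise ValueError("cannot compute metrics on an empty sample set")

    accuracy = (tp + tn) / n
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    bacc = (recall + sp) / 2

    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den) if mcc_den else 0.0

    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )

    if y_true is not None and proba is not None:
        y_true = np.asarray(y_true).astype(int)
        proba = np.asarray(proba, dtype=float)
        if len(np.unique(y_true)) < 2:
            auc = ap = 0.5
        else:
            auc = float(roc_auc_score(y_true, proba))
            ap = float(average_precision_score(y_true, proba))
    else:
        auc = ap = 0.5

    return MetricSet(
        accuracy=accuracy,
        recall=recall,
        precision=precision,
        mcc=mcc,
        f1=f1,
        bacc=bacc,
        auc=auc,
        ap=ap,
        se=recall,
        sp=sp,
        auc_point=bacc,
    )


def metrics_from_predictions(
    y_true: np.ndarray, proba: np.ndarray, threshold: float = 0.5
) -> MetricSet:
    """Convenience: confusion at the threshold plus score-based metrics."""
    counts = confusion_from_scores(y_true, proba, threshold)
    return compute_metrics(counts, y_true=y_true, proba=proba)
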