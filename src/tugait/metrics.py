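"""Classification evaluation: confusion matrix, accuracy, kappa, ROC AUC.

PD is the positive class and ET the negative class throughout. Kappa uses
the closed form in the confusion-matrix cells,

    kappa = 2 (TP·TN − FN·FP) / [(TP+FP)(FP+TN) + (TP+FN)(FN+TN)],

which is algebraically identical to Cohen's chance-corrected agreement.
AUC is computed rank-based (tie-aware), i.e. the normalized Mann–Whitney
U statistic. Degenerate denominators yield NaN with a warning instead of
raising, so batch evaluation stays robust.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import SchemaError, UndefinedMetricError

POSITIVE = "PD"
NEGATIVE = "ET"


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise SchemaError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclasses.dataclass
class MetricsReport:
    accuracy: float
    kappa: float
    sensitivity: float
    specificity: float
    auc: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def confusion(labels: Sequence[str], predictions: Sequence[str]) -> ConfusionMatrix:
    """Count TP/FN/TN/FP with PD positive."""
    labels = list(labels)
    predictions = list(predictions)
    if len(labels) != len(predictions):
        raise SchemaError(
            f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions"
        )
    bad = {x for x in labels + predictions} - {POSITIVE, NEGATIVE}
    if bad:
        raise SchemaError(f"labels must be PD/ET, got {sorted(bad)}")
    tp = sum(1 for y, p in zip(labels, predictions) if y == POSITIVE and p == POSITIVE)
    fn = sum(1 for y, p in zip(labels, predictions) if y == POSITIVE and p == NEGATIVE)
    tn = sum(1 for y, p in zip(labels, predictions) if y == NEGATIVE and p == NEGATIVE)
    fp = sum(1 for y, p in zip(labels, predictions) if y == NEGATIVE and p == POSITIVE)
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); returning NaN")
        return float("nan")
    return num / den


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Area under the ROC curve, rank-based with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == POSITIVE]
    neg = scores[labels == NEGATIVE]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def compute_metrics(
    cm: ConfusionMatrix,
    scores: Sequence[float] | None = None,
    labels: Sequence[str] | None = None,
) -> MetricsReport:
    """Accuracy, kappa, sensitivity, specificity, F1 and (optionally) AUC.

    AUC requires the per-subject continuous scores and their true labels;
    without them it is reported as NaN.
    """
    tp, fn, tn, fp = cm.tp, cm.fn, cm.tn, cm.fp
    accuracy = _safe_div(tp + tn, cm.n, "accuracy")
    kappa = _safe_div(
        2.0 * (tp * tn - fn * fp),
        (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn),
        "kappa",
    )
    sensitivity = _safe_div(tp, tp + fn, "sensitivity")
    specificity = _safe_div(tn, tn + fp, "specificity")
    f1 = _safe_div(2.0 * tp, 2.0 * tp + fp + fn, "F1")
    if scores is not None and labels is not None:
        auc = roc_auc(scores, labels)
    else:
        auc = float("nan")
    return MetricsReport(
        accuracy=accuracy,
        kappa=kappa,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        f1=f1,
    )


def roc_curve_points(
    scores: Sequence[float], labels: Sequence[str]
) -> list[tuple[float, float, float]]:
    """(threshold, TPR, FPR) points sweeping every distinct score."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE
    neg = labels == NEGATIVE
    if pos.sum() == 0 or neg.sum() == 0:
        raise UndefinedMetricError("ROC needs both classes present")
    points = []
    for thr in np.concatenate([[np.inf], np.unique(scores)[::-1]]):
        pred = scores >= thr
        tpr = (pred & pos).sum() / pos.sum()
        fpr = (pred & neg).sum() / neg.sum()
        points.append((float(thr), float(tpr), float(fpr)))
    return points
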