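"""Classification and segmentation metrics.

The positive class throughout is the artifact-free class (a patch without
artifacts).  Specificity is the standard TN / (TN + FP); note precision
TP / (TP + FP) is also reported separately, so every variant in circulation
can be derived from the returned counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "classification_metrics",
    "dice",
    "roc_points",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(labels, predictions, positive_class: int = 0) -> ConfusionCounts:
    """One-vs-rest confusion counts on the given positive class (default: the
    artifact-free code 0)."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    pos = labels == positive_class
    ppos = predictions == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos & ppos)),
        fn=int(np.sum(pos & ~ppos)),
        fp=int(np.sum(~pos & ppos)),
        tn=int(np.sum(~pos & ~ppos)),
    )


def classification_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity (recall), specificity, precision and F1.

    Metrics with a zero denominator are reported as ``nan``.
    """
    def ratio(num, den):
        return num / den if den else float("nan")

    accuracy = ratio(c.tp + c.tn, c.total)
    sensitivity = ratio(c.tp, c.tp + c.fn)
    specificity = ratio(c.tn, c.tn + c.fp)
    precision = ratio(c.tp, c.tp + c.fp)
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
    }


def dice(a, b) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|) between binary masks.

    Two empty masks score 1 (no-disagreement convention).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(a & b)) / denom


def roc_points(scores, labels):
    """ROC curve with thresholds = unique scores plus 0, rule score >= t.

    Returns ``(points, auc)`` where ``points`` is a list of
    ``(threshold, tpr, fpr)`` in descending-threshold order and ``auc`` is the
    trapezoidal area under the (fpr, tpr) curve, anchored at (0, 0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to trace a ROC curve")
    thresholds = np.unique(np.concatenate([scores, [0.0]]))[::-1]
    points = []
    tprs, fprs = [0.0], [0.0]
    for t in thresholds:
        tpr = float(np.sum(scores[pos] >= t)) / n_pos
        fpr = float(np.sum(scores[~pos] >= t)) / n_neg
        points.append((float(t), tpr, fpr))
        tprs.append(tpr)
        fprs.append(fpr)
    auc = float(np.trapezoid(tprs, fprs))
    return points, auc
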