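"""Held-out evaluation: ROC and PR curves, AUROC, AUPRC, precision/recall/F1.

Curve construction and the area computations are delegated to scikit-learn
(threshold sweep over distinct scores with ties grouped; trapezoidal AUROC;
step-wise right-continuous AUPRC, which avoids optimistic interpolation).
F1 is the harmonic mean 2 * precision * recall / (precision + recall), with
0/0 defined as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn import metrics as _skm

from .errors import MetricError

__all__ = ["MetricsReport", "roc_curve", "pr_curve", "f1_score", "compute_metrics"]


@dataclass
class MetricsReport:
    auroc: float
    auprc: float
    precision: float
    recall: float
    f1: float
    threshold: float
    roc_points: np.ndarray  # (k, 2) of (FPR, TPR)
    pr_points: np.ndarray  # (k, 2) of (recall, precision)

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "threshold": self.threshold,
            "roc_points": self.roc_points.tolist(),
            "pr_points": self.pr_points.tolist(),
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _check(scores, labels, need_both: bool = True):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise MetricError("scores and labels must be matching 1-D arrays")
    if not np.all(np.isin(labels, (0, 1))):
        raise MetricError("labels must be binary {0, 1}")
    if labels.sum() == 0:
        raise MetricError("no positive samples")
    if need_both and labels.sum() == labels.size:
        raise MetricError("no negative samples")
    return scores, labels


def roc_curve(scores, labels) -> tuple[np.ndarray, float]:
    """(FPR, TPR) points over all distinct thresholds, plus trapezoidal AUROC.

    The point list starts at (0, 0) and ends at (1, 1).
    """
    scores, labels = _check(scores, labels)
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    auroc = float(_skm.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), auroc


def pr_curve(scores, labels) -> tuple[np.ndarray, float]:
    """(recall, precision) points over all distinct thresholds, plus the
    step-wise AUPRC (average precision)."""
    scores, labels = _check(scores, labels, need_both=False)
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    auprc = float(_skm.average_precision_score(labels, scores))
    # sklearn returns points from high threshold to low; order by recall.
    order = np.argsort(recall)
    return np.column_stack([recall[order], precision[order]]), auprc


def f1_score(precision: float, recall: float) -> float:
    """F1 = 2 * P * R / (P + R); defined as 0 when P + R = 0."""
    if not 0 <= precision <= 1 or not 0 <= recall <= 1:
        raise MetricError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Full report: curves plus point metrics at the operating threshold."""
    roc_points, auroc = roc_curve(scores, labels)
    pr_points, auprc = pr_curve(scores, labels)
    scores_a, labels_a = _check(scores, labels)
    pred = (scores_a >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels_a == 1)))
    fp = int(np.sum((pred == 1) & (labels_a == 0)))
    fn = int(np.sum((pred == 0) & (labels_a == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return MetricsReport(
        auroc=auroc,
        auprc=auprc,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        threshold=threshold,
        roc_points=roc_points,
        pr_points=pr_points,
    )
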