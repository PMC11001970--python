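"""Classification metrics: confusion-matrix metrics, balanced accuracy, AUC.

Balanced accuracy (BAC) is the mean of sensitivity and specificity and is
the tuning / early-stopping criterion throughout the package.  AUC is the
Mann-Whitney probability that a random positive outscores a random
negative, with ties counted 1/2 (midrank convention).  F1 is defined as 0
when precision + recall is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["MetricReport", "confusion_metrics", "auc", "METRIC_NAMES"]

METRIC_NAMES = ("accuracy", "bac", "auc", "f1", "sensitivity", "specificity")


@dataclass(frozen=True)
class MetricReport:
    """One evaluation's metrics, all fractions in [0, 1]."""

    accuracy: float
    bac: float
    auc: float
    f1: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f.name} out of [0, 1]: {v}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _validate(labels, scores):
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-d arrays")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if np.min(scores) < 0 or np.max(scores) > 1:
        raise ValueError("scores must lie in [0, 1]")
    return labels, scores


def auc(labels, scores) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    labels, scores = _validate(labels, scores)
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: only one class present in labels")
    return float(roc_auc_score(labels, scores))


def confusion_metrics(labels, scores, threshold: float = 0.5) -> MetricReport:
    """Thresholded confusion-matrix metrics plus ranking AUC.

    Requires both classes present (sensitivity, specificity and AUC are
    otherwise undefined).
    """
    labels, scores = _validate(labels, scores)
    if labels.min() == labels.max():
        raise ValueError("metrics undefined: only one class present")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (2 * precision * sens / (precision + sens)
          if (precision + sens) > 0 else 0.0)
    return MetricReport(
        accuracy=(tp + tn) / labels.size,
        bac=0.5 * (sens + spec),
        auc=auc(labels, scores),
        f1=f1, sensitivity=sens, specificity=spec)
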