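"""Binary classification metrics reported on the percent scale."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["MetricsReport", "metrics_from_probabilities"]


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy/precision/recall/F1/AUC-ROC in percent, plus confusion counts.

    ``auc_roc`` is None when the evaluation set contains a single class
    (the ranking statistic is undefined there).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float | None
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return asdict(self)


def metrics_from_probabilities(p, y, threshold: float = 0.5) -> MetricsReport:
    """Confusion metrics at ``threshold`` and tie-aware rank AUC from ``p``."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: p {p.shape} vs y {y.shape}")
    yhat = (p > threshold).astype(np.int64)
    tp = int(np.sum((yhat == 1) & (y == 1)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    fn = int(np.sum((yhat == 0) & (y == 1)))
    n = len(y)
    accuracy = 100.0 * (tp + tn) / n
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    auc = 100.0 * float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else None
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        auc_roc=auc, tp=tp, fp=fp, tn=tn, fn=fn,
    )
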