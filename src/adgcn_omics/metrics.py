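"""Classification metrics and cross-validation fold planning.

Every metric here is computed from first principles on the confusion matrix
(or, for AUC, from midranks), so that they can be checked against brute-force
enumeration oracles. Conventions for degenerate cases:

* MCC with a zero denominator (e.g. a constant prediction) is defined as 0.
* AUC requires both classes; it is an error to call it otherwise.

Classes are binary and encoded 0/1 throughout; 1 is the positive (more
severe) class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger("adgcn_omics")

__all__ = [
    "confusion_counts",
    "mcc",
    "accuracy",
    "precision",
    "f1",
    "g_mean",
    "auc",
    "FoldPlan",
    "stratified_folds",
    "MetricsReport",
    "fold_metrics",
]


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return y


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    """Return (TP, TN, FP, FN) for binary 0/1 labels."""
    yt, yp = _as_binary(y_true), _as_binary(y_pred)
    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    return tp, tn, fp, fn


def mcc(y_true, y_pred) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    tp, tn, fp, fn = confusion_counts(y_true, y_pred)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.debug("mcc: zero denominator, returning 0 by convention")
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def accuracy(y_true, y_pred) -> float:
    tp, tn, fp, fn = confusion_counts(y_true, y_pred)
    return float((tp + tn) / (tp + tn + fp + fn))


def precision(y_true, y_pred) -> float:
    """Positive predictive value; 0 when nothing is predicted positive."""
    tp, _, fp, _ = confusion_counts(y_true, y_pred)
    return float(tp / (tp + fp)) if (tp + fp) > 0 else 0.0


def f1(y_true, y_pred) -> float:
    tp, _, fp, fn = confusion_counts(y_true, y_pred)
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom > 0 else 0.0


def g_mean(y_true, y_pred) -> float:
    """Geometric mean of sensitivity and specificity."""
    tp, tn, fp, fn = confusion_counts(y_true, y_pred)
    sens = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    spec = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    return float(np.sqrt(sens * spec))


def auc(y_true, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with midranks for ties."""
    yt = _as_binary(y_true)
    scores = np.asarray(scores, dtype=float)
    n1 = int(yt.sum())
    n0 = len(yt) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("auc requires both classes present")
    ranks = rankdata(scores)
    u = ranks[yt == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class FoldPlan:
    """A seeded stratified k-fold partition of sample indices."""

    n_folds: int
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    stratified: bool
    seed: int

    def __iter__(self):
        return iter(self.folds)


def stratified_folds(labels, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded stratified CV plan; every fold contains both classes."""
    y = _as_binary(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < n_folds={n_folds}; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(y)), y)]
    return FoldPlan(n_folds=n_folds, folds=folds, stratified=True, seed=seed)


@dataclass
class MetricsReport:
    """Per-fold and aggregate classification metrics.

    ``aggregate`` holds the unweighted mean over folds for each metric.
    """

    per_fold: list[dict[str, float]]
    aggregate: dict[str, float]
    seed: int
    config_snapshot: dict = field(default_factory=dict)

    @classmethod
    def from_folds(cls, fold_rows: Sequence[dict[str, float]], seed: int,
                   config_snapshot: dict | None = None) -> "MetricsReport":
        keys = fold_rows[0].keys()
        agg = {k: float(np.mean([r[k] for r in fold_rows])) for k in keys}
        return cls(per_fold=list(fold_rows), aggregate=agg, seed=seed,
                   config_snapshot=dict(config_snapshot or {}))

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "aggregate": self.aggregate,
            "seed": self.seed,
            "config_snapshot": self.config_snapshot,
        }


def fold_metrics(y_true, y_pred, scores=None) -> dict[str, float]:
    """The standard metric row used throughout: MCC, accuracy, precision,
    F1, G-mean and (when scores are given) AUC."""
    row = {
        "mcc": mcc(y_true, y_pred),
        "accuracy": accuracy(y_true, y_pred),
        "precision": precision(y_true, y_pred),
        "f1": f1(y_true, y_pred),
        "g_mean": g_mean(y_true, y_pred),
    }
    if scores is not None:
        row["auc"] = auc(y_true, scores)
    return row
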