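"""Hybrid class balancing at the decision boundary.

Minority samples are categorized by the composition of their m nearest
neighbors (borderline-SMOTE1 taxonomy): all-majority neighborhoods are
NOISE, at-least-half-majority are DANGER (boundary), the rest SAFE. The
hybrid balancer first removes majority samples adjacent to DANGER minority
neighborhoods (borderline undersampling), then interpolates new minority
samples between DANGER points and their nearest minority neighbors
(borderline-SMOTE) until the imbalance ratio reaches the target. NOISE
minority samples never seed synthesis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("adgcn_omics")

__all__ = [
    "imbalance_ratio",
    "BoundaryLabels",
    "classify_boundary",
    "borderline_smote",
    "borderline_undersample",
    "hybrid_balance",
    "BalanceResult",
    "SAFE", "DANGER", "NOISE",
]

SAFE, DANGER, NOISE = "SAFE", "DANGER", "NOISE"


def imbalance_ratio(y) -> float:
    """IR = n_majority / n_minority (>= 1). Requires both classes."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("imbalance_ratio requires exactly two classes")
    return float(counts.max() / counts.min())


def _split_classes(y):
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts[0] == counts[1]:
        maj, mino = classes[0], classes[1]   # tie: first label as majority
    else:
        maj = classes[np.argmax(counts)]
        mino = classes[np.argmin(counts)]
    return maj, mino


@dataclass
class BoundaryLabels:
    minority_indices: np.ndarray       # indices into X of minority samples
    minority_category: np.ndarray      # SAFE/DANGER/NOISE per minority sample
    majority_indices: np.ndarray
    majority_boundary: np.ndarray      # bool per majority sample
    majority_danger_hits: np.ndarray   # DANGER neighborhoods containing it
    m_neighbors: int


def classify_boundary(X, y, m: int = 5) -> BoundaryLabels:
    """Borderline taxonomy of the minority class plus majority boundary flags.

    A minority point whose m nearest neighbors (any class, self excluded)
    are all majority is NOISE; at least half majority is DANGER; otherwise
    SAFE. A majority point is boundary-flagged iff it appears among the m
    nearest neighbors of some DANGER minority point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if m >= n:
        raise ValueError("m must be smaller than the sample count")
    maj, mino = _split_classes(y)
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    minority_idx = np.where(y == mino)[0]
    majority_idx = np.where(y == maj)[0]
    cats = []
    hits = np.zeros(n, dtype=int)
    for i in minority_idx:
        nn = np.argsort(D[i], kind="stable")[:m]
        n_maj = int(np.sum(y[nn] == maj))
        if n_maj == m:
            cats.append(NOISE)
        elif n_maj >= m / 2.0:
            cats.append(DANGER)
            for j in nn[y[nn] == maj]:
                hits[j] += 1
        else:
            cats.append(SAFE)
    return BoundaryLabels(
        minority_indices=minority_idx,
        minority_category=np.array(cats),
        majority_indices=majority_idx,
        majority_boundary=hits[majority_idx] > 0,
        majority_danger_hits=hits[majority_idx],
        m_neighbors=m,
    )


def borderline_smote(X, y, m: int = 5, k: int = 5, n_new: int = 0,
                     seed: int = 0, u_override: float | None = None
                     ) -> np.ndarray:
    """Synthesize n_new minority rows on segments between DANGER points and
    their k nearest minority neighbors.

    Each synthetic row is d + u (nn - d) with u ~ Uniform(0,1) (or the
    u_override test hook). Generation cycles through DANGER points in index
    order. With no DANGER points, returns zero rows with a warning (the
    classes are either separated or fully mixed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, mino = _split_classes(y)
    minority_idx = np.where(y == mino)[0]
    if k > len(minority_idx) - 1:
        raise ValueError("k must be <= n_minority - 1")
    boundary = classify_boundary(X, y, m=m)
    danger = boundary.minority_indices[boundary.minority_category == DANGER]
    if danger.size == 0:
        logger.warning("borderline_smote: no DANGER minority samples; "
                       "no synthesis possible")
        return np.empty((0, X.shape[1]))
    rng = np.random.default_rng(seed)
    Dm = cdist(X[danger], X[minority_idx])
    # nearest minority neighbors of each danger point, self excluded
    nn_lists = []
    for r, i in enumerate(danger):
        row = Dm[r].copy()
        row[minority_idx == i] = np.inf
        nn_lists.append(minority_idx[np.argsort(row, kind="stable")[:k]])
    out = np.empty((n_new, X.shape[1]))
    for t in range(n_new):
        r = t % len(danger)
        d = X[danger[r]]
        nn = X[rng.choice(nn_lists[r])]
        u = rng.random() if u_override is None else u_override
        out[t] = d + u * (nn - d)
    return out


def borderline_undersample(X, y, m: int = 5, fraction: float = 0.0,
                           seed: int = 0) -> np.ndarray:
    """Boolean keep-mask removing ceil(fraction * n_boundary) boundary
    majority samples.

    Removal order: decreasing count of DANGER-minority neighborhoods the
    majority point appears in, ties broken by a seeded shuffle.
    Non-boundary majority samples are never removed.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    keep = np.ones(len(y), dtype=bool)
    b = classify_boundary(X, y, m=m)
    flagged = b.majority_indices[b.majority_boundary]
    if fraction == 0 or flagged.size == 0:
        return keep
    n_remove = math.ceil(fraction * flagged.size)
    hits = b.majority_danger_hits[b.majority_boundary]
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(flagged.size)
    order = np.lexsort((tiebreak, -hits))
    keep[flagged[order[:n_remove]]] = False
    return keep


@dataclass
class BalanceResult:
    X_out: np.ndarray
    y_out: np.ndarray
    n_synthetic: int
    n_removed: int
    ir_before: float
    ir_after: float

    def to_dict(self) -> dict:
        return {"n_synthetic": self.n_synthetic, "n_removed": self.n_removed,
                "ir_before": self.ir_before, "ir_after": self.ir_after}


def hybrid_balance(X, y, target_ir: float = 1.0, m: int = 5, k: int = 5,
                   seed: int = 0) -> BalanceResult:
    """Borderline undersampling followed by borderline-SMOTE oversampling.

    Undersampling removes boundary majority points up to half of the
    majority-minority gap; oversampling then adds DANGER-seeded synthetic
    minority rows until IR <= target_ir (within 5%). With no DANGER
    samples the oversampling step is skipped.
    """
    if target_ir < 1:
        raise ValueError("target_ir must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ir_before = imbalance_ratio(y)
    maj, mino = _split_classes(y)
    n_maj = int(np.sum(y == maj))
    n_min = int(np.sum(y == mino))

    cap = (n_maj - n_min) // 2
    b = classify_boundary(X, y, m=m)
    n_flagged = int(b.majority_boundary.sum())
    n_remove = min(cap, n_flagged)
    if n_remove > 0:
        keep = borderline_undersample(X, y, m=m,
                                      fraction=n_remove / n_flagged,
                                      seed=seed)
    else:
        keep = np.ones(len(y), dtype=bool)
    X1, y1 = X[keep], y[keep]
    n_maj1 = int(np.sum(y1 == maj))
    n_min1 = int(np.sum(y1 == mino))

    n_new = 0
    if n_maj1 / n_min1 > target_ir * 1.05:
        n_needed = math.ceil(n_maj1 / target_ir) - n_min1
        k_eff = min(k, n_min1 - 1)
        if k_eff < 1:
            logger.warning("hybrid_balance: minority class too small for "
                           "SMOTE neighbors; skipping oversampling")
            synth = np.empty((0, X1.shape[1]))
        else:
            synth = borderline_smote(X1, y1, m=m, k=k_eff, n_new=n_needed,
                                     seed=seed)
        n_new = len(synth)
        if n_new:
            X1 = np.vstack([X1, synth])
            y1 = np.concatenate([y1, np.full(n_new, mino, dtype=y.dtype)])
    ir_after = imbalance_ratio(y1) if len(np.unique(y1)) == 2 else 1.0
    logger.info("hybrid_balance: IR %.3f -> %.3f (removed %d, synthesized %d)",
                ir_before, ir_after, int((~keep).sum()), n_new)
    return BalanceResult(X_out=X1, y_out=y1, n_synthetic=n_new,
                         n_removed=int((~keep).sum()),
                         ir_before=ir_before, ir_after=ir_after)
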