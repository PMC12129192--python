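"""Methylation marker selection.

Reduces an island-annotated beta matrix (samples x probes, values in [0,1])
to a small marker panel through a fixed cascade:

    KNN imputation -> per-probe Welch t test -> Benjamini-Hochberg q < 0.001
    -> CpG-island restriction -> class balancing (see `imbalance`) ->
    Fisher-score quantile filter (default: drop the lowest quartile, i.e.
    keep probes above the 25th-percentile score) -> positive stump
    information gain -> random-forest importance top-k -> incremental SVM
    evaluation -> final top markers.

The differential test is a Welch two-sample t test on beta values — a
deliberate self-contained simplification of array pipelines that use
moderated statistics. The entropy filter is realized as best single
threshold (decision stump) information gain in bits, which makes "zero
information gain" well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .imbalance import hybrid_balance
from .metrics import MetricsReport, fold_metrics, stratified_folds

logger = logging.getLogger("adgcn_omics")

__all__ = [
    "ProbePanel",
    "knn_impute_beta",
    "differential_probe_test",
    "bh_adjust",
    "prefilter_probes",
    "fisher_score",
    "top_quantile_mask",
    "stump_information_gain",
    "rf_rank",
    "incremental_svm_eval",
    "select_markers",
    "MarkerSelection",
]


@dataclass
class ProbePanel:
    """Per-probe statistics accumulated along the selection cascade."""

    probe_ids: list[str]
    beta: np.ndarray                   # samples x probes
    island: np.ndarray                 # bool per probe
    p_value: np.ndarray | None = None
    q_value: np.ndarray | None = None
    fisher: np.ndarray | None = None
    info_gain: np.ndarray | None = None
    rf_rank: np.ndarray | None = None

    def subset(self, mask) -> "ProbePanel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.where(mask)[0]
        else:
            idx = mask

        def take(a):
            return None if a is None else a[idx]

        return ProbePanel(
            probe_ids=[self.probe_ids[i] for i in idx],
            beta=self.beta[:, idx],
            island=self.island[idx],
            p_value=take(self.p_value),
            q_value=take(self.q_value),
            fisher=take(self.fisher),
            info_gain=take(self.info_gain),
            rf_rank=take(self.rf_rank),
        )


def knn_impute_beta(beta, k: int = 100) -> np.ndarray:
    """Impute missing beta values from the k nearest samples.

    Distances are Euclidean over probes observed in both samples, scaled to
    the full probe count. A probe missing in every sample is dropped after a
    warning (callers should align probe ids via the returned column mask if
    that happens; here we impute the column to 0.5 and warn instead to keep
    shapes stable for the cascade).
    """
    B = np.asarray(beta, dtype=float).copy()
    n = B.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError("k must be in [1, n_samples - 1]")
    all_missing = np.isnan(B).all(axis=0)
    if all_missing.any():
        logger.warning("knn_impute_beta: %d probes missing in all samples; "
                       "filled with 0.5", int(all_missing.sum()))
        B[:, all_missing] = 0.5
    if not np.isnan(B).any():
        return np.clip(B, 0.0, 1.0)
    obs = ~np.isnan(B)
    filled = np.where(obs, B, 0.0)
    for i in np.where(~obs.all(axis=1))[0]:
        shared = obs & obs[i]                       # per (other, probe)
        diff = (filled - filled[i]) * shared
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2 = (diff ** 2).sum(axis=1) / np.maximum(n_shared, 1)
        d2[i] = np.inf
        d2[n_shared == 0] = np.inf
        order = np.argsort(d2, kind="stable")[:k]
        for j in np.where(~obs[i])[0]:
            donors = order[obs[order, j]]
            if donors.size == 0:
                donors = np.where(obs[:, j])[0]
            B[i, j] = filled[donors, j].mean() if donors.size else 0.5
    return np.clip(B, 0.0, 1.0)


def differential_probe_test(beta, labels) -> np.ndarray:
    """Two-sided Welch t-test p-value per probe.

    Degenerate probes (zero variance in both groups): p = 1 when the group
    means agree, else p ~ 0 (perfect separation).
    """
    B = np.asarray(beta, dtype=float)
    y = np.asarray(labels).astype(int)
    g0, g1 = B[y == 0], B[y == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("both classes need >= 2 samples")
    with np.errstate(all="ignore"):
        res = ttest_ind(g0, g1, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        same_mean = np.isclose(g0.mean(axis=0), g1.mean(axis=0))
        p[degenerate & same_mean] = 1.0
        p[degenerate & ~same_mean] = np.finfo(float).tiny
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, order preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def prefilter_probes(panel: ProbePanel, q_max: float = 0.001,
                     islands_only: bool = True) -> ProbePanel:
    """Retain probes with q < q_max that sit on CpG islands."""
    if panel.q_value is None:
        raise ValueError("q-values not computed")
    keep = panel.q_value < q_max
    if islands_only:
        keep &= panel.island
    if not keep.any():
        raise ValueError(
            f"no probe survives q < {q_max} (islands_only={islands_only}); "
            f"min q = {panel.q_value.min():.3g} — consider relaxing q_max"
        )
    return panel.subset(keep)


def fisher_score(X, y) -> np.ndarray:
    """Fisher score per feature:
    F_j = sum_c n_c (mu_cj - mu_j)^2 / (sum_c n_c var_cj + eps)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in np.unique(y):
        Xc = X[y == c]
        nc = len(Xc)
        num += nc * (Xc.mean(axis=0) - mu) ** 2
        den += nc * Xc.var(axis=0)
    return num / (den + 1e-12)


def top_quantile_mask(scores, keep_top: float = 0.25) -> np.ndarray:
    """Boolean mask of the ceil(keep_top * m) highest scores; ties at the
    cut resolved in favor of lower feature index."""
    if not (0 < keep_top <= 1):
        raise ValueError("keep_top must be in (0, 1]")
    s = np.asarray(scores, dtype=float)
    m = s.size
    n_keep = int(np.ceil(keep_top * m))
    order = np.lexsort((np.arange(m), -s))  # by -score, then feature index
    mask = np.zeros(m, dtype=bool)
    mask[order[:n_keep]] = True
    return mask


def _entropy(y) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def stump_information_gain(x, y) -> float:
    """Best single-threshold information gain (bits) of feature x for
    binary y; thresholds at midpoints of consecutive sorted unique values.
    Constant x has zero gain."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    uniq = np.unique(x)
    if uniq.size < 2:
        return 0.0
    h0 = _entropy(y)
    n = len(y)
    best = 0.0
    for t in (uniq[:-1] + uniq[1:]) / 2.0:
        left = x <= t
        nl = int(left.sum())
        h = (nl / n) * _entropy(y[left]) + ((n - nl) / n) * _entropy(y[~left])
        best = max(best, h0 - h)
    return float(best)


def rf_rank(X, y, n_top: int = 50, n_trees: int = 200, seed: int = 0):
    """Random-forest mean-impurity-decrease feature ranking.

    Returns (ranked feature indices, importances aligned to the ranking).
    Ties break toward the lower feature index.
    """
    from sklearn.ensemble import RandomForestClassifier

    X = np.asarray(X, dtype=float)
    if n_top > X.shape[1]:
        raise ValueError("n_top exceeds the number of features")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                n_jobs=1)
    rf.fit(X, np.asarray(y).astype(int))
    imp = rf.feature_importances_
    order = np.lexsort((np.arange(len(imp)), -imp))[:n_top]
    return order, imp[order]


def incremental_svm_eval(X_ranked, y, n_folds: int = 5, seed: int = 0,
                         k_max: int | None = None) -> list[MetricsReport]:
    """Stratified-CV margin-classifier metrics for each prefix size k.

    Columns of X_ranked must already be in rank order; element k-1 of the
    returned list holds the G-mean/accuracy/precision/F1 report at k
    features.
    """
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = np.asarray(X_ranked, dtype=float)
    y = np.asarray(y).astype(int)
    k_max = X.shape[1] if k_max is None else min(k_max, X.shape[1])
    plan = stratified_folds(y, n_folds=n_folds, seed=seed)
    reports = []
    for k in range(1, k_max + 1):
        rows = []
        for tr, te in plan:
            clf = make_pipeline(StandardScaler(), SVC(random_state=seed))
            clf.fit(X[tr, :k], y[tr])
            rows.append(fold_metrics(y[te], clf.predict(X[te, :k])))
        reports.append(MetricsReport.from_folds(
            rows, seed=seed, config_snapshot={"k_features": k}))
    return reports


@dataclass
class MarkerSelection:
    """Outcome of the full selection cascade."""

    panel: ProbePanel                  # surviving probes with statistics
    selected_ids: list[str]            # final marker probe ids (rank order)
    selected_indices: np.ndarray       # indices into the ORIGINAL probe set
    stage_counts: dict[str, int]
    svm_reports: list[MetricsReport] = field(default_factory=list)


def select_markers(beta, labels, island, probe_ids=None, *,
                   q_max: float = 0.001, islands_only: bool = True,
                   keep_top: float = 0.75, n_top_rf: int = 50,
                   n_final: int = 10, target_ir: float = 1.0,
                   knn_k: int = 10, run_svm_eval: bool = False,
                   seed: int = 0) -> MarkerSelection:
    """Run the full cascade and return the top marker probes.

    Balancing is applied after the differential prefilter and before the
    filter/embedded selection stages, so Fisher, information-gain and
    random-forest scores are computed on the balanced data; the returned
    beta panel keeps the original (unbalanced) samples.
    """
    B = np.asarray(beta, dtype=float)
    y = np.asarray(labels).astype(int)
    island = np.asarray(island, dtype=bool)
    if probe_ids is None:
        probe_ids = [f"probe{j}" for j in range(B.shape[1])]
    if np.isnan(B).any():
        B = knn_impute_beta(B, k=min(knn_k, B.shape[0] - 1))
    orig_index = np.arange(B.shape[1])
    panel = ProbePanel(probe_ids=list(probe_ids), beta=B, island=island)
    panel.p_value = differential_probe_test(B, y)
    panel.q_value = bh_adjust(panel.p_value)
    stage = {"input": B.shape[1]}
    keep0 = (panel.q_value < q_max) & (panel.island if islands_only else True)
    if not keep0.any():
        raise ValueError("no probe survives the q/island prefilter")
    panel = panel.subset(keep0)
    orig_index = orig_index[keep0]
    stage["prefilter"] = len(panel.probe_ids)

    bal = hybrid_balance(panel.beta, y, target_ir=target_ir, seed=seed)
    Xb, yb = bal.X_out, bal.y_out

    panel.fisher = fisher_score(Xb, yb)
    fmask = top_quantile_mask(panel.fisher, keep_top=keep_top)
    panel = panel.subset(fmask)
    orig_index = orig_index[fmask]
    Xb = Xb[:, fmask]
    stage["fisher"] = len(panel.probe_ids)

    panel.info_gain = np.array(
        [stump_information_gain(Xb[:, j], yb) for j in range(Xb.shape[1])])
    gmask = panel.info_gain > 0
    if not gmask.any():
        raise ValueError("all probes have zero information gain")
    panel = panel.subset(gmask)
    orig_index = orig_index[gmask]
    Xb = Xb[:, gmask]
    stage["info_gain"] = len(panel.probe_ids)

    n_top = min(n_top_rf, Xb.shape[1])
    ranked, _ = rf_rank(Xb, yb, n_top=n_top, seed=seed)
    rank_vec = np.full(len(panel.probe_ids), -1)
    rank_vec[ranked] = np.arange(n_top)
    panel.rf_rank = rank_vec
    stage["rf_top"] = n_top

    reports = []
    if run_svm_eval:
        reports = incremental_svm_eval(Xb[:, ranked], yb, seed=seed)
    final = ranked[:min(n_final, n_top)]
    stage["final"] = len(final)
    logger.info("select_markers: %s", stage)
    return MarkerSelection(
        panel=panel,
        selected_ids=[panel.probe_ids[i] for i in final],
        selected_indices=orig_index[final],
        stage_counts=stage,
        svm_reports=reports,
    )
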