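"""Polygenic risk scoring and evaluation.

Two PRS constructions are implemented:

* **P+T** (pruning/clumping then p-value thresholding): greedy LD clumping
  keeps, per block, index SNPs in ascending p order and discards their LD
  partners at r^2 >= threshold; scoring then uses clumped SNPs passing each
  candidate p threshold, with the threshold chosen to maximize Nagelkerke's
  R^2 of a label~PRS logistic fit.
* **LDpred-inf**: the analytic infinitesimal-model posterior mean,
  per LD block B:  w_B = (D_B + (M/(N h^2)) I)^-1 b_B,
  with D the block dosage-correlation matrix, b the marginal log-odds,
  M the panel size, N the discovery sample size and h^2 the assumed
  heritability. (The Gibbs-sampled point-mixture variant is a different,
  stochastic estimator and is not provided; PRS-CS and lassosum are
  published standalone tools and are only stubbed.)

Evaluation: Nagelkerke's R^2 from the log-likelihoods of the in-package
IRLS logistic solver (avoids cross-library likelihood conventions),
stratified-CV AUC of BDI vs BDI+PRS logistic models, and the two-sample
KS statistic for distributional comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .metrics import auc as rank_auc
from .metrics import stratified_folds
from .qc import mean_impute

logger = logging.getLogger("adgcn_omics")

__all__ = [
    "LdBlocks",
    "PrsResult",
    "ld_from_genotypes",
    "clump",
    "prs_pt",
    "ldpred_inf",
    "score",
    "fit_logistic",
    "nagelkerke_r2",
    "evaluate_bdi_prs",
    "ks_two_sample",
    "prs_cs",
    "lassosum",
    "default_p_grid",
]


@dataclass
class LdBlocks:
    """Block partition of the SNP panel with per-block dosage correlations."""

    block_index: np.ndarray            # per-SNP block id, len = n_snps
    matrices: dict[int, np.ndarray]    # block id -> correlation matrix

    def snps_in(self, b: int) -> np.ndarray:
        return np.where(self.block_index == b)[0]


@dataclass
class PrsResult:
    method: str                        # "PT" | "LDPRED_INF"
    weights: np.ndarray                # per-panel-SNP effect used in scoring
    scores: np.ndarray                 # per-sample PRS
    tuning: dict
    r2_nagelkerke: float


def ld_from_genotypes(genotypes, block_index, ridge: float = 1e-6) -> LdBlocks:
    """Per-block Pearson correlation of mean-imputed dosages.

    A constant SNP gets zero off-diagonal correlation; a ridge is added to
    the diagonal so every block matrix stays positive semidefinite.
    """
    G = mean_impute(genotypes)
    if G.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate LD")
    block_index = np.asarray(block_index)
    mats = {}
    for b in np.unique(block_index):
        idx = np.where(block_index == b)[0]
        sub = G[:, idx]
        sd = sub.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(sub, rowvar=False)
        R = np.atleast_2d(R)
        bad = sd == 0
        if bad.any():
            R[bad, :] = 0.0
            R[:, bad] = 0.0
        np.fill_diagonal(R, 1.0)
        R = np.nan_to_num(R, nan=0.0)
        R[np.diag_indices_from(R)] += ridge
        mats[int(b)] = R
    return LdBlocks(block_index=block_index, matrices=mats)


def clump(stats: pd.DataFrame, ld: LdBlocks, r2_threshold: float = 0.1
          ) -> np.ndarray:
    """Greedy LD clumping. Returns the sorted index-SNP set (panel indices).

    Repeatedly claim the unclaimed SNP with the smallest p (ties broken by
    SNP id lexicographic order) as an index SNP and discard all unclaimed
    SNPs in its block with r^2 >= r2_threshold.
    """
    if stats.empty:
        return np.array([], dtype=int)
    snp_order = stats.sort_values(
        ["P", "SNP"], key=lambda s: s.astype(str).str.zfill(12)
        if s.name == "SNP" else s
    )
    # positions in the panel; stats SNP column stores panel indices
    claimed: set[int] = set()
    removed: set[int] = set()
    index_snps = []
    pos_in_block = {}
    for b, mat in ld.matrices.items():
        for local, j in enumerate(ld.snps_in(b)):
            pos_in_block[int(j)] = (b, local)
    for _, row in snp_order.iterrows():
        j = int(row["SNP"])
        if j in claimed or j in removed:
            continue
        index_snps.append(j)
        claimed.add(j)
        b, local = pos_in_block[j]
        mat = ld.matrices[b]
        for other_local, other in enumerate(ld.snps_in(b)):
            other = int(other)
            if other in claimed or other in removed:
                continue
            if mat[local, other_local] ** 2 >= r2_threshold:
                removed.add(other)
    return np.array(sorted(index_snps), dtype=int)


def score(genotypes, weights, snp_indices=None) -> np.ndarray:
    """PRS_i = sum_j w_j * dosage_ij with per-SNP mean substitution for
    missing dosages.

    weights may be a full panel-length vector, or paired with snp_indices
    selecting columns of the genotype matrix.
    """
    G = np.asarray(genotypes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if snp_indices is not None:
        snp_indices = np.asarray(snp_indices, dtype=int)
        if snp_indices.size and snp_indices.max() >= G.shape[1]:
            missing = snp_indices[snp_indices >= G.shape[1]]
            raise KeyError(f"weights refer to SNPs absent from genotypes: "
                           f"{missing.tolist()}")
        G = G[:, snp_indices]
    elif w.shape[0] != G.shape[1]:
        raise KeyError("weight vector length does not match genotype panel")
    return mean_impute(G) @ w


def fit_logistic(X, y, max_iter: int = 100, tol: float = 1e-10,
                 ridge: float = 1e-8):
    """Newton-IRLS logistic regression with an intercept.

    Returns (coef including intercept first, log-likelihood). The tiny ridge
    stabilizes separable fits; the reported log-likelihood is of the fitted
    probabilities.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(A.shape[1])
    for _ in range(max_iter):
        eta = np.clip(A @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = A.T @ (y - p) - ridge * beta
        H = (A * W[:, None]).T @ A + ridge * np.eye(A.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(A @ beta, -30, 30)
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return beta, loglik


def null_loglik(y) -> float:
    """Log-likelihood of the intercept-only logistic model (closed form)."""
    y = np.asarray(y, dtype=float)
    p = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's rescaling of the Cox-Snell pseudo-R^2, clipped to [0,1].

    R2_CS = 1 - exp(2 (ll_null - ll_full) / n); R2 = R2_CS / (1 - exp(2 ll_null / n)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r2_cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    if denom <= 0:
        return 0.0
    return float(np.clip(r2_cs / denom, 0.0, 1.0))


def default_p_grid(n_points: int = 50) -> np.ndarray:
    """Logarithmic p-threshold grid from 5e-8 to 1."""
    return np.logspace(np.log10(5e-8), 0.0, n_points)


def prs_pt(genotypes, labels, stats: pd.DataFrame, ld: LdBlocks,
           p_grid=None, r2_threshold: float = 0.1) -> PrsResult:
    """P+T polygenic score with in-sample tuning of the p threshold.

    For each threshold in the grid, score with the clumped SNPs at p <= p_T
    (weights = marginal BETA) and evaluate Nagelkerke's R^2 of the
    label~PRS logistic fit; keep the best threshold.
    """
    if p_grid is None:
        p_grid = default_p_grid()
    p_grid = np.asarray(p_grid, dtype=float)
    if p_grid.size == 0:
        raise ValueError("p_grid must be nonempty")
    index_snps = clump(stats, ld, r2_threshold=r2_threshold)
    stats_idx = stats.set_index("SNP")
    clumped = stats_idx.loc[stats_idx.index.intersection(index_snps)]
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(labels)
    ll0 = null_loglik(y)
    best = None
    any_pass = False
    for p_t in np.sort(p_grid):
        sel = clumped[clumped["P"] <= p_t]
        if sel.empty:
            continue
        any_pass = True
        idx = sel.index.to_numpy(dtype=int)
        w = sel["BETA"].to_numpy(float)
        s = score(G, w, snp_indices=idx)
        if np.std(s) == 0:
            r2 = 0.0
        else:
            _, ll = fit_logistic((s - s.mean()) / s.std(), y)
            r2 = nagelkerke_r2(ll, ll0, len(y))
        if best is None or r2 > best["r2"]:
            best = {"r2": r2, "p_t": float(p_t), "idx": idx, "w": w, "s": s}
    if not any_pass:
        raise ValueError(
            f"no SNP passes any threshold in the grid; smallest p in stats "
            f"is {stats['P'].min():.3g}"
        )
    weights_full = np.zeros(len(ld.block_index))
    weights_full[best["idx"]] = best["w"]
    return PrsResult(
        method="PT", weights=weights_full, scores=best["s"],
        tuning={"p_threshold": best["p_t"], "n_snps": int(len(best["idx"])),
                "r2_grid_best": best["r2"],
                "index_snps": best["idx"].tolist()},
        r2_nagelkerke=best["r2"],
    )


def ldpred_inf(stats: pd.DataFrame, ld: LdBlocks, n_gwas: int, h2: float
               ) -> np.ndarray:
    """Infinitesimal-model LDpred weights, solved block by block.

    Per block: w = (D + (M/(N h^2)) I)^-1 b, with M the total panel size.
    Returns a panel-length weight vector (zero where stats carry no SNP).
    """
    if not (0 < h2 <= 1):
        raise ValueError("h2 must be in (0, 1]")
    if n_gwas <= 0:
        raise ValueError("n_gwas must be positive")
    m_total = len(ld.block_index)
    shrink = m_total / (n_gwas * h2)
    beta = np.zeros(m_total)
    have = np.zeros(m_total, dtype=bool)
    snp_idx = stats["SNP"].to_numpy(dtype=int)
    beta[snp_idx] = stats["BETA"].to_numpy(float)
    have[snp_idx] = True
    weights = np.zeros(m_total)
    for b, D in ld.matrices.items():
        idx = ld.snps_in(b)
        sub = have[idx]
        if not sub.any():
            continue
        ii = idx[sub]
        loc = np.where(sub)[0]
        A = D[np.ix_(loc, loc)] + shrink * np.eye(len(loc))
        try:
            weights[ii] = np.linalg.solve(A, beta[ii])
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"singular LDpred-inf system in block {b}") from e
    return weights


def prs_cs(*args, **kwargs):
    """PRS-CS is a published standalone tool (continuous-shrinkage prior);
    it is intentionally not reimplemented here."""
    raise NotImplementedError(
        "PRS-CS is an external published method; use the PRScs package. "
        "This framework implements P+T (prs_pt) and LDpred-inf (ldpred_inf)."
    )


def lassosum(*args, **kwargs):
    """lassosum is a published standalone tool (penalized regression on
    summary statistics); it is intentionally not reimplemented here."""
    raise NotImplementedError(
        "lassosum is an external published method; use the lassosum R "
        "package. This framework implements P+T and LDpred-inf."
    )


def evaluate_bdi_prs(clinical_bdi, prs, labels, n_folds: int = 5,
                     seed: int = 0) -> dict:
    """Stratified-CV logistic AUC of BDI alone versus BDI + PRS.

    Returns per-fold and mean AUC for both feature sets plus the delta.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    X_bdi = np.asarray(clinical_bdi, dtype=float)
    if X_bdi.ndim == 1:
        X_bdi = X_bdi[:, None]
    s = np.asarray(prs, dtype=float)[:, None]
    y = np.asarray(labels)
    plan = stratified_folds(y, n_folds=n_folds, seed=seed)
    auc_bdi, auc_both = [], []
    for tr, te in plan:
        for X, out in ((X_bdi, auc_bdi), (np.hstack([X_bdi, s]), auc_both)):
            clf = make_pipeline(StandardScaler(),
                                LogisticRegression(max_iter=1000))
            clf.fit(X[tr], y[tr])
            out.append(rank_auc(y[te], clf.predict_proba(X[te])[:, 1]))
    return {
        "auc_bdi_folds": auc_bdi,
        "auc_bdi_prs_folds": auc_both,
        "auc_bdi": float(np.mean(auc_bdi)),
        "auc_bdi_prs": float(np.mean(auc_both)),
        "delta": float(np.mean(auc_both) - np.mean(auc_bdi)),
    }


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
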