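"""SNP quality control, population-structure PCA, clinical KNN imputation,
and the per-SNP logistic association scan producing GWAS summary statistics.

QC drops a SNP when its missingness exceeds 5%, its minor allele frequency
falls below 1%, or its Hardy-Weinberg equilibrium test rejects at 1e-6 —
the PLINK ``--geno 0.05 --maf 0.01 --hwe 1e-6`` convention. Rules apply in
that order and a SNP is attributed to the first rule it fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger("adgcn_omics")

__all__ = [
    "QcThresholds",
    "QcReport",
    "hwe_test",
    "filter_snps",
    "genotype_pca",
    "association_scan",
    "clinical_impute_knn",
    "meta_analyze",
]


@dataclass(frozen=True)
class QcThresholds:
    max_missing_rate: float = 0.05
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6

    def __post_init__(self):
        for name in ("max_missing_rate", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class QcReport:
    n_input: int
    n_retained: int
    dropped_missing: int
    dropped_maf: int
    dropped_hwe: int
    per_snp_reason: list[str] = field(repr=False, default_factory=list)


class EmptyPanelError(ValueError):
    """All SNPs failed QC."""


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg proportions.

    Expected genotype counts come from the sample allele frequency. A
    monomorphic SNP (one allele absent) has no testable deviation: p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return float(chi2.sf(stat, df=1))


def _snp_stats(col: np.ndarray):
    obs = col[~np.isnan(col)]
    miss = 1.0 - len(obs) / len(col)
    if len(obs) == 0:
        return miss, 0.0, 1.0
    freq_alt = obs.mean() / 2.0
    maf = min(freq_alt, 1.0 - freq_alt)
    n2 = int(np.sum(obs == 2))
    n1 = int(np.sum(obs == 1))
    n0 = int(np.sum(obs == 0))
    return miss, maf, hwe_test(n0, n1, n2)


def filter_snps(genotypes, thresholds: QcThresholds = QcThresholds()):
    """Return (boolean keep-mask over SNPs, QcReport).

    Drop order per SNP: missingness, then MAF, then HWE; a SNP counts
    against the first rule it fails. Raises EmptyPanelError if nothing
    survives.
    """
    G = np.asarray(genotypes, dtype=float)
    m = G.shape[1]
    keep = np.ones(m, dtype=bool)
    reasons = []
    counts = {"missing": 0, "maf": 0, "hwe": 0}
    for j in range(m):
        miss, maf, hwe_p = _snp_stats(G[:, j])
        if miss > thresholds.max_missing_rate:
            keep[j] = False
            reasons.append("missing")
            counts["missing"] += 1
        elif maf < thresholds.min_maf:
            keep[j] = False
            reasons.append("maf")
            counts["maf"] += 1
        elif hwe_p < thresholds.hwe_alpha:
            keep[j] = False
            reasons.append("hwe")
            counts["hwe"] += 1
        else:
            reasons.append("pass")
    report = QcReport(
        n_input=m, n_retained=int(keep.sum()),
        dropped_missing=counts["missing"], dropped_maf=counts["maf"],
        dropped_hwe=counts["hwe"], per_snp_reason=reasons,
    )
    if report.n_retained == 0:
        raise EmptyPanelError("all SNPs failed QC; relax thresholds")
    logger.info("filter_snps: retained %d/%d SNPs (missing=%d maf=%d hwe=%d)",
                report.n_retained, m, *counts.values())
    return keep, report


def mean_impute(genotypes) -> np.ndarray:
    """Replace missing dosages by the per-SNP mean (column mean)."""
    G = np.asarray(genotypes, dtype=float).copy()
    col_mean = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.where(np.isnan(G))
    G[nan_r, nan_c] = col_mean[nan_c]
    return G


def genotype_pca(genotypes, n_components: int = 3) -> np.ndarray:
    """Centered PCA scores of the dosage matrix (missing mean-imputed).

    Columns are ordered by decreasing explained variance. If the matrix
    rank is below n_components, the available components are returned with
    a warning.
    """
    G = mean_impute(genotypes)
    X = G - G.mean(axis=0)
    # eigendecomposition of the SNP covariance: invariant to sample order,
    # so scores are exactly equivariant under row permutation
    C = X.T @ X
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(evals[0], 0) * 1e-9
    rank = int(np.sum(evals > tol))
    if rank < n_components:
        logger.warning("genotype_pca: requested %d components, rank is %d",
                       n_components, rank)
    k = min(n_components, rank)
    if k == 0:
        return np.zeros((X.shape[0], n_components))
    # deterministic sign: largest-magnitude loading positive
    for j in range(k):
        lead = np.argmax(np.abs(evecs[:, j]))
        if evecs[lead, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return X @ evecs[:, :k]


def association_scan(genotypes, labels, covariates=None) -> pd.DataFrame:
    """Per-SNP logistic regression of label on dosage plus covariates.

    Returns summary statistics with columns SNP A1 BETA SE P N (PLINK
    association dialect; A1 is the dosage-counted allele, 'ALT' for
    synthetic panels). SNPs whose fit fails to converge or separates are
    flagged and excluded.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(labels, dtype=float)
    n, m = G.shape
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.shape[0] != n:
            raise ValueError("covariates not row-aligned with genotypes")
    else:
        C = np.empty((n, 0))
    Gi = mean_impute(G)
    rows = []
    n_failed = 0
    base = np.column_stack([np.ones(n), C])
    for j in range(m):
        x = Gi[:, j]
        if np.std(x) == 0:
            n_failed += 1
            continue
        X = np.column_stack([x, base])
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, X).fit(disp=0, maxiter=60)
            if not res.mle_retvals.get("converged", False):
                raise RuntimeError("not converged")
            beta, se = res.params[0], res.bse[0]
            p = res.pvalues[0]
            if not (np.isfinite(beta) and np.isfinite(se) and se > 0
                    and np.isfinite(p)):
                raise RuntimeError("non-finite estimate")
        except (PerfectSeparationError, RuntimeError, np.linalg.LinAlgError,
                ValueError):
            n_failed += 1
            continue
        rows.append({"SNP": j, "A1": "ALT", "BETA": float(beta),
                     "SE": float(se), "P": float(max(p, 1e-300)), "N": n})
    if n_failed:
        logger.info("association_scan: %d/%d SNPs flagged (separation or "
                    "non-convergence) and excluded", n_failed, m)
    return pd.DataFrame(rows, columns=["SNP", "A1", "BETA", "SE", "P", "N"])


def meta_analyze(stats_list: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis of summary statistics
    sharing SNP ids and effect alleles."""
    from scipy.stats import norm
    merged = None
    for i, s in enumerate(stats_list):
        s = s.rename(columns={"BETA": f"B{i}", "SE": f"S{i}", "P": f"P{i}",
                              "N": f"N{i}"})
        merged = s if merged is None else merged.merge(s, on=["SNP", "A1"])
    k = len(stats_list)
    w = np.column_stack([1.0 / merged[f"S{i}"] ** 2 for i in range(k)])
    b = np.column_stack([merged[f"B{i}"] for i in range(k)])
    beta = (w * b).sum(axis=1) / w.sum(axis=1)
    se = np.sqrt(1.0 / w.sum(axis=1))
    z = beta / se
    p = 2 * norm.sf(np.abs(z))
    n = sum(merged[f"N{i}"] for i in range(k))
    return pd.DataFrame({"SNP": merged["SNP"], "A1": merged["A1"],
                         "BETA": beta, "SE": se,
                         "P": np.clip(p, 1e-300, 1.0), "N": n})


def clinical_impute_knn(clinical: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """KNN imputation of the clinical table.

    For each row with missing cells, the k nearest complete-case rows are
    found by Euclidean distance on the standardized numeric columns observed
    in that row; numeric gaps take the neighbor mean, categorical gaps the
    neighbor mode. A row with every cell missing is an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = clinical.copy()
    numeric_cols = [c for c in df.columns
                    if pd.api.types.is_numeric_dtype(df[c])]
    cat_cols = [c for c in df.columns if c not in numeric_cols]
    complete = df.dropna().index.to_numpy()
    if len(complete) == 0:
        raise ValueError("KNN imputation needs at least one complete row")
    num = df[numeric_cols].to_numpy(float) if numeric_cols else \
        np.zeros((len(df), 0))
    mu = np.nanmean(num, axis=0) if num.size else np.zeros(0)
    sd = np.nanstd(num, axis=0) if num.size else np.zeros(0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (num - mu) / sd if num.size else num

    for i in df.index[df.isna().any(axis=1)]:
        row_missing = df.loc[i].isna()
        if row_missing.all():
            raise ValueError(f"row {i} has all cells missing")
        obs_num = [j for j, c in enumerate(numeric_cols)
                   if not row_missing[c]]
        if obs_num:
            d = np.sqrt(((z[complete][:, obs_num] - z[i, obs_num]) ** 2)
                        .sum(axis=1))
        else:
            d = np.zeros(len(complete))
        order = np.argsort(d, kind="stable")
        neighbors = complete[order[:k]]
        for c in df.columns[row_missing]:
            vals = df.loc[neighbors, c]
            if c in numeric_cols:
                df.loc[i, c] = float(vals.astype(float).mean())
            else:
                df.loc[i, c] = vals.mode().iloc[0]
    return df
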