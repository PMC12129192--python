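"""Synthetic multi-omics cohort generation.

Real Alzheimer's staging cohorts (genotype + methylation + clinical) are
access-restricted, so every downstream stage of the pipeline is exercised on
simulated cohorts that reproduce the statistical structure the methods
assume:

* two-class labels at a configurable imbalance ratio (majority/minority);
* LD-blocked genotypes — a Gaussian copula per block with exchangeable
  latent correlation, thresholded to 0/1/2 dosages by MAF quantiles — with a
  sparse set of causal SNPs carrying log-odds effects;
* island-annotated methylation beta values in [0,1] with a small informative
  subset whose latent deviations enter the disease liability;
* 12 cognitive scores correlated with the label (the edge-weight signal for
  the patient-similarity graph), with loadings of alternating sign so that
  between-sample score-profile correlations retain the label component;
* a 4-column clinical table (age, sex, education, marital status) with
  MCAR missingness.

The label is a thresholded logistic liability: genotype effects plus
informative-probe latent deviations plus logistic noise, cut at the
empirical quantile that yields the requested class ratio exactly (within
rounding). All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("adgcn_omics")

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "Cohort",
    "generate_cohort",
    "generate_ld_blocked_genotypes",
    "inject_missing",
]

# Liability weight of one informative probe's latent deviation (the
# forward, methylation-to-risk direction).  Fixed generator constant, not a
# user knob.
PROBE_LIABILITY_WEIGHT = 1.0
# Scale of the latent deviation's footprint in the observed beta values,
# relative to probe_effect; it sets the within-class beta spread of
# informative probes.
PROBE_LATENT_BETA_SCALE = 2.0

COGNITIVE_SCORE_NAMES = [
    "CDRSB", "ADAS11", "ADAS13", "ADASQ4", "MMSE", "RAVLT_immediate",
    "RAVLT_learning", "RAVLT_forgetting", "RAVLT_perc_forgetting",
    "LDELTOTAL", "TRABSCOR", "FAQ",
]


class ConfigurationError(ValueError):
    """Raised when a CohortConfig is internally inconsistent."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    class_ratio is the target imbalance ratio (majority/minority, >= 1);
    snp_effect_sd is the standard deviation of causal log-odds effects;
    probe_effect is the beta-value displacement produced by one standard
    deviation of an informative probe's latent deviation; cognitive_signal
    is the target |Pearson r| between each cognitive score and the label.
    """

    n_samples: int = 200
    class_ratio: float = 2.0
    n_snps: int = 200
    n_ld_blocks: int = 20
    n_causal_snps: int = 5
    snp_effect_sd: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.45)
    within_block_r: float = 0.6
    n_probes: int = 200
    n_informative_probes: int = 10
    probe_effect: float = 0.15
    island_fraction: float = 0.5
    cognitive_signal: float = 0.7
    clinical_missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.class_ratio < 1:
            raise ConfigurationError("class_ratio must be >= 1")
        if self.n_causal_snps > self.n_snps:
            raise ConfigurationError("n_causal_snps exceeds n_snps")
        if self.n_informative_probes > self.n_probes:
            raise ConfigurationError("n_informative_probes exceeds n_probes")
        if self.n_ld_blocks < 1 or self.n_ld_blocks > max(self.n_snps, 1):
            raise ConfigurationError("n_ld_blocks must be in [1, n_snps]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi < 0.5")
        if not (0 <= self.within_block_r < 1):
            raise ConfigurationError("within_block_r must be in [0, 1)")
        for name in ("island_fraction", "clinical_missing_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not (0 <= self.cognitive_signal <= 1):
            raise ConfigurationError("cognitive_signal must be in [0, 1]")
        if not (0 < self.probe_effect < 1):
            raise ConfigurationError("probe_effect must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass
class CohortTruth:
    """Ground-truth bookkeeping: exactly the indices/effects used in the
    liability model."""

    causal_snp_indices: np.ndarray
    causal_snp_effects: np.ndarray
    informative_probe_indices: np.ndarray
    informative_probe_shifts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "causal_snp_indices": self.causal_snp_indices.tolist(),
            "causal_snp_effects": self.causal_snp_effects.tolist(),
            "informative_probe_indices": self.informative_probe_indices.tolist(),
            "informative_probe_shifts": self.informative_probe_shifts.tolist(),
        }


@dataclass
class Cohort:
    """Row-aligned multi-omics container (all blocks share sample order)."""

    sample_ids: list[str]
    labels: np.ndarray                 # 0 = milder group, 1 = more severe
    clinical: pd.DataFrame             # age, sex, education, marital (may have NaN)
    cognitive: np.ndarray              # n x 12
    genotypes: np.ndarray              # n x n_snps float, {0,1,2,NaN}
    snp_ids: list[str]
    ld_block_index: np.ndarray         # per-SNP block id
    methylation: np.ndarray            # n x n_probes beta in [0,1]
    probe_ids: list[str]
    probe_meta: pd.DataFrame           # island flag + synthetic p-value
    truth: CohortTruth
    config: CohortConfig

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx: Sequence[int]) -> "Cohort":
        """Row subset preserving alignment (used for discovery/target splits)."""
        idx = np.asarray(idx)
        return Cohort(
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            clinical=self.clinical.iloc[idx].reset_index(drop=True),
            cognitive=self.cognitive[idx],
            genotypes=self.genotypes[idx],
            snp_ids=self.snp_ids,
            ld_block_index=self.ld_block_index,
            methylation=self.methylation[idx],
            probe_ids=self.probe_ids,
            probe_meta=self.probe_meta,
            truth=self.truth,
            config=self.config,
        )


def generate_ld_blocked_genotypes(n_samples: int, n_snps: int, n_ld_blocks: int,
                                  maf_range: tuple[float, float],
                                  within_block_r: float = 0.6,
                                  seed: int = 0):
    """Gaussian-copula genotypes with exchangeable within-block LD.

    SNPs are partitioned into contiguous blocks. Per chromosome copy, each
    block draws a latent MVN with exchangeable correlation within_block_r
    (one shared factor per block), and an allele is called when the latent
    falls below the MAF quantile. Genotype = sum of the two allele calls, so
    within-block dosage correlations track within_block_r and cross-block
    correlations are ~0.

    Returns (genotypes n x m int array, maf vector, block_index vector).
    """
    lo, hi = maf_range
    if not (0 < lo <= hi < 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi < 0.5")
    if not (0 <= within_block_r < 1):
        raise ValueError("within_block_r must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    block_index = np.minimum(
        np.arange(n_snps) * n_ld_blocks // max(n_snps, 1), n_ld_blocks - 1
    )
    from scipy.stats import norm

    thresholds = norm.ppf(mafs)
    geno = np.zeros((n_samples, n_snps), dtype=np.int8)
    sqrt_r = np.sqrt(within_block_r)
    sqrt_1mr = np.sqrt(1.0 - within_block_r)
    for _copy in range(2):
        # one shared factor per block + idiosyncratic noise per SNP
        shared = rng.standard_normal((n_samples, n_ld_blocks))
        idio = rng.standard_normal((n_samples, n_snps))
        latent = sqrt_r * shared[:, block_index] + sqrt_1mr * idio
        geno += (latent < thresholds[None, :]).astype(np.int8)
    return geno.astype(float), mafs, block_index


def inject_missing(matrix, rate: float, seed: int = 0) -> np.ndarray:
    """Set a Bernoulli(rate) mask of cells to NaN (MCAR); reproducible."""
    if not (0 <= rate < 1):
        raise ValueError("missing rate must be in [0, 1)")
    out = np.asarray(matrix, dtype=float).copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.shape) < rate
    out[mask] = np.nan
    return out


def _cognitive_block(labels: np.ndarray, signal: float, rng) -> np.ndarray:
    """12 scores = label loading + general-performance factor + unit noise.

    Each column loads on the centered label (one magnitude, alternating
    sign — scales like CDRSB/FAQ increase with severity while MMSE/RAVLT
    decrease) and on a per-sample general factor g ~ N(0,1) that is
    independent of the diagnosis, mimicking the shared ability component of
    real cognitive batteries. Loadings are calibrated so each column's
    population r with the label equals `signal`; the general factor makes
    between-sample score-profile correlations reflect more than the class,
    as in real data.
    """
    n = len(labels)
    signs = np.array([1, -1] * 6)
    g = rng.standard_normal(n)
    base = g[:, None] * signs[None, :] + rng.standard_normal((n, 12))
    centered = labels - labels.mean()
    sd_label = centered.std()
    if signal <= 0 or sd_label == 0:
        return base
    signal = min(signal, 0.99)
    # r = a sd_label / sqrt(a^2 sd_label^2 + var(g) + var(noise))
    a = signal * np.sqrt(2.0) / (np.sqrt(1.0 - signal ** 2) * sd_label)
    return centered[:, None] * (a * signs)[None, :] + base


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full multi-omics cohort from the liability model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    geno, mafs, block_index = generate_ld_blocked_genotypes(
        n, config.n_snps, config.n_ld_blocks, config.maf_range,
        config.within_block_r, seed=int(rng.integers(2 ** 31)),
    )

    causal_idx = np.sort(rng.choice(config.n_snps, size=config.n_causal_snps,
                                    replace=False))
    causal_beta = rng.normal(0.0, config.snp_effect_sd,
                             size=config.n_causal_snps)

    info_idx = np.sort(rng.choice(config.n_probes,
                                  size=config.n_informative_probes,
                                  replace=False))
    # latent standardized deviations of the informative probes
    u = rng.standard_normal((n, config.n_informative_probes))

    liability = np.zeros(n)
    if config.n_causal_snps:
        g = geno[:, causal_idx]
        g_centered = g - 2 * mafs[causal_idx][None, :]
        liability += g_centered @ causal_beta
    if config.n_informative_probes:
        liability += PROBE_LIABILITY_WEIGHT * u.sum(axis=1)
    liability += rng.logistic(0.0, 1.0, size=n)

    # class counts from the target ratio; threshold at the empirical quantile
    n_minority = int(round(n / (1.0 + config.class_ratio)))
    n_minority = max(1, min(n_minority, n - 1))
    cut = np.partition(liability, n - n_minority - 1)[n - n_minority - 1]
    labels = (liability > cut).astype(int)
    # ties at the cut could over/under-shoot; fix up deterministically
    if labels.sum() != n_minority:
        order = np.argsort(-liability, kind="stable")
        labels = np.zeros(n, dtype=int)
        labels[order[:n_minority]] = 1

    # methylation: per-probe baseline + measurement noise; informative
    # probes additionally carry (a) the latent deviation that fed the
    # liability and (b) a disease-state shift of probe_effect — the
    # reverse-causation footprint of the disease on the epigenome
    base = rng.uniform(0.15, 0.85, size=config.n_probes)
    noise_sd = 0.03
    meth = base[None, :] + rng.normal(0.0, noise_sd, size=(n, config.n_probes))
    shifts = np.full(config.n_informative_probes, config.probe_effect)
    if config.n_informative_probes:
        dev = (labels - labels.mean())[:, None]
        meth[:, info_idx] += (config.probe_effect * dev
                              + PROBE_LATENT_BETA_SCALE
                              * config.probe_effect * u)
    meth = np.clip(meth, 0.0, 1.0)

    island = rng.random(config.n_probes) < config.island_fraction
    island[info_idx] = True  # informative probes live on CpG islands
    probe_meta = pd.DataFrame({
        "probe_id": [f"cg{i:06d}" for i in range(config.n_probes)],
        "island": island,
        "synthetic_p": rng.uniform(size=config.n_probes),
    })

    cognitive = _cognitive_block(labels, config.cognitive_signal, rng)

    clinical = pd.DataFrame({
        "age": rng.normal(73.0, 7.0, size=n).round(1),
        "sex": rng.choice(["M", "F"], size=n),
        "education": np.clip(rng.normal(16.0, 2.5, size=n).round(), 6, 24),
        "marital": rng.choice(["married", "widowed", "divorced", "never"],
                              size=n, p=[0.75, 0.12, 0.09, 0.04]),
    })
    if config.clinical_missing_rate > 0:
        miss_seed = int(rng.integers(2 ** 31))
        num_cols = ["age", "education"]
        vals = inject_missing(clinical[num_cols].to_numpy(float),
                              config.clinical_missing_rate, seed=miss_seed)
        clinical[num_cols] = vals
        cat_rng = np.random.default_rng(miss_seed + 1)
        for col in ("sex", "marital"):
            mask = cat_rng.random(n) < config.clinical_missing_rate
            clinical.loc[mask, col] = np.nan

    truth = CohortTruth(
        causal_snp_indices=causal_idx,
        causal_snp_effects=causal_beta,
        informative_probe_indices=info_idx,
        informative_probe_shifts=shifts,
    )
    return Cohort(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        labels=labels,
        clinical=clinical,
        cognitive=cognitive,
        genotypes=geno,
        snp_ids=[f"rs{i:06d}" for i in range(config.n_snps)],
        ld_block_index=block_index,
        methylation=meth,
        probe_ids=list(probe_meta["probe_id"]),
        probe_meta=probe_meta,
        truth=truth,
        config=config,
    )
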