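"""Polygenic scoring: LD estimation, clumping, P+T, LDpred-inf,
Nagelkerke R^2, scoring arithmetic, KS comparisons."""

import numpy as np
import pandas as pd
import pytest

from adgcn_omics import prs
from adgcn_omics.metrics import auc
from adgcn_omics.synthetic import CohortConfig, generate_cohort


def make_stats(snps, betas, ps, n=500):
    return pd.DataFrame({"SNP": snps, "A1": "ALT", "BETA": betas,
                         "SE": 0.1, "P": ps, "N": n})


# ---------------------------------------------------------------- LD

def test_ld_single_snp_block():
    G = np.random.default_rng(0).binomial(2, 0.3, size=(50, 1)).astype(float)
    ld = prs.ld_from_genotypes(G, [0])
    assert ld.matrices[0].shape == (1, 1)
    assert ld.matrices[0][0, 0] == pytest.approx(1.0, abs=1e-5)


def test_ld_duplicated_snps_and_constant_snp():
    rng = np.random.default_rng(1)
    g = rng.binomial(2, 0.3, size=200).astype(float)
    G = np.column_stack([g, g, np.ones(200)])
    ld = prs.ld_from_genotypes(G, [0, 0, 0])
    R = ld.matrices[0]
    assert R[0, 1] == pytest.approx(1.0, abs=1e-5)
    assert R[0, 2] == 0.0 and R[1, 2] == 0.0


def test_ld_independent_snps_near_zero():
    rng = np.random.default_rng(2)
    G = rng.binomial(2, 0.3, size=(1000, 20)).astype(float)
    ld = prs.ld_from_genotypes(G, np.zeros(20, int))
    R = ld.matrices[0].copy()
    np.fill_diagonal(R, 0.0)
    assert np.abs(R).mean() < 0.05


# ---------------------------------------------------------------- clump

def brute_force_clump(stats, R2, r2_threshold):
    """Literal restatement of the greedy rule on one block."""
    remaining = list(stats.sort_values(["P", "SNP"])["SNP"])
    index = []
    removed = set()
    while remaining:
        j = remaining.pop(0)
        if j in removed:
            continue
        index.append(j)
        for other in list(remaining):
            if R2[j, other] >= r2_threshold:
                removed.add(other)
    return sorted(index)


def test_clump_perfect_ld_keeps_smallest_p():
    rng = np.random.default_rng(3)
    g = rng.binomial(2, 0.3, size=100).astype(float)
    G = np.column_stack([g] * 4)
    ld = prs.ld_from_genotypes(G, [0] * 4)
    stats = make_stats([0, 1, 2, 3], [0.1] * 4, [0.5, 0.01, 0.2, 0.9])
    assert list(prs.clump(stats, ld)) == [1]


def test_clump_independent_keeps_all():
    rng = np.random.default_rng(4)
    G = rng.binomial(2, 0.3, size=(2000, 5)).astype(float)
    ld = prs.ld_from_genotypes(G, [0] * 5)
    stats = make_stats(range(5), [0.1] * 5, np.linspace(0.01, 0.5, 5))
    assert list(prs.clump(stats, ld, r2_threshold=0.1)) == [0, 1, 2, 3, 4]


def test_clump_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    for trial in range(10):
        n_snps = 8
        L = rng.normal(size=(n_snps, 3))
        R = np.corrcoef(L @ L.T + np.eye(n_snps))
        block = np.zeros(n_snps, int)
        ld = prs.LdBlocks(block_index=block, matrices={0: R})
        ps = rng.uniform(size=n_snps)
        stats = make_stats(range(n_snps), rng.normal(size=n_snps), ps)
        got = list(prs.clump(stats, ld, r2_threshold=0.3))
        want = brute_force_clump(stats, R ** 2, 0.3)
        assert got == want


def test_clump_empty_stats():
    ld = prs.LdBlocks(block_index=np.zeros(2, int), matrices={0: np.eye(2)})
    assert len(prs.clump(make_stats([], [], []), ld)) == 0


# ---------------------------------------------------------------- score

def test_score_arithmetic():
    G = np.array([[2.0, 1.0]])
    assert prs.score(G, [0.5, -1.0]) == pytest.approx([0.0])
    assert np.allclose(prs.score(G, [0.0, 0.0]), 0.0)
    assert np.allclose(prs.score(G, [1.0], snp_indices=[1]), G[:, 1])


def test_score_missing_snp_raises():
    with pytest.raises(KeyError, match="absent"):
        prs.score(np.zeros((3, 2)), [1.0], snp_indices=[5])


def test_score_mean_imputes_missing_dosage():
    G = np.array([[2.0], [np.nan], [0.0]])
    assert prs.score(G, [1.0]) == pytest.approx([2.0, 1.0, 0.0])


# ---------------------------------------------------------------- ldpred-inf

def test_ldpred_identity_ld_closed_form():
    m = 10
    ld = prs.LdBlocks(block_index=np.zeros(m, int), matrices={0: np.eye(m)})
    beta = np.linspace(-0.5, 0.5, m)
    stats = make_stats(range(m), beta, 0.1)
    w = prs.ldpred_inf(stats, ld, n_gwas=1000, h2=0.5)
    shrink = m / (1000 * 0.5)
    assert np.allclose(w, beta / (1 + shrink), atol=1e-12)


def test_ldpred_small_shrink_limit_is_joint_solve():
    rng = np.random.default_rng(6)
    D = np.corrcoef(rng.normal(size=(100, 6)), rowvar=False)
    ld = prs.LdBlocks(block_index=np.zeros(6, int), matrices={0: D})
    beta = rng.normal(size=6)
    stats = make_stats(range(6), beta, 0.1)
    w = prs.ldpred_inf(stats, ld, n_gwas=10 ** 9, h2=1.0)
    assert np.allclose(w, np.linalg.solve(D, beta), atol=1e-6)


def test_ldpred_blockwise_equals_dense_solve():
    """Block solution == dense whole-panel solve when the dense LD matrix is
    block-diagonal (independent oracle via scipy)."""
    from scipy.linalg import block_diag, solve
    rng = np.random.default_rng(7)
    sizes = [8, 5, 7]
    mats, block_index = [], []
    for b, s in enumerate(sizes):
        L = rng.normal(size=(s, s))
        mats.append(np.corrcoef(L @ L.T + s * np.eye(s)))
        block_index += [b] * s
    m = sum(sizes)
    ld = prs.LdBlocks(block_index=np.array(block_index),
                      matrices=dict(enumerate(mats)))
    beta = rng.normal(size=m)
    stats = make_stats(range(m), beta, 0.1)
    n_gwas, h2 = 800, 0.3
    w = prs.ldpred_inf(stats, ld, n_gwas=n_gwas, h2=h2)
    dense = block_diag(*mats) + (m / (n_gwas * h2)) * np.eye(m)
    assert np.allclose(w, solve(dense, beta), atol=1e-10)


def test_ldpred_invalid_inputs():
    ld = prs.LdBlocks(block_index=np.zeros(1, int), matrices={0: np.eye(1)})
    stats = make_stats([0], [0.1], [0.1])
    with pytest.raises(ValueError):
        prs.ldpred_inf(stats, ld, n_gwas=100, h2=0.0)
    with pytest.raises(ValueError):
        prs.ldpred_inf(stats, ld, n_gwas=0, h2=0.5)


# ---------------------------------------------------------------- nagelkerke

def test_nagelkerke_zero_when_no_improvement():
    assert prs.nagelkerke_r2(-10.0, -10.0, 50) == 0.0


def test_nagelkerke_perfect_balanced_n2():
    # ll_full = 0, ll_null = 2 ln 0.5: R2_CS = 1 - exp(2*ll_null/2) = 0.75,
    # denominator = 0.75 -> R2 = 1
    ll_null = 2 * np.log(0.5)
    assert prs.nagelkerke_r2(0.0, ll_null, 2) == pytest.approx(1.0)


def test_nagelkerke_monotone_in_full_loglik():
    ll_null = -100.0
    vals = [prs.nagelkerke_r2(ll, ll_null, 150)
            for ll in np.linspace(-100, -10, 20)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------- P+T

def test_pt_single_causal_snp_scores_track_dosage():
    rng = np.random.default_rng(8)
    g = rng.binomial(2, 0.4, size=300).astype(float)
    y = (rng.random(300) < 1 / (1 + np.exp(-3 * (g - g.mean())))).astype(int)
    ld = prs.ld_from_genotypes(g[:, None], [0])
    stats = make_stats([0], [1.5], [1e-5])
    res = prs.prs_pt(g[:, None], y, stats, ld, p_grid=[1.0])
    assert np.corrcoef(res.scores, g)[0, 1] == pytest.approx(1.0)


def test_pt_error_when_nothing_passes_grid():
    rng = np.random.default_rng(9)
    g = rng.binomial(2, 0.4, size=(100, 1)).astype(float)
    ld = prs.ld_from_genotypes(g, [0])
    stats = make_stats([0], [0.5], [0.5])
    with pytest.raises(ValueError, match="smallest p"):
        prs.prs_pt(g, np.random.default_rng(0).integers(0, 2, 100), stats,
                   ld, p_grid=[1e-8])


def test_pt_tuning_is_reproducible(small_cohort):
    from adgcn_omics import qc
    c = small_cohort
    stats = qc.association_scan(c.genotypes, c.labels)
    ld = prs.ld_from_genotypes(c.genotypes, c.ld_block_index)
    a = prs.prs_pt(c.genotypes, c.labels, stats, ld)
    b = prs.prs_pt(c.genotypes, c.labels, stats, ld)
    assert a.tuning["p_threshold"] == b.tuning["p_threshold"]
    assert np.array_equal(a.weights, b.weights)


def test_prs_affine_invariance_of_auc_and_ks():
    rng = np.random.default_rng(10)
    scores = rng.normal(size=200)
    y = (scores + rng.normal(size=200) > 0).astype(int)
    z = (scores - scores.mean()) / scores.std()
    assert auc(y, scores) == pytest.approx(auc(y, z))
    d1, _ = prs.ks_two_sample(scores[y == 0], scores[y == 1])
    d2, _ = prs.ks_two_sample(z[y == 0], z[y == 1])
    assert d1 == pytest.approx(d2)


def test_r2_nondecreasing_with_effect_size():
    """Median Nagelkerke R^2 of an oracle-weight PRS grows with the causal
    effect scale (3-point grid, 5 seeds)."""
    meds = []
    for sd in (0.2, 1.0, 2.5):
        vals = []
        for seed in range(5):
            c = generate_cohort(CohortConfig(
                n_samples=300, snp_effect_sd=sd, n_informative_probes=0,
                class_ratio=1.0, seed=seed))
            s = prs.score(c.genotypes[:, c.truth.causal_snp_indices],
                          c.truth.causal_snp_effects)
            if s.std() == 0:
                vals.append(0.0)
                continue
            _, ll = prs.fit_logistic((s - s.mean()) / s.std(), c.labels)
            vals.append(prs.nagelkerke_r2(ll, prs.null_loglik(c.labels), 300))
        meds.append(np.median(vals))
    assert meds[0] <= meds[1] + 1e-9 <= meds[2] + 0.02


# ---------------------------------------------------------------- KS / eval

def test_ks_known_values():
    assert prs.ks_two_sample([1, 2, 3], [1, 2, 3])[0] == 0.0
    assert prs.ks_two_sample([0, 1], [5, 6])[0] == 1.0
    assert prs.ks_two_sample([1, 2, 3], [1, 2, 4])[0] == pytest.approx(1 / 3)


def test_evaluate_bdi_prs_null_and_separating():
    rng = np.random.default_rng(11)
    y = np.r_[np.zeros(200, int), np.ones(200, int)]
    bdi = rng.normal(size=(400, 4))
    noise_prs = rng.normal(size=400)
    res = prs.evaluate_bdi_prs(bdi, noise_prs, y, seed=0)
    assert 0.4 <= res["auc_bdi"] <= 0.6
    assert 0.4 <= res["auc_bdi_prs"] <= 0.6
    perfect = y + rng.normal(scale=1e-3, size=400)
    res2 = prs.evaluate_bdi_prs(bdi, perfect, y, seed=0)
    assert res2["auc_bdi_prs"] == pytest.approx(1.0)


def test_informative_prs_never_hurts_auc():
    """Adding a signal-bearing PRS does not lower the median CV AUC."""
    deltas = []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        y = rng.integers(0, 2, 300)
        bdi = rng.normal(size=(300, 4))
        prs_scores = y * 1.0 + rng.normal(scale=1.0, size=300)
        res = prs.evaluate_bdi_prs(bdi, prs_scores, y, seed=seed)
        deltas.append(res["delta"])
    assert np.median(deltas) >= 0


def test_prs_stub_interfaces():
    with pytest.raises(NotImplementedError):
        prs.prs_cs()
    with pytest.raises(NotImplementedError):
        prs.lassosum()
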