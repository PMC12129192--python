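# Methods

This note documents the statistical models implemented by `adgcn_omics`,
the synthetic-data generator used to exercise them, the numerical and
design choices made where the design was genuinely open, and the
limitations of what the synthetic experiments can show.

## Study design

The framework targets pairwise disease-stage classification (milder group
coded 0, more severe group coded 1) from three feature blocks per patient:
basic demographic information (BDI: age, sex, education, marital status),
one polygenic risk score (PRS), and a small panel of methylation marker
probes. Twelve cognitive test scores are deliberately kept **out** of the
feature blocks; they enter only as prior knowledge through the
patient-similarity graph's edge weights. GWAS summary statistics come from
a separate discovery sample; in the synthetic pipeline one cohort is
generated and split in half (discovery for the association scan, target
for scoring and classification), so PRS weights are always out-of-sample.

## Genotype QC and association scan

SNPs are dropped when missingness exceeds 5%, minor allele frequency falls
below 1%, or the 1-df chi-square Hardy-Weinberg goodness-of-fit test
rejects at p < 1e-6 (the PLINK `--geno/--maf/--hwe` convention; "detection
rate below 95%" is implemented as missingness above 5%). Rules are applied
in that order and each dropped SNP is attributed to the first rule it
fails. Monomorphic SNPs are defined to have HWE p = 1 (no testable
deviation). The chi-square approximation is poor below ~30 samples; the
exact test is out of scope and the caveat applies to toy-scale inputs
only.

The association scan fits, per SNP, a logistic regression of the label on
dosage plus covariates (age, sex, education, and the top three genotype
principal components; PCA by eigendecomposition of the SNP covariance,
missing dosages mean-imputed). Non-converging or separated fits are
flagged and excluded rather than fatal. A fixed-effect inverse-variance
meta-analysis utility combines summary statistics from multiple cohorts.

## Polygenic scores

**P+T.** Greedy clumping: repeatedly claim the smallest-p unclaimed SNP as
an index SNP and discard unclaimed block-mates with r² ≥ 0.1 (ties on p
break by SNP id). Clumping is block-bounded because synthetic SNPs carry
no genomic coordinates. For each threshold in a 50-point logarithmic grid
from 5e-8 to 1, the clumped SNPs at p ≤ p_T are scored with their marginal
log-odds as weights, and p_T is chosen to maximize Nagelkerke's R² of a
label~PRS logistic fit on the same data (in-sample tuning; recorded in the
result's provenance).

**LDpred-inf.** The infinitesimal-model posterior mean per LD block B:

    w_B = (D_B + (M / (N h²)) I)⁻¹ β_B

with D the block dosage-correlation matrix (ridge 1e-6 on the diagonal for
PSD stability; constant SNPs get zero off-diagonal correlation), β the
marginal effects, M the panel size, N the discovery sample size, and h²
the assumed heritability (default 0.3). The Gibbs-sampled point-mixture
variant is a different stochastic estimator and is not provided; PRS-CS
and lassosum are published standalone tools and are only stubbed.

**Evaluation.** Nagelkerke's R² is computed from the log-likelihoods of
the package's own Newton-IRLS logistic solver (tiny ridge 1e-8 for
separable fits), avoiding cross-library likelihood conventions:
R²_CS = 1 − exp(2(ll₀ − ll₁)/n), R² = R²_CS / (1 − exp(2 ll₀ / n)),
clipped to [0,1]. PRS utility is additionally measured as the change in
stratified-5-fold logistic AUC when the PRS is added to the BDI block, and
distributional separation by the two-sample Kolmogorov-Smirnov statistic.

## Methylation marker selection

The cascade runs: KNN imputation (k nearest samples by Euclidean distance
over mutually observed probes) → per-probe Welch two-sample t test →
Benjamini-Hochberg step-up q-values, retaining q < 0.001 → CpG-island
restriction → hybrid class balancing → Fisher score
F_j = Σ_c n_c(μ_cj − μ_j)² / (Σ_c n_c σ²_cj + 1e-12), dropping the lowest
quartile (the threshold sits at the 25th percentile of the score
distribution, so the top 75% is retained — consistent with the retention
arithmetic of island panels reduced to roughly half after intersecting
with the entropy filter) → decision-stump information gain in bits
(best single threshold at midpoints of sorted unique values; "zero gain"
is then well defined and constant probes have exactly zero), retaining
IG > 0 → random-forest mean-impurity-decrease ranking (seeded, ties to the
lower feature index), top 50 → incremental SVM evaluation (stratified
5-fold G-mean/accuracy/precision/F1 per prefix size) → final top-10
markers.

Two deliberate simplifications: the differential test is a plain Welch t
test rather than an empirical-Bayes moderated statistic (self-contained,
adequate at cohort-scale n), and the entropy filter is a decision stump
rather than a binned discretization. Balancing precedes the filter and
embedded stages so that selection scores are computed on the balanced
data; the q/island prefilter runs on the original samples.

## Hybrid class balancing

Minority samples are categorized by the majority count among their m = 5
nearest neighbors (self excluded): all-majority → NOISE, at least half →
DANGER, otherwise SAFE (the borderline-SMOTE1 taxonomy; NOISE samples
never seed synthesis). A majority sample is boundary-flagged iff it
appears in the m-neighborhood of a DANGER minority sample. Balancing first
removes boundary majority samples — ranked by how many DANGER
neighborhoods contain them, seeded-random ties — up to half the
majority-minority gap, then synthesizes minority rows d + u(nn − d)
(u ~ U(0,1), nn among the k = 5 nearest minority neighbors of DANGER point
d) until IR ≤ target (default 1.0, with 5% slack checked before
synthesis). Undersampling precedes oversampling so synthesis sees the
cleaned boundary. When no DANGER samples exist (classes already separated
or fully mixed) oversampling is skipped with a warning — the degenerate
case is observable in practice when the marker panel separates classes
strongly.

## Ensemble integration baselines

All preprocessing is fit on training folds only (scalers and PCA live
inside per-fold pipelines), and all strategies can share one stratified
fold plan for controlled comparisons.

* *Concatenation*: z-scored column concatenation of the selected blocks
  into eight classifiers (KNN, logistic regression, Gaussian naive Bayes,
  SVM, random forest, decision tree, gradient boosting, MLP — the five
  core learners plus three conventional additions, all config-selectable).
* *Transformation*: per-block PCA to target dimensions 3/4/5 for the
  block ladder, clamped to block width (the width-1 PRS block passes
  through).
* *Model-based*: per block, the core learner (KNN/LR/NB/SVM/RF)
  minimizing inner-3-fold cross-validated log-loss on the training fold is
  selected; predictions are the unweighted mean of the chosen per-block
  probability vectors (soft vote), argmax ties resolving to class 0.

## The graph classifier

Nodes are patients; features are the concatenated blocks, z-scored per
column. Edges: cosine similarity strictly greater than 0.5 (cosine is
scale-free after z-scoring and makes the 0.5 cut meaningful on its (−1,1]
range), expanded with each node's k = 10 nearest Euclidean neighbors.
Edge weights: Pearson correlation of the two patients' 12 cognitive
scores, floored at 1e-3 so the graph stays nonnegatively weighted and
"high weight = strong agreement" is preserved (a (r+1)/2 rescaling was
considered and rejected for inverting that semantics); kNN-added edges are
weighted the same way. The three ablation strategies are: similarity-only
weighted (1), similarity+kNN unweighted (2), similarity+kNN weighted (3,
the full model).

Propagation uses Â = D^{−1/2}(A + I)D^{−1/2} with unit self-loops. The
network is H1 = BN(ReLU(Â X W1)) with width 8, then
H2 = BN(ReLU(H1 W2_self + meanN(H1) W2_neigh)) with width 3 — meanN the
weighted neighbor mean excluding self, zero for isolated nodes — and a
3→2 linear softmax head. Batch normalization runs over the node axis (the
only batch axis in full-graph training); batch statistics in training,
running statistics (momentum 0.9) at evaluation. Training is full-batch
transductive: all nodes propagate, only train-mask nodes contribute
cross-entropy; gradients are derived analytically (verified against
finite differences), clipped at global norm 5, and stepped with Adam.

Training defaults (epochs 500, learning rate 0.03, weight decay 5e-3 on
the weight matrices, early stop after 100 epochs without a 1e-4 loss
improvement) were chosen after observing that conventional GCN settings
(lr 0.01, decay 5e-4, clip 1.0) overfit the training mask at cohort scale
— training accuracy ~1.0 while a plain logistic baseline generalized
better by ~0.13 MCC — and that a clip norm of 1 throttles Adam on this
problem. All are config-exposed.

Cross-validation is transductive: the graph is built once over all nodes,
including test nodes. A strict variant (`strict_weights=True`) resets the
cognitive weights of edges touching test nodes to 1 per fold, so test
patients' cognitive scores never influence propagation; whether the
transductive weighting constitutes leakage is a design question the
package leaves to the caller by providing both.

## Synthetic cohort generator

The generator draws, per cohort:

* **Genotypes** — SNPs in contiguous LD blocks; per chromosome copy a
  Gaussian copula with one shared factor per block (exchangeable latent
  correlation `within_block_r`, default 0.6) thresholded at the MAF
  quantile (MAF ~ U(0.05, 0.45)). Dosage correlations within blocks track
  the latent correlation; across blocks they are ~0.
* **Liability and labels** — liability = Σ_k β_k (g_k − 2 MAF_k) +
  Σ_j γ u_ij + logistic noise, with β ~ N(0, snp_effect_sd²) on
  `n_causal_snps` SNPs (default 5, sd 1.0) and γ = 1.0 per informative
  probe's standard-normal latent deviation u. Labels threshold the
  liability at its empirical quantile, making the class ratio exact within
  rounding (the "intercept" is solved empirically rather than in
  expectation).
* **Methylation** — beta values = per-probe baseline U(0.15, 0.85) +
  N(0, 0.03) measurement noise, clipped to [0,1]. Informative probes
  (default 10, always island-annotated; island flags otherwise Bernoulli
  at `island_fraction`) additionally carry 2·probe_effect·u (the latent
  that fed the liability) plus a direct disease-state shift of
  `probe_effect` (default 0.15) between classes. The direct term models
  the disease's footprint on the epigenome; without it, a pure
  probe→liability coupling caps the marker panel's class separation at a
  ~1.6σ one-dimensional gap (the label is one bit of a noisy liability),
  far below what strong differentially methylated positions show. With
  the defaults, per-probe class separation is ~0.7–1σ (per-probe AUC
  ≈ 0.7–0.76).
* **Cognitive scores** — 12 columns = a_j(label − p̄) + b_j g_i + ε, with
  g_i ~ N(0,1) a per-sample general-performance factor independent of
  diagnosis and loadings of alternating sign (scales that rise vs fall
  with severity). |a| is calibrated so each column's population
  correlation with the label equals `cognitive_signal` (default 0.7,
  reflecting strongly separating batteries). The general factor matters:
  without it, the between-sample correlation of score profiles is a
  near-perfect same-class oracle at any per-column signal level, and every
  weighted graph trivializes.
* **Clinical table** — age N(73, 7), education N(16, 2.5) clipped to
  [6, 24], sex and marital categories, MCAR missingness at
  `clinical_missing_rate` (default 0.05; real cohort missingness rates
  are rarely published, so this is a placeholder, not an estimate).

Everything is a pure function of (config, seed); identical configurations
are byte-identical.

**Calibration.** Generator defaults were calibrated once against the
qualitative landscape reported for real cohorts — ensemble MCCs in the
0.3–0.86 band, feasible causal-SNP and marker recovery, pre-balance
imbalance ratios up to ~10 — and then frozen. Study sizes used by the
validation suite: GWAS recovery at n = 600 with 500 SNPs, marker recovery
at n = 600 with 200 probes, integration and ablation on cohorts of 500
(250 discovery / 250 target).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic allele-frequency spectra and
fine-scale LD; age/sex confounding of the omics layers; batch and
cell-composition structure in methylation; informatively missing clinical
data; probe-type intensity artifacts; and any real-data pathology of the
cosine-similarity graph. On these synthetic cohorts the similarity-
threshold graph is necessarily dense (with 15 z-scored features the
cosine noise floor is 1/√15, so a few percent of pairs exceed 0.5 by
chance), and the ε-floored cognitive weights prune its cross-class edges;
consequently the weighted similarity-only strategy performs on par with
the full model rather than collapsing, and the reported real-data pattern
in which kNN expansion contributes the bulk of the gain is not reproduced
here. The other ablation relations (full model ≥ unweighted kNN variant;
full model ≥ model-based ensemble) do hold on the default cohorts.

## Numerical conventions

* MCC with a zero denominator is 0 (logged); AUC uses midranks for ties;
  fold aggregates are unweighted means of per-fold values.
* BH q-values: step-up with a reverse cumulative minimum, capped at 1.
* Quantile masks keep ⌈q·m⌉ features, ties at the cut resolved toward the
  lower feature index; all other ties (clumping, RF ranking, soft-vote
  argmax) break deterministically as documented at the call site.
* Logistic IRLS clips the linear predictor at ±30 and falls back to
  least-squares steps on singular Hessians.
* Allele harmonization matches summary statistics to target genotypes by
  (id, effect allele); strand flips are unsupported (synthetic panels are
  strand-consistent).
* Effect allele in synthetic VCFs is the ALT/minor allele by construction.

## Known limitations

* The LDpred implementation is the infinitesimal closed form only; for
  sparse architectures (few causal SNPs) it over-shrinks relative to the
  point-mixture variant.
* In-sample p_T tuning inflates P+T's apparent R²; the package mirrors
  this standard practice and records the tuned threshold.
* The Welch test ignores the mean-variance relationship of beta values;
  at very small n a moderated test would be more powerful.
* Transductive graph construction uses test-node features and cognitive
  scores at graph-building time unless the strict mode is requested.
* Binary comparisons only; a three-class staging model is out of scope.
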