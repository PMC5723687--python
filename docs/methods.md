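# Methods

## Klemera–Doubal biologic age

The estimator assumes each biomarker is linear in a latent biologic age
BA_true with Gaussian noise. Per-biomarker OLS on chronological age (CA)
gives intercept q_j, slope k_j (units/year), residual SD s_j and age
correlation r_j. BA_E combines the biomarkers by inverse-variance weights
k_j²/s_j²; BA_EC additionally treats CA itself as one more "biomarker"
whose deviation variance is s²_BA, yielding a precision-weighted blend of
BA_E and CA. ΔAge = BA_EC − CA.

s²_BA is estimated as Var(BA_E − CA) minus the share of that spread due to
estimation noise, ((1 − r²_char)/r²_char)·(ca_max − ca_min)²/(12·m). For
the characteristic correlation we use r²_char = S/(m + S) with
S = Var(CA)·Σ_j k_j²/s_j². This choice makes the noise penalty equal the
actual sampling variance of BA_E, 1/Σ_j k_j²/s_j², when ages are roughly
uniform — i.e. the penalty removes exactly what it is meant to remove — and
reduces to the single biomarker's age correlation at m = 1. The simpler
weighted-RMS alternative sqrt(Σ w_j r_j²/Σ w_j) is available
(`fit_kd(..., r_char_method="weighted_rms")`) but understates the penalty
when the panel's age correlations are modest, which over-weights the noisy
BA_E in the blend; on synthetic data this made BA_EC track the latent truth
*worse* than CA alone, so it is not the default. If the penalized s²_BA is
non-positive, the fit falls back to Var(BA_E − CA) with a warning,
preserving the shrinkage structure.

A consequence of honest shrinkage worth stating: with inflammatory-panel
age correlations of r ≈ 0.15–0.35 (the realistic regime; pairwise biomarker
correlations of 0.06–0.27 cap how large they can jointly be), BA_E carries
~150–190 y² of estimation noise, so the calibrated blend keeps only ~25% of
the BA_E signal and SD(ΔAge) ≈ 4 y even when the generating offset SD is
7 y. An estimated ΔAge whose SD equals the generating 7 y would require an
implausibly informative panel; analyses that report ΔAge SDs comparable to
the offset itself imply estimators with little or no shrinkage.

Training and scoring on the same sample is the default (single-exam
design); `fit_kd`/`estimate_ba` are split so an external reference sample
can be used. Missing biomarkers: complete-case by default; an optional
`renormalize` mode rescores on the observed subset. A per-biomarker log
transform is available for skewed markers (off by default).

## Mixed-model association scan

Model per feature: y = β·ΔAge + Xγ + u + ε, u ~ N(0, σ²g·K),
ε ~ N(0, σ²e·I). K is the exchangeable family-block matrix built from
family ids (cov(u_i, u_j) = σ²g iff same family) or any user-supplied
symmetric PSD relatedness matrix. K is eigendecomposed once; in the rotated
basis the covariance is diagonal in λ = σ²g/σ²e, and each feature needs a
1-D REML profile over λ: a 26-point log-spaced grid (vectorized across all
features, since the design is shared) brackets the optimum, then a bounded
Brent polish refines it per feature. λ = 0 at the grid boundary reduces the
fit exactly to OLS — the identity-kinship case agrees with OLS to machine
precision.

Inference is a Wald test with a Student-t reference on the residual degrees
of freedom. At the sample sizes the method is usually reported at
(n > 2000) this is indistinguishable from the normal-z reporting of kinship
LMM packages; at desk-scale n the normal tail understates p by ~30% at the
Bonferroni threshold, which measurably inflates the familywise error in
simulation, so the t reference is the default. REML rather than ML is used
for the variance ratio; p-values are two-sided throughout. With Bonferroni
at α = 0.05/m over m features, a calibrated null scan of 1,000 features has
at least one hit with probability ≈ 1 − exp(−0.05) ≈ 5%; the test suite
checks this nominal rate (not zero hits) together with per-scan KS
uniformity.

Missing feature values are handled complete-case per feature (a per-feature
sub-eigendecomposition; the synthetic data has none). Technical covariates
are whatever columns the configuration names.

## Expression score and mortality

Score_j = Σ_i β_i·G_ij over significant features. Cox PH on the
standardized score (per-SD hazard ratios; the per-unit HR is also emitted),
Efron tie handling, robust family-clustered sandwich variance, two
adjustment tiers (age + sex; plus smoking, diabetes, hypertension
treatment, lipid treatment, prevalent CVD, prevalent cancer), follow-up
administratively censored at 10 years. A Schoenfeld-type
proportional-hazards diagnostic warns (only) on failure.

## Enrichment

Fisher's exact test per gene set against the scanned-gene universe
(two-sided by the point-probability method; the one-sided enrichment tail
is a flag away — enrichment web tools conventionally report the one-sided
tail). Enrichment ratio = observed/expected hits. BH step-up FDR across the
sets actually tested (≥ 10 universe genes by default), with the family size
m overridable. Gene symbols are matched exactly after one uppercase pass.

On the reference overlap computation (448- and 1,497-gene lists sharing 56
genes in a 17,562-gene universe) the one-sided tail gives p = 0.00239 and
the two-sided method 0.00348; published values near 0.0023 for these
margins are consistent with the one-sided convention and/or a slightly
larger background universe (~18,000 genes reproduces 0.0023 two-sided).

## Dense-module search

Node scores g = Φ⁻¹(1 − p), truncated at 0 for p > 0.5 (p = 0 capped at
1e-30); a signed z colors nodes by effect direction. Module score
Z_m = Σg_i/√k. From each of the top-25 seed genes, the single best
neighboring candidate is added iff it strictly increases Z_m (ties: higher
g, then lexicographically smaller symbol), to a fixed point. Under strict
improvement a zero-score node can never join (adding g = 0 always lowers
Z_m), so "connector" genes require at least modest association; unscored
network nodes are kept at g = 0 rather than removed so the candidate
neighborhoods are faithful to the network. Modules are merged by union and
the subnetwork is the induced subgraph. A relaxed acceptance rule
(Z' > Z_m·(1+r)) is available behind a rate parameter, default r = 0.

## Methylation integration

The EWAS reuses the expression scan's mixed model on CpG β-values. DMG
calling: N = number of tested CpGs mapped to the gene list under study,
cutoff 0.05/N; a gene is a DMG iff any of its CpGs passes; the most
significant CpG (ties: smallest p, then lexicographic id) is recorded. The
permutation null draws uniform same-size gene subsets without replacement
from the scanned-gene universe (batched Gumbel-argpartition sampling;
reproducible under the seed) and uses the add-one estimator
p = (1 + #{null ≥ obs})/(n_perm + 1), never zero; its mean is validated
against the closed-form hypergeometric expectation. Attenuation refits each
DMG's expression model with the top CpG added as a covariate; "attenuated"
is any decrease in |β| (no magnitude threshold), so a null CpG attenuates
~50% of the time — the mediated-vs-non-mediated *contrast* is the
informative quantity.

## Synthetic cohort generator

What it emulates: CA ~ Uniform(50, 85) (mean 67.5, SD 10, matching an
older-adult exam window); latent offset δ ~ N(0, 7²) years, residualized
against CA in-sample so realized corr(δ, CA) = 0 exactly; nine biomarkers
affine in BA_true = CA + δ with noise solved so population biomarker-age
correlations hit their targets (defaults 0.15–0.35 for seven markers, ~0
for two), which induces modest pairwise correlations via the shared BA
factor, plus one designated strongly-correlated pair (target r = 0.52)
wired through an extra shared factor carved out of the pair's noise budget;
infeasible targets raise an error naming the offender. Families are random
assignments of ~2.5 subjects; family structure enters expression as a
shared Gaussian intercept per family (SD 0.5), not the biomarkers.

Expression: 1,000 genes, 50 true, signs fixed at a 2:1 positive:negative
ratio, effect magnitudes 0.08·U(0.5, 1.5) expression units per year of δ,
plus sex/age/cell-count nuisance effects and unit noise. The 0.08 scale was
calibrated once by simulation so that planted genes are detectable at
Bonferroni with the desk-scale sample sizes used throughout, and then
frozen; cohort-scale studies detect per-year effects an order of magnitude
smaller because n and the feature count are both ~10× larger. Methylation:
3 CpGs per gene, β = logistic(μ + 0.8·latent); for half the true genes one
CpG's latent carries the δ signal that also feeds the gene's expression
(mediation strength 0.6), so adjusting for that CpG attenuates the
expression association by construction. Survival: exponential times with
hazard 0.012·exp(0.4·standardized true score) per year (≈10% 10-year
mortality), independent uniform dropout, administrative censoring at 10
years. Network: G(n, p) with mean degree 4 plus a planted connected
20-gene cluster of true genes (spanning tree + 30% densification). One
root seed drives named per-data-type substreams, so outputs are
bit-reproducible and adding a stage never perturbs another.

What it does not emulate — and hence what passing tests do not show about
real data: probe-level measurement, normalization artifacts, batch
structure beyond a single technical covariate, realistic LD/pedigree
kinship (exchangeable families only), cell-type composition effects beyond
two given covariates, non-Gaussian biomarker marginals, or confounding
between ΔAge and expression. Recovery results here demonstrate correctness
of the estimators under their assumed data model, not robustness to those
violations.

## Numerical choices and degenerate inputs

Residual SDs floored at 1e-12; s²_BA fallback as above. λ grid 1e-3..1e3
(26 points) with boundary handling at λ = 0; REML criterion guarded against
zero residuals. Fisher tables with a zero margin return p = 1 with a
degeneracy flag. BH ties share ranks by stable order. Constant covariate
columns are dropped (the intercept covers them); rank-deficient designs
raise an error naming a collinear column. Constant CpGs make a gene's
attenuation call indeterminate rather than failing. Empirical permutation
p-values are reported as "<1/n_perm" when no null draw reaches the observed
count. Problem sizes in the test and acceptance runs (300–2,000 subjects,
150–1,000 genes, 1e5 permutations) were chosen as the smallest at which the
calibration and recovery properties are statistically decisive.

## Known limitations

Family random effects are exchangeable within family — a full kinship
matrix is accepted but never richer than PSD; no frailty Cox model (robust
clustered variance only); no GO-DAG-aware enrichment or GSEA-style rank
statistics; no permutation significance for modules; the dense-module
search is greedy and order-deterministic, not globally optimal; the CpG
attenuation analysis conditions on one CpG per gene and is descriptive, not
a formal mediation test.
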