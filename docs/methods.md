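# Methods

This note documents the statistical models implemented in `lupinqg`, the
generative model behind its synthetic data, the numerical choices that are
not forced by the science, and what the package's tests do and do not
demonstrate.

## Synthetic populations

The generator emulates a breeding program's multi-cross population:

* **Founders.** Eight fully inbred founders in two pools (four "sweet"
  elite parents, four landrace parents). Ancestral allele frequencies are
  Beta(0.9, 0.9) draws truncated to [0.1, 0.9] so that the descendant minor
  allele frequency spectrum keeps most of its mass above the 0.05 QC
  threshold; pool-specific frequencies follow a Balding–Nichols Beta around
  the ancestral value with differentiation parameter F
  (`pool_differentiation`, default 0.2). Founders are individually distinct
  draws: the cross-of-origin structure of the descendants — the dominant
  structure signal in this type of population — comes from founder
  individuality, with pool divergence layered on top.
* **Mating design.** A 4 × 4 factorial (16 crosses); 140 lines allocated
  4–10 per cross (default 8–10). Each line descends from an independent F1
  by single-seed descent through `selfing_generations` (default 4, so
  F5-equivalent lines with expected residual heterozygosity (1/2)⁴ = 6.25%
  at loci heterozygous in the F1).
* **Recombination.** One obligate crossover plus a Poisson(1) number of
  extras per chromosome per meiosis, at uniform physical positions. This is
  the simplest model that produces intra-chromosomal LD decay; it makes no
  attempt to match a real genetic map.
* **Genome.** 25 chromosomes of 20 Mb, markers at uniform random positions
  (5,000 by default).

Distances in base pairs, trait values in the units of their field
definitions (t/ha for yield, cm for height, g for seed weight, 1–9 ordinal
for the lime-susceptibility score).

## Trait architectures

Each trait draws background effects at `n_background_loci` random markers
(default 200) from a bivariate normal across the two environments with
correlation `rg_true`; the resulting genetic-value vectors are rescaled to
the target per-environment genetic standard deviations, so the realized
genetic variance is exact and the realized genetic correlation scatters
around `rg_true` with the finite-locus sampling variance a real trait would
show. Optional major QTL add fixed per-dose effects, with an environment
mask for site-specific loci. Residual plot variance derives from the target
line-mean heritability by inverting H² = s²g/(s²g + s²e/n) at n = 3 blocks.

The default architectures are the study conditions themselves: per-trait
environment means, genetic CVs, heritabilities and cross-environment genetic
correlations of the six analysis traits (grain yield 0.48/0.36 and
r_g = 0.32; LS score 0.77/0.39 and 0.03; plant height 0.68/0.46 and 0.73;
pods per plant 0.43/0.48 and 0.33; seeds per pod 0.57/0.58 and −0.13; seed
weight 0.72/0.71 and 0.68).

The ordinal LS score is generated from a latent liability — a weighted sum
of the standardized grain-yield plot deviations (negative weight) and
independent noise — shifted to the target site mean and snapped to the odd
levels {1,3,5,7,9}. The liability weights (−0.66 high-stress, −0.40
mild-stress) were calibrated once so that the *realized line-mean
phenotypic correlation* with yield matches the target values (−0.68 and
−0.41): line-mean aggregation slightly amplifies, and 5-level
discretization slightly attenuates, the plot-level correlation, and the
calibration absorbs both.

Missingness is masked completely at random, with optionally Beta-distributed
per-marker rates (`marker_rate_concentration`, default 6 in the pipeline) to
emulate the heterogeneous coverage of GBS markers — this heterogeneity is
what makes the 0.15/0.20/0.30 missing-rate thresholds retain different
panels. What the generator does *not* emulate: genotyping error,
missingness correlated with heterozygosity or allele frequency, selection
during line development, phenology, spatial field trends. Tests passing on
these simulations therefore validate the estimators under their assumed
models, not robustness to those artifacts.

## Genotype QC

Filter cascade, in fixed order: monomorphic markers; MAF (retain ≥ 0.05 —
the boundary marker is kept, matching common tool semantics); per-marker
missing rate (grid 0.15/0.20/0.30); per-sample missing rate (< 50%);
heterozygosity excess at mean + 3 SD (samples) and mean + 2 SD (markers),
with MAF rechecked after sample removal. Because the heterozygosity cutoffs
adapt to the retained panel, that block iterates to a fixed point — the
cascade is then idempotent (a second identical call removes nothing), at
the cost of occasionally shaving slightly deeper into the het-rate tail
than a single pass would.

Imputation is iterative random-forest with genotypes as categorical
classes: missing calls start at the per-marker mode; each iteration refits,
per marker, a 100-tree classifier on that marker's 30 most-correlated
markers (exploiting local LD rather than all markers, which bounds runtime
without changing the method class) and re-predicts missing classes until
the changes stall or 10 iterations. Observed calls are never altered.

## Variance components and derived statistics

Balanced RCBD data use the closed-form two-way ANOVA (REML and
method-of-moments coincide there; the equality is a test); unbalanced data
fall back to an iterative REML fit of the same model (statsmodels MixedLM).
Negative moment estimates of s²g truncate at 0, which makes the degenerate
"no genetic variance" case representable; CVg and H² then follow their
definitions, and the cross-environment genetic correlation returns NaN with
a warning (the analogue of an inestimable table entry).

Two estimators had to be fixed where the literature the study cites was not
reproduced in its text; both are validated by parameter recovery and are
swappable:

* **Line BLUPs** as grand-mean shrinkage by H²: BLUP_i = m + H²(ȳ_i − m) —
  the standard single-trait RCBD line-mean BLUP.
* **Genetic correlation** as the cross-environment covariance of line means
  over the product of genetic SDs, clamped to [−1, 1]; unbiased because
  plot errors are independent across sites.

The combined two-site ANOVA and its cross / line-within-cross partition are
computed from balanced sums of squares directly (a formula interface with a
saturated line-within-cross-by-environment term is numerically wasteful at
140 × 16 levels); all F-tests are against the residual mean square.

## Structure

PCA keeps all components. k-means model selection uses the conventional
k-means BIC, n·ln(WSS/n) + K·ln(n), best of 50 starts per K, chosen at the
first local minimum (global minimum if none interior; ties break to lower
WSS then lower K). One deliberate choice: the clustering and BIC run on the
leading PCs that explain 50% of the variance (`n_pcs_cluster`). On the full
140-dimensional score matrix the isotropic noise floor dominates WSS and
the BIC stops at K ≈ 4 even when the 16 crosses are perfectly separable;
on the informative subspace the procedure recovers K = 16–17 with
near-perfect alignment to the crosses, and still selects K = 1 on
unstructured data.

DAPC retains at most K − 1 discriminant axes; the number of PCs fed to the
discriminant analysis is chosen by the a-score over label permutations
(default 10). When no candidate's a-score clears 0.1 — the level permutation
noise reaches at these sample sizes — retention falls back to one
component, implementing "minimal retention under overfitting risk".
Downstream models always receive the discriminant scores, never raw PCs.

## LD decay

r² is the squared Pearson correlation of dose vectors for intra-chromosomal
pairs within 100 kb. The decay summary is the smallest distance where a
fitted curve reaches half the 90th percentile of all pair r². The default
curve is a degree-2 polynomial in log10 distance fitted to equal-log-width
bin means (fitting raw pairs lets the dense long-distance tail dominate),
clipped monotone non-increasing from its peak (guarding against
edge-extrapolation artifacts); a Hill–Weir drift expectation with the
sample-size term and a free scale is available as the alternative family,
fitted by multi-start least squares. Both recover the analytic crossing of
an exponential-decay testbed within 15% (the polynomial within ~2%).

## GWAS

The scan residualizes phenotype and doses on [1, covariates]
(Frisch–Waugh), then computes per-marker Wald t-tests with
n − rank(C) − 1 degrees of freedom — numerically identical to per-marker
OLS, vectorized over markers. Effects are oriented to the minor allele.
Markers collinear with the covariates (or monomorphic) are flagged with
p = 1. Genomic inflation is the median chi-square ratio. The iterative
pseudo-QTN scan (off by default) promotes the top Bonferroni-significant
marker to a covariate each round, skipping markers in r² > 0.8 with
already-selected ones; it is a deliberately simple, auditable conditioning
scan, not a reimplementation of any published multi-locus tool.

## Genomic prediction

* **rrBLUP.** The ridge parameter λ = σ²e/σ²q is profiled by *restricted*
  maximum likelihood on the eigendecomposition of the centered marker
  kernel, after projecting out fixed effects: the unrestricted profile
  degenerates because the intercept aligns with the kernel's null
  eigenvector. Grid (33 points over log10 λ ∈ [−6, 10]) then Brent.
  Marker effects follow as q = W′c(K + λI)⁻¹(y − Xβ̂).
* **Bayesian Lasso.** Park–Casella parameterisation, single-site Gibbs
  (numba-compiled; a pure-Python fallback keeps the package functional
  without numba). Hyperpriors: scaled-inverse-χ²(df 5, mode at half the
  phenotypic variance) for σ²e, and — the one place this implementation is
  deliberately more informative than textbook — a Gamma prior on λ²
  centered at the prior-R² = 0.5 heuristic scale 2Σx′x/n with weight 0.5·p
  pseudo-observations. With a diffuse prior the sampler exhibits shrinkage
  runaway in p ≫ n polygenic settings (λ² grows without bound, effects
  collapse, the predictor's variance vanishes); the centered prior prevents
  the runaway while leaving accuracy unchanged on simulation.
* **RKHS / G-BLUP.** Gibbs sampling in the eigenbasis of the kernel
  (eigenvalues below 10⁻¹⁰ of the largest dropped), where the conditional
  of the transformed genetic values is diagonal, so each iteration is a few
  matrix-vector products. Held-out predictions use
  ĝ_new = G_new,train G_train⁻¹ ĝ_train (with 10⁻⁷ jitter).
* **Weighted G-BLUP.** Association p-values from a scan on the training
  fold only map to diagonal weights d_i ∝ −log10 p_i, rescaled to mean 1
  and floored at 10⁻³ — preserving the genomic variance scale and reducing
  exactly to VanRaden's G at uniform weights. The kernel covers all samples
  (marker data carry no phenotype leakage); a scan failure falls back
  loudly to D = I.

Cross-validation stratifies folds by cross so families appear on both sides
of every split; per repeat, held-out predictions are pooled over folds into
one Pearson correlation. The cross-environment scheme trains on 90% of one
site's lines (k-fold), scores the held-out lines against the *other* site's
observations, and averages the two directions. Default 10 folds × 10
repeats and 10,000/1,000 MCMC iterations; the test suite and acceptance
script run reduced sizes (5–10 folds, 2–5 repeats, 1,500/300 iterations,
800–2,000 markers), chosen so the full suite completes in a few minutes
while keeping Monte-Carlo error well below the tolerances being asserted.
Predictive-ability metrics reported by the acceptance script are averaged
over several independent trait draws, because the realized architecture of
a single 140-line draw has heavy tails.

## Known limitations

* The MCAR missingness profile and the absence of genotyping error make the
  imputation benchmark optimistic relative to real GBS data.
* Recombination is physical-distance-uniform; chromosome-specific LD decay
  in the tests is produced synthetically, not by map heterogeneity.
* The Bayesian Lasso's informative λ² prior trades some posterior-spread
  fidelity for stability; users wanting the textbook diffuse prior can
  lower `lambda_prior_weight` (and should watch the chain).
* Single-trait models only: no multi-trait or factor-analytic G×E models,
  no spatial adjustment, no dominance or epistasis.
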