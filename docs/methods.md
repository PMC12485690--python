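# Methods

This note documents the models implemented in `gliastate`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish.

## Synthetic atlas generator

The generator (`gliastate.atlas`) emulates the structure of a multi-dataset
single-nucleus atlas of annotated glial subclusters:

- **Cohort layout.** `n_datasets` datasets, each contributing the same
  region panel (default one cortical, one subcortical region), with
  `donors_per_group` donors per diagnostic group per dataset. Ages are
  uniform on 60–90 and sexes Bernoulli(0.5); these covariates carry no
  effect by default — they exist so the models that adjust for them can be
  exercised, and hooks in the config can give them effects.
- **Cell totals.** Per-(donor × region) total cell counts are negative
  binomial. `cluster_size_nb` defaults to (mean 300, size 4), a desk-scale
  post-QC glial yield per sample; the NB sampler itself is exposed
  (`sample_subcluster_sizes`) and is exercised in tests and in the
  acceptance script at the atlas-scale parameterization (mean 9,831,
  size 0.26) that describes subcluster totals in a ~4-million-cell atlas.
- **Composition.** Cells are multinomial across subclusters; planted
  disease effects shift a subcluster's odds by `exp(log-odds)` before
  renormalization, so the compositional GLM's estimand matches the planted
  value up to renormalization (exact for rare subclusters).
- **Expression.** Per cell, gene rates are
  softmax(base + subcluster offset + dataset batch offset + disease log-FC +
  usage × GEP loadings), scaled by a lognormal library size, with NB
  observation noise (per-gene size θ, default 2). The softmax
  renormalization makes planted log fold-changes exact on the
  relative-abundance scale under library-size variation. GEP usage per cell
  is baseline + disease shift + Gaussian noise, truncated at zero —
  the simplest non-negative usage model consistent with NMF.

Not simulated: ambient RNA, doublets, dropout curves, spatial structure,
cell-level covariate effects. Consequently, passing recovery tests shows
the estimators are correct for their stated models, not that they are
robust to those artifacts; the upstream QC that removes them is outside
this package's scope (subcluster labels are an input).

## Compositional analysis

Proportions per (donor × region) sample; logit transform with a 1e-6
boundary offset; Gaussian OLS on the logit scale (the minimal reading of a
"GLM on transformed proportions"), disease coefficient reported in log-odds
units with its Wald SE/p. Age is standardized within each comparison;
constant or collinear covariates (e.g. single-sex comparisons) are dropped
with a logged warning. BH adjustment is applied across all tests of a scan;
the correction family is configurable. Welch's t-test (Satterthwaite df)
serves the cortical-vs-subcortical region contrasts. Ages in top-coded
cohorts should be truncated to 90 before input; the generator draws within
60–90 so no truncation is needed for synthetic data.

## Empirical-Bayes multivariate shrinkage

`fit_mixture` implements the covariance-mixture model over (pattern, scale)
pairs plus an exact null. Numerical choices:

- **Scale grid**: geometric with ratio √2 from min(ŝ)/10 to 2·max|b̂|
  (variances ω = sd²), plus ω = 0.
- **EM**: because the component covariances are fixed, the feature ×
  component log-likelihood matrix is computed once; EM then only reweights
  π (monotone by construction; rel-tol 1e-8, ≤ 2000 iterations). Singular
  covariances get 1e-8·I jitter, logged.
- **Null correlation** among conditions is assumed identity (configurable
  via the SE matrix); the null-mass interpretation below depends on it.
- **Strong subset**: the R = 1 special case of the same machinery run per
  condition; features with min-condition LFSR below the threshold
  (0.05 for proportions, 1e-4 for DE z-scores) are "strong". An empty
  strong set logs a warning and the caller falls back to canonical-only
  covariances.
- **Data-driven covariances**: uncentered SVD of the strong estimates;
  rank-1 components for every PC explaining > 5% of overall variance plus
  their pooled, trace-normalized sum ("tPCA"); each refined by a zero-mean
  MVN-mixture extreme-deconvolution EM with per-feature diagonal noise
  (rel-tol 1e-6, ≤ 500 iterations), then trace-normalized and projected to
  the PSD cone if eigenvalues dip below zero numerically.
- **Identifiability of aggregated weights.** Mixture entries whose effect
  sd is far below the observation noise are statistically indistinguishable
  from the exact null, so `mixture_summary` accepts a `null_sd` floor:
  entries with sd ≤ null_sd count toward the null. Recovery tests use
  0.3–0.5 × SE (≤ 9–25% added variance); without the floor, per-component
  totals absorb arbitrary shares of the null and are not comparable.
- **Pattern assignment** is the argmax of scale-summed responsibilities;
  ties break to the lowest component index, logged. K-means over pattern
  genes uses 25 restarts per k on k = 1..10 and picks k at the
  chord-distance knee of the WSS curve (max perpendicular distance from the
  chord joining the endpoints), overridable.

## Differential expression with latent covariates

- **Gene filter**: detected in ≥ 0.5% of cells, boundary inclusive.
- **TMM**: reference = sample with upper quartile closest to the mean;
  30% / 5% double trimming of M / A values; precision-weighted mean of
  M-values; factors centered to geometric mean 1.
- **Latent components**: per-gene OLS of log₂-CPM on disease; the
  gene-centered residual matrix is SVD'd; candidate components are the
  first ⌊samples/2⌋ left singular vectors. The OLS/log₂-CPM residual
  (rather than a count-scale GLM deviance residual) keeps the SVD
  well-defined; this is an analog of the original residual-based procedure,
  not a byte-level replication.
- **Elbow and inflection**: the curve records the mean over genes of
  RSS/TSS for designs [disease, W₁..W_k]; the selected k* is the maximal
  inflection — midpoint of argmin/argmax of the chord deviations when the
  deviations change sign (sigmoid-type), else the deviation argmax (knee);
  exactly linear curves return k* = 0 with a warning. Under pure noise the
  curve is mildly convex, so a small spurious k* is expected; the test
  below remains calibrated in that regime.
- **NB GLM**: log link, offset log(library × TMM factor). The per-gene
  dispersion is method-of-moments with a df correction, estimated under the
  **disease-only** model: the latent components are fit to residual
  variance, so estimating dispersion under the full design lets their
  overfit shrink the variance estimate and inflates the Wald test
  (measured: type-I ≈ 0.07–0.09 at nominal 0.05); the reduced-model
  estimate restores calibration (≈ 0.04–0.06) at the cost of mild
  conservatism when real latent structure is present. P-values use a t
  reference with residual df rather than the normal — the plug-in
  dispersion makes the normal reference anti-conservative at pseudobulk n.
  Non-convergent genes and genes with SE > 10 (natural-log scale) are
  flagged and excluded from BH and downstream use.
- **z-scored log₂FC** within each comparison makes effects comparable
  across comparisons for the shrinkage stage.

## Consensus factorization and the signature rule

Preprocessing library-size normalizes counts (to the median library),
ranks genes by variance-to-mean ratio, keeps the top 2,000 (or all
available, warned), and scales genes by their sd without centering. The
solver is multiplicative-update Frobenius NMF (uniform random init scaled
to the data, rel-tol 1e-6, ≤ 500 iterations, objective monotone and
recorded). Consensus over seeded restarts: L2-normalize replicate spectra,
drop low-density spectra (mean distance to the K = n_replicates nearest
neighbors above the `density_quantile` of that distribution), k-means the
survivors, take cluster medians; usages are refit by NNLS and full-gene
"eigenvalues" come from OLS of all genes' normalized expression on the
usages (these can be negative, like any usage-regression score). Stability
(silhouette over clustered spectra) and reconstruction error are reported
per k; the choice of k is deliberately left to the caller, mirroring a
manual stability/error trade-off. The consensus signature intersects genes
detected in all datasets, z-scores each gene's eigenvalue within its GEP,
averages across datasets, and keeps average z > 5. A practical ceiling
follows from the z-scoring itself: with m signature genes among N, the
attainable average z is ≈ √((N−m)/m), so the z > 5 rule presupposes sparse
signatures (m/N ≲ 1/26) — which is exactly the regime of a 105-gene
signature in a ~20,000-gene transcriptome.

## Signature scoring

PCA score: TMM, log₂-CPM, subset to signature genes with nonzero counts,
drop zero-variance genes, gene-center and unit-scale (correlation-style
PCA, so no single high-expression gene dominates), PC1 by SVD. PC1 is
oriented to correlate non-negatively with mean signature expression; the
association test is orientation-invariant, as the score is inherently
directionless. Rosner/generalized-ESD outlier removal on PC1 (α = 0.05,
k_max = ⌊n/10⌋) iterates with PCA recomputation until clean, then OLS
PC1 ~ disease + covariates. GSEA: signed −log₁₀(p) ranking (p floored at
1e-300, ties broken by gene id), weighted KS running sum with exponent 1,
ES evaluated analytically at hit boundaries, seeded gene-label permutation
null (default 10,000), NES = ES / mean |same-sign null ES|, p computed
within the same-sign null with a +1 floor — the only convention under
which null p-values are approximately uniform while respecting the
1/(1+n_perm) floor.

## TF variance partitioning

Single-response variance partitioning is algebraically partial OLS, so it
is implemented as such: unique fraction = adjR²(focus + condition) −
adjR²(condition), Ezekiel adjustment, negatives clamped to 0 with the
p-value suppressed (a negative increment means the focus explains less
than a random predictor would). Significance via residual permutation of
the condition-only model (pseudo-F), exhaustive when n! ≤ n_perm. The
combined fraction conditions only on covariates; comparator TFs condition
on the full signature-TF set. The score fed in should be computed with the
focal TFs removed from the signature matrix beforehand. Note the clamping
rule can in principle leave the combined fraction below a unique fraction;
values are reported as computed and only negatives are clamped.

## Problem sizes

Simulation sizes used by the test suite and `scripts/acceptance.py`, chosen
as the smallest sizes at which each estimand is stably identified: mixture
recovery at 5,000 features × 3 conditions (calibration at 1,500–2,000);
DE at 20 samples × 600–2,000 genes with 500 balanced planted effects;
factorization at 3 datasets × ~2,000 cells × 400 genes with 30 restarts at
k = 3; scoring cohorts of 24 donors × 300 genes over 10 seeds; TF
partitioning at 40 samples with 999 permutations (720 exhaustive at n = 6).

## Known limitations

- The pseudobulk NB GLM replaces the cell-level NB mixed model used for
  the original cohort analyses; the two were reported concordant, but
  donor-level pseudobulk discards within-donor cell heterogeneity.
- The EM for π is plain (no constrained convex solver); with many
  near-degenerate mixture entries it converges slowly in the weights while
  the likelihood is effectively flat — posteriors are unaffected.
- The consensus solver is deliberately simple (MU Frobenius); it is
  pluggable, and the consensus/selection layers do not depend on it.
- BH across comparisons treats comparisons as independent; no hierarchical
  or mixed-model alternative is provided.
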