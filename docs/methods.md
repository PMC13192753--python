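# Methods

This note documents the statistical procedures implemented in `gutlink`,
the defaults they ship with, and the design decisions taken where more than
one reasonable choice existed.

## The analysis problem

The pipeline relates two feature-by-sample count tables measured on the same
tissue samples: host gene expression (RNA-seq, ~10²–10⁴ genes) and the
mucosal microbiome (16S amplicon counts aggregated to genus, ~10²
genera), collected across intestinal locations from patients who may
contribute one sample per location. Associations are sought at three
granularities — whole-matrix concordance, sparse module-to-group coupling,
and single gene-to-microbe effects — after removing known nuisance
structure (technical covariates, patient identity, contamination,
compositionality, sequencing depth).

## Synthetic cohorts (`gutlink.synthetic`)

Because raw cohorts of this design are not freely available at development
scale, the package ships a generator whose draws carry full ground truth.
Per sample *i*:

* **Genes.** Counts are gamma–Poisson (negative binomial,
  var = μ + φμ², default dispersion φ = 0.3, typical of bulk RNA-seq).
  The log-mean is a gene baseline (N(0,1)) plus sparse latent-factor
  loadings, fixed covariate effects, a region shift, and a patient random
  intercept, mapped through a per-sample softmax and scaled to a log-normal
  library size (default mean 100,000 reads).
* **Taxa.** Counts are multinomial at a log-normal depth (default mean
  20,000 reads, σ = 0.5 — depth heterogeneity makes rarefaction
  non-trivial) with logits composed the same way, plus direct
  gene→microbe terms.
* **Latent factors.** Factor scores are standard normal per sample;
  loadings outside the sparse supports are exactly zero (defaults: 2
  factors, 4% of genes and 10% of taxa per factor, loading magnitudes
  U(0.75, 1.25) with random sign). This gives clean support-recovery
  targets for sparse CCA.
* **Direct pairs.** Each of the default 10 pairs shares a standard-normal
  latent that drives one gene with unit loading and one taxon logit with
  loading ±2 (the `effect_size_direct`). Pair genes and taxa are drawn
  outside the factor supports so the two kinds of planted signal do not
  overlap. No published effect sizes exist for such associations; ±2 CLR
  units per gene-SD was chosen once as a clearly detectable but not
  degenerate effect at n ≈ 60.
* **Contaminants.** Contaminant taxa have expected abundance ∝ 1/DNA
  concentration (the signature the frequency method tests for); negative
  controls contain only contaminant signal at ~2% of the real-sample depth.
* **Tree.** A random rooted bifurcating tree over taxa, built by
  coalescent-style pairwise joins with exponential branch lengths. Any
  rooted tree with positive lengths exercises Faith's PD and UniFrac; no
  phylogenetic signal is planted in the abundances, and none is claimed.
* **Cohort layout.** Defaults: 3 regions × 30 samples from 45 patients, so
  most patients contribute two regions — the structure that makes the
  patient random intercept identifiable.

Identical configs (including seed) give bit-identical cohorts. What the
generator does **not** emulate: taxonomic label structure, phylogenetic
autocorrelation of abundances, batch effects beyond a scalar covariate,
zero-inflation beyond what the multinomial/NB sampling produces. Passing
recovery tests on these cohorts demonstrates correctness of the estimators
under the stated model, not performance on real tissue data.

## Preprocessing (`gutlink.prep`)

* Prevalence filters use `count ≥ ceil(frac · n_samples)` — "at least X%
  of samples" with integer samples. Defaults: taxa kept at ≥ 0.01% relative
  abundance in ≥ 10% of samples; genes kept at ≥ 10 counts in ≥ 33% of
  samples; after residualization the lowest 25% variance quantile of genes
  is dropped (ties at the quantile retained, deterministically).
* CLR is computed on the relative-abundance scale with a pseudocount of
  10⁻⁶ (configurable), so `clr(tss(t)) == clr(t)` exactly.
* Expression is variance-stabilized as log₂ CPM with a 0.5 prior count.
  The integration stages need a roughly variance-stable continuous matrix;
  log-CPM is the simplest transform with that property and keeps the
  package dependency-light.
* Contaminant scoring follows the frequency method: per feature, on samples
  where it is present, log₁₀ relative frequency is fitted against log₁₀ DNA
  concentration under two one-parameter models — slope fixed at −1
  (contaminant) vs slope 0 (non-contaminant) — and the residual
  sum-of-squares ratio is referred to F(m−1, m−1), lower tail. Features in
  fewer than 5 usable samples are "not evaluable" and never flagged.
  Default flagging threshold 0.1. On generator defaults (60 samples, 20
  contaminants) this flags ≥ 90% of true contaminants with ≤ 10% false
  positives (seeded test).

## Diversity (`gutlink.diversity`)

Metric computations are delegated to scikit-bio; rarefaction is an exact
without-replacement subsample via the multivariate hypergeometric
distribution, averaged over (default) 1,000 seeded iterations. Conventions:
Shannon uses natural log (uniform k-taxon sample → ln k); Simpson is
1 − Σp²; Fisher's α solves S = α ln(1 + N/α); Faith's PD includes the path
to the root (this changes values by the root-edge length, hence stated);
weighted UniFrac is the normalized variant so all of Bray–Curtis and both
UniFracs lie in [0, 1]; Aitchison distance is the Euclidean distance of
CLR vectors with the same 10⁻⁶ pseudocount. UniFrac inputs are integer
counts (both variants are invariant to per-sample scaling; relative
abundances are scaled by 10⁹ and rounded when given).

## Covariate models (`gutlink.covariates`)

Residualization fits, per feature, a REML linear mixed model with the
declared fixed covariates and a patient random intercept, and returns
**marginal** residuals (observed minus fixed-effect fit). Predicted random
effects are retained by default because patient variation is signal-like
where patients contribute a single sample per region; `conditional=True`
subtracts them. With ≤ 2–3 samples per patient the variance estimate is
fragile: singular or failed fits fall back to OLS with a logged warning,
and an all-singleton grouping short-circuits to OLS directly.
Residualization is idempotent to numerical tolerance.

Differential abundance runs the same mixed model on CLR taxa with location
as a treatment-coded fixed effect (reference region configurable), Wald
tests per non-reference level, and BH adjustment across taxa within each
contrast. On 500 null taxa with realistic patient structure the empirical
type-I error at nominal 0.05 falls in [0.03, 0.07] (seeded acceptance
test). BH q-values come from `statsmodels.multipletests`; the test suite
checks them against a brute-force step-up implementation.

## Global concordance (`gutlink.concordance`)

PCoA double-centers −½D², eigendecomposes, and keeps positive-eigenvalue
axes (negative eigenvalues are dropped with a logged magnitude share — for
Aitchison input they are numerical noise, so no Cailliez/Lingoes correction
is applied). Procrustes is symmetric: both configurations are centered and
scaled to unit total sum of squares before the SVD rotation, so
ρ = Σσ ∈ [0, 1] and the statistic is invariant to argument order. The
permutation test relabels whole rows of the second configuration and refits
per permutation (batched SVDs of the k×k cross-products), with the add-one
rule p = (#{ρ_perm ≥ ρ_obs} + 1)/(n_perm + 1); the default 99,999
permutations give a floor of 10⁻⁵. Under independence the permutation p is
uniform (KS-tested in the acceptance suite).

## Sparse CCA (`gutlink.scca`)

The rank-one penalized matrix decomposition maximizes uᵀKv for
K = X_stdᵀZ_std subject to ‖u‖₂ ≤ 1, ‖u‖₁ ≤ c₁ (and symmetrically v), by
alternating updates u ← S(Kv, δ)/‖·‖₂ with the smallest δ meeting the L1
budget. Implementation details:

* **Penalty parameterization.** c = frac · √dim, frac ∈ (0, 1], clamped
  into [1, √dim] — the L1 norm of a unit-L2 vector cannot be below 1, so
  very small fractions mean "maximally sparse" rather than infeasible.
* **Exact threshold.** The critical δ is computed in closed form rather
  than by numeric bisection: the L1/L2 ratio of S(a, δ) is non-increasing
  in δ (Cauchy–Schwarz), so the crossing support size is found by scanning
  order statistics with prefix sums and δ solves a per-support quadratic.
  This is exact, an order of magnitude faster in the LOOCV loops, and is
  validated against a long bisection on random vectors (including tied
  values) in the test suite. Boundaries inside clusters of tied values lose
  all precision to cancellation and are masked (their true ratio is never
  the first crossing).
* **Numerically constant columns** (sd below 10⁻¹⁰·(1 + |mean|)) are
  dropped before standardization; standardizing them would amplify mean
  rounding noise into spurious O(1) columns.
* Successive components deflate K by d·uvᵀ. With both fractions 1 the model
  reproduces the truncated SVD (acceptance-tested at 10⁻⁵).
* **Penalty tuning** scores each grid point by the Pearson correlation of
  LOOCV held-out variate pairs of component 1 (the held-out sample is
  standardized with the fold's parameters), ties broken toward the
  sparsest pair. Default grid {0.1, …, 1.0}²; the pipeline default is a
  reduced 5-point grid for runtime.
* **Component significance.** Each LOOCV fold refits all K components;
  folds are matched to the full-data model by extraction order and the
  (u, v) pair's joint sign is aligned by the sign of uᵀu_full. Per
  component, the n held-out pairs give a Pearson ρ tested one-sided
  (canonical pairs are positively oriented: a negative held-out correlation
  is evidence of overfitting, not association) with a t statistic at
  df = n − 2, BH-adjusted across components, flagged at adjusted p < 0.1.

  The held-out pairs are not independent — every two folds share n − 2
  training samples. Measured on independent Gaussian matrices (and
  reproduced with a from-scratch SVD-per-fold oracle), the null standard
  deviation of the LOOCV correlation is ≈ 1.9–2.0 × the independent-pairs
  value 1/√(n−1), stably across n ∈ [20, 160], dimensions and penalties.
  The t statistic is therefore divided by a fixed variance-inflation factor
  of 2.0 (slightly conservative at small n); `variance_inflation=1.0`
  recovers the naive test. With the correction the null any-component
  false-flag rate at BH level 0.1 is ≈ 0.05 (acceptance-tested ≤ 0.15),
  while a strongly coupled planted factor is flagged in every seeded run.

## Gene–microbe elastic nets (`gutlink.genemicrobe`)

Per microbe: CLR residual ~ intercept + all gene residuals, elastic-net
penalized. Backend is scikit-learn coordinate descent; the λ path is
log-spaced from λ_max = max|Xᵀy|/(n·α) down four decades (100 values), the
mixing grid defaults to {0.1, …, 1.0}, and (α, λ) minimize mean RMSE over
5-fold CV repeated 5 times (seeded `RepeatedKFold`; RMSE is taken per fold
from the CV error surface, then averaged). Final coefficients come from a
full-data refit at the selected pair and are reported on the original
predictor scale. Covariates are not in the model — inputs are expected to
be residualized upstream. Microbes whose CV fails (constant response) are
logged and skipped. Nonzero coefficients populate the pair table, sorted by
microbe then |coefficient|, with post-hoc Pearson ρ and two-sided t-test p
per pair. Under an orthonormal design the lasso solution equals
soft-thresholded univariate projections (closed-form acceptance test), and
the α → 0 limit approaches the ridge solution.

## Enrichment (`gutlink.enrichment`)

One-sided Fisher's exact / upper hypergeometric tail P(X ≥ k) per gene set,
after intersecting sets with the universe and excluding sets below 10
testable genes; BH across tested sets, flagged at adjusted p < 0.1. The
universe is the set of genes surviving the integration filters, not the
whole genome. Gene sets are user-supplied GMT files; synthetic sets are
generated in the tests.

## Pipeline (`gutlink.pipeline`, CLI `gutlink`)

Intestine-wide runs include location as a fixed effect and compute CLR
before splitting is irrelevant; per-region runs split **before** any
transformation, so filters and CLR are region-specific. The taxon order of
operations is filter → CLR → residualize. The global level computes
Aitchison distances on the (decontaminated, unfiltered-by-prevalence)
counts, PCoA, residualizes the coordinate matrix against the covariates,
and runs Procrustes against the PCoA of Euclidean distances of the
residualized expression matrix. Every run writes intermediate tables and a
`manifest.json` (config, derived per-stage seeds from one master seed,
package version, completed stages) with no timestamps, so identical configs
reproduce outputs byte for byte. Non-protein-coding gene removal is an
optional user-supplied id-list filter; the package bundles no annotation.

## Problem sizes in the test suite

The suite exercises the estimators at deliberately small scales: cohorts of
24–90 samples, 60–500 genes, 25–80 taxa; 99–9,999 permutations in pipeline
tests and the full 99,999 in the dedicated floor test; 500 null replicates
for the calibration tests; elastic-net grids of 1–3 mixing values with 1–2
CV repeats inside pipeline runs. These sizes were chosen so the estimators'
properties (recovery, calibration, determinism) are measurable with the
whole suite completing in minutes on one CPU; the library defaults remain
at the full analysis scale (99,999 permutations, 10 components, 5×5 CV).

## Known limitations

* The LOOCV variance-inflation constant (2.0) is an empirical calibration;
  a permutation-based component test would be exact but costs n_perm full
  LOOCV passes.
* Component matching across LOOCV folds by extraction order is an
  approximation; label switching between near-degenerate components
  inflates neither error rate strongly at default penalties but is not
  impossible.
* Mixed-model residualization treats fixed effects as nuisance only; no
  shrinkage of covariate effects, no batch-specific variance.
* The frequency contaminant score's F reference is a contract-level
  implementation of the published description; decontam's exact numerics
  may differ in tie and edge handling.
* PCoA negative eigenvalues are dropped, not corrected; use Aitchison (or
  any Euclidean) distances if axes must embed exactly.
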