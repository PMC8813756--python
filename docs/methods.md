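# Methods

## Problem and scope

Bulk placental DNA methylation mixes the methylomes of the constituent cell
types, so any association study on bulk beta values must separate composition
effects from genuine per-CpG effects.  This package re-implements, as a tested
pipeline on synthetic cohorts with known ground truth, the comparison of two
deconvolution strategies:

* **reference-based** — robust regression of each sample's marker-CpG betas on
  a purified-cell reference (six placental cell types: trophoblasts, stromal,
  Hofbauer, endothelial, nucleated red blood cells, syncytiotrophoblasts);
* **reference-free** — constrained low-rank factorization of the bulk beta
  matrix into latent component methylomes and per-sample proportions.

Because the original cohort data cannot be distributed, every analysis runs on
cohorts from the built-in generator, and claims are validated by parameter
recovery and oracle equivalence rather than by reproducing cohort-specific
numbers.

## Synthetic cohort model

Bulk betas follow the linear mixing model
`B[j, i] = sum_k P[i, k] * M[j, k] + eps[j, i]`, clipped to [0, 1].

* **Compositions** `P[i, :]` are Dirichlet with `alpha = mean * concentration`.
  Study presets give the mean vectors of four arms (first-trimester CVS and
  three term cohorts); the default concentration of 150 makes the per-type SDs
  land in the 0.02–0.08 range reported for those arms.  Mean entries of zero
  are floored at 1e-4 (Dirichlet parameters must be positive), which also
  reproduces the realistic pattern that rare types (Hofbauer, nRBC) are zero
  in most samples and small in a few.
* **Gestational-age trend**: `ga_effect_size` (fraction per week, default 0 in
  the library, 0.02 for CVS/BET arms in the default pipeline) moves Dirichlet
  mean mass from trophoblasts to syncytiotrophoblasts linearly in the sample's
  GA relative to the mid-range, then renormalizes; shifted means are floored
  at 1e-4 with a logged warning.  This emulates placental maturation —
  trophoblasts decline, syncytiotrophoblast mass expands — as a monotone trend
  rather than a mechanistic model.  A value of 0.02/week makes the
  GA-attributable shift across a CVS cohort comparable to the between-sample
  SD, which yields rank correlations of the same moderate size as reported
  placental GA associations.
* **Profiles**: marker CpGs are uniquely hypo- or hypermethylated in one cell
  type with a guaranteed between-type spread of at least 0.5 (targets drawn in
  [0.75, 0.95] against backgrounds in [0.03, 0.20], round-robin across types).
  Non-marker CpGs share a trimodal base landscape (mixture of Beta(0.5, 5),
  Beta(5, 5), Beta(5, 0.5)) mimicking the characteristic three-mode histogram
  of array beta values.  By default half of the non-marker CpGs additionally
  get cell-type-dependent Gaussian offsets (sd 0.2, clipped): real arrays
  carry many thousands of composition-sensitive CpGs beyond the curated
  deconvolution markers, and without them the post-marker-exclusion matrix
  would contain no composition signal at all — the premise that composition
  drives the dominant methylation variance axis would fail by construction.
  Setting `celltype_cpg_fraction=0` recovers the strict
  shared-base-profile model.
* **Noise** is i.i.d. Gaussian on the beta scale (default sd 0.02) with
  clipping; `heavy_tail_fraction` optionally inflates a subset of CpGs to sd
  0.2 to exercise the robustness of the reference-based fit.  An optional sex
  effect adds ±0.03 to a designated CpG subset (default 1% when enabled) so a
  non-composition latent factor can confound the reference-free components.
* **Phenotypes**: GA is truncated-normal within the arm's sampling window with
  the arm's reported mean/SD; sex is Bernoulli at the arm's male fraction;
  ancestry components are standard normal placeholders.

What the generator does **not** emulate: array chemistry (probe types,
detection p-values), batch structure, spatially correlated noise, and any
nonlinearity of the mixing model.  Passing tests therefore demonstrate the
correctness and calibration of the *methods*, not the cohort-level numbers of
any real study.

## Reference-based deconvolution

Per sample, betas at the marker CpGs are regressed on the reference columns
without intercept by iteratively reweighted least squares with Huber weights
(tuning constant 1.345, scale re-estimated each iteration as MAD/0.6745, at
most 50 iterations, coefficient tolerance 1e-8).  A scale collapsing to zero
(perfect fit) terminates immediately, which makes noise-free recovery exact.
Negative coefficients are truncated to zero and the remainder rescaled to sum
to one; if no coefficient is positive a uniform vector is returned with a
warning.  Missing markers are dropped per sample (no imputation); fewer than
50% present markers is an error.  `nnls` provides the non-robust limit
(non-negative least squares, same rescaling) used as the comparison oracle.
Truncate-then-rescale was chosen over refit-after-truncation as the simplest
contract consistent with proportions that sum to 100%.

## Reference-free factorization

Alternating constrained least squares of `B ~ M @ Omega'` on the most-variable
CpGs: the Omega update solves, per sample, the least-squares problem
constrained to the probability simplex *exactly* (small active-set QP with KKT
verification; a shared full-support KKT solve handles all samples at once and
only violators fall back to the per-sample active set).  The M update is exact
per-coordinate descent with clipping to [0, 1].  Because both block updates
are exact constrained minimizers, the reconstruction deviance (mean squared
error) is non-increasing across iterations and this is asserted at run time.
NNLS-then-normalize for Omega would be cheaper but does not guarantee
monotonicity, which is why the exact QP was chosen.  Initialization is
Ward-linkage hierarchical clustering of samples with cluster mean profiles as
initial components.  Defaults: top 10,000 variable CpGs, tolerance 1e-6
(relative deviance change), 100 iterations.

`select_k` fits each candidate K on bootstrap resamples of samples and scores
the out-of-bag samples' reconstruction deviance (their Omega re-solved on the
fitted components); the K with smallest mean out-of-bag deviance wins, ties
toward smaller K.  On noise-free low-rank data this recovers the true
component count; on noisy data the criterion keeps improving with K (held-out
samples can always use extra components to absorb their own noise), mirroring
the tendency of deviance-based protocols to select dataset-specific counts.
The deviance is Gaussian mean squared reconstruction error; a quasi-binomial
deviance would weight intermediate betas differently but the protocol being
emulated does not pin this down.

## Filtering, PCA, screening

* Non-variable CpGs: 10th–90th percentile beta range (linear-interpolation
  quantiles) below 0.05 in *every* supplied cohort (intersection rule).
* Deconvolution marker CpGs are removed from all downstream analyses of
  methylation variance to avoid circularity.
* PCA: CpG-wise mean-centered SVD, no scaling (betas share a scale); scores
  are right singular vectors times singular values.  PC1's sign is fixed to
  correlate non-negatively with per-sample mean beta.  Samples with PC1
  outside quartiles ± 3×IQR are excluded and PCs recomputed (quartile fences,
  not median fences — the convention had to be chosen; it is documented here
  and asserted against hand-computed values).
* Sample screen: mean Spearman correlation of each sample with all others.

## Model comparison

Six linear models predict PC1: intercept; phenotypes (GA, sex, ancestry);
reference-based proportions; those plus phenotypes; reference-free
proportions; those plus phenotypes.  Proportion blocks drop the largest-mean
column (simplex sum-to-one would otherwise make the design rank-deficient
with an intercept).  Repeated k-fold cross-validation (default 10 folds, 500
repeats; the bundled pipeline and tests run 10–100 repeats, a deliberate
desk-scale reduction) shares one fold partition per repeat across all models;
RMSE pools out-of-fold residuals; the repeat's winner is the smallest RMSE
with ties to the earlier model in the canonical order.  The 95% interval on
RMSE is the 2.5/97.5 percentile across repeats.  Singular training designs
fall back to ridge with penalty 1e-8 (logged).  The winner is refit on all
data and summarized by adjusted R² with p = non-intercept predictor count.
Per-CpG adjusted R² under the two composition designs is computed in closed
form via a shared QR decomposition; the cross-cohort set of strongly
composition-driven CpGs uses a strict threshold (R² > 0.30 in every cohort).

## Composition statistics

* Spearman association matrices use mid-ranks with the two-sided t
  approximation; Bonferroni multiplies by the number of tests in the family.
* Paired comparisons use the Wilcoxon signed-rank statistic with zero
  differences dropped, mid-ranks on ties, tie-corrected variance, and a
  normal-approximation Z whose sign is positive when the first condition
  tends to exceed the second.  Tests verify the approximation against
  exhaustive sign-flip enumeration for n ≤ 8.
* Relative effects: group effect = (mean global mid-rank − (N+1)/2)/N + 1/2,
  the probability that a random group member exceeds a random member of the
  pooled sample; the size-weighted mean is exactly 0.5.
* The global multivariate group comparison is an ANOVA-type statistic on the
  rank-transformed proportion matrix (between-group share of total rank
  variance) with a permutation null (add-one convention).  This deliberately
  replaces the F-distribution approximations of the classical nonparametric
  MANOVA criteria: a permutation null is assumption-light and its calibration
  is directly testable (type-I error within [0.03, 0.07] at alpha = 0.05 over
  500 null simulations is part of the acceptance suite).  The post-hoc subset
  search procedure is likewise replaced by per-cell-type rank tests with
  Bonferroni control.

## Pipeline

`run_benchmark` fixes the stage order: marker exclusion and joint non-variable
filtering → PCA → PC1 outlier exclusion → PC recomputation → both
deconvolutions → six-model CV → per-CpG R² and the cross-cohort high-R²
intersection → composition statistics (between-study global test on the term
arms, a synthetic longitudinal CVS→term paired design on shared individuals,
GA/sex associations per arm).  All cohorts share one CpG universe, base
profile and reference (as arrays measured against one published reference
would).  Every artifact is written as CSV/TSV/JSON and the JSON report is
byte-reproducible under fixed seeds.

The pipeline's factorization subset defaults to the top 2.5% most-variable
CpGs of the analysis matrix (at least 30).  The full-scale protocol's 10,000
CpGs are roughly 2% of a filtered EPIC array; keeping the *fraction* rather
than the absolute count preserves the protocol's geometry at desk scale —
using all CpGs of a small synthetic matrix would let the factorization
reconstruct the very axis (PC1) the model comparison predicts, a circularity
the full-scale analysis does not have.

## Problem sizes and defaults

Tests and the acceptance script run at desk scale as the package's own
standard conditions: cohorts of 30–264 samples, 400–2000 CpGs, 90–600
markers; CV at 10 folds × 100 repeats; K selection over 2–5 with 5 bootstrap
resamples; 199–999 permutations.  Defaults printed at full scale (10 × 500
CV; 10,000 factorization CpGs) remain the library defaults and are
configurable everywhere.

## Known limitations

* The robust-regression variant and constants of the published reference-based
  implementation are not specified there; the Huber/1.345 convention is used
  and exposed as configuration.
* The Dirichlet concentration conflates biological and sampling variability;
  only the marginal mean/SD structure is matched.
* The exact deviance and initialization of the published reference-free
  protocol are unspecified; mean squared error and Ward initialization are
  this package's documented choices.
* Noise-free exactness and recovery tolerances hold for the linear mixing
  model; real tissue deviates from it in ways the generator does not model.
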