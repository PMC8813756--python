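# placentadeconv

Benchmarking reference-based versus reference-free cell-type deconvolution
for placental DNA-methylation studies.

Bulk placental methylation is a mixture of cell-type methylomes: at CpG *j*
in sample *i*, the beta value is modelled as
`B[j,i] = Σ_k P[i,k] · M[j,k] + ε`, with `P[i,·]` the sample's cell
composition on the probability simplex.  Whether composition is estimated
**with** a purified-cell reference (robust regression of marker-CpG betas on
the reference, the "robust partial correlation" constrained-projection
family) or **without** one (constrained factorization `B ≈ M Ωᵀ` into K
latent methylomes and proportions) changes how well downstream models can
account for the dominant axis of methylation variance (PC1).  This package
implements both estimators, the filtering/PCA scaffolding around them, a
six-model repeated-cross-validation comparison predicting PC1, and the
nonparametric composition statistics (relative effects, permutation rank
MANOVA, paired signed-rank tests, Spearman/Bonferroni associations) — plus a
synthetic-cohort generator with known ground truth so every stage is testable
by parameter recovery.  It is aimed at methylation analysts who want a
transparent, tested re-implementation of this comparison that runs anywhere,
with no cohort downloads.

## Worked example

```python
import numpy as np
from placentadeconv import CohortConfig, generate_cohort, deconvolve_cohort

cfg = CohortConfig(n_samples=100, n_cpgs=1000, n_markers=300,
                   study_preset="CVS-ITU", seed=7)
cohort = generate_cohort(cfg)                      # betas + known truth
result = deconvolve_cohort(cohort.betas, cohort.reference, method="rpc")
print(result.proportions.head(3).round(3))
err = np.abs(result.proportions - cohort.true_proportions)
print(f"mean abs error vs truth: {err.to_numpy().mean():.4f}")
print(f"max |row sum - 1|: {np.abs(result.proportions.sum(axis=1)-1).max():.2e}")
```

prints

```
               Trophoblasts  Stromal  ...   nRBC  Syncytiotrophoblasts
CVS-ITU_s0001         0.269    0.198  ...  0.000                 0.529
CVS-ITU_s0002         0.251    0.134  ...  0.001                 0.613
CVS-ITU_s0003         0.272    0.142  ...  0.004                 0.579
mean abs error vs truth: 0.0021
max |row sum - 1|: 2.22e-16
```

Each row is one sample's estimated composition (first-trimester CVS preset:
syncytiotrophoblasts around 0.57, trophoblasts around 0.26).  Rows sum to 1
exactly, and with beta-scale noise of 0.02 the robust fit recovers the true
composition to about two parts in a thousand per entry.

The full analysis graph — marker exclusion, non-variable CpG filtering, PCA
with outlier removal, both deconvolutions, the six-model CV comparison,
per-CpG variance decomposition and the composition statistics — runs with

```python
from placentadeconv import default_pipeline_config, run_benchmark
report = run_benchmark(default_pipeline_config(seed=0), outdir="benchmark_out")
```

or from the shell via `placentadeconv run-benchmark --seed 0 --out DIR`.
Sub-stages are available as `placentadeconv simulate | deconvolve | reffree |
filter | pca | compare-models | composition-stats` on TSV/CSV files.

See `docs/methods.md` for the model, the estimators' numerical details, the
generator's assumptions, and known limitations.

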