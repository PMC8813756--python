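"""End-to-end benchmark pipeline and file I/O.

Orchestrates the full comparison on one or more cohorts: exclusion of
deconvolution marker CpGs and non-variable CpGs, methylation PCA with
PC1-outlier removal and PC recomputation, reference-based and reference-free
deconvolution, the six-model repeated cross-validation comparison, per-CpG
variance decomposition with the cross-cohort high-R² intersection, and the
composition statistics (between-study global rank test, paired first-trimester
vs term comparison, gestational-age/sex associations).  Every stage writes its
artifact to disk and logs its exclusion counts; the whole run is deterministic
given the configured seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition, filtering, model_selection, reference_based, reference_free
from .synthetic import (
    CohortConfig,
    ReferenceMatrix,
    SyntheticCohort,
    generate_cohort,
    make_base_profile,
    make_reference_profiles,
    sample_phenotypes,
    sample_proportions,
    synthesize_betas,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_beta_matrix(path) -> pd.DataFrame:
    """Read a CpG x sample beta matrix (TSV or CSV) with strict validation."""
    df = _read_table(path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate CpG id {dup!r} in {path}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    vals = df.to_numpy()
    bad = ~((vals >= 0) & (vals <= 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value {vals[i, j]!r} outside [0, 1] at CpG {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {path}"
        )
    return df.astype(float)


def load_reference(path) -> ReferenceMatrix:
    """Read a marker CpG x cell type reference matrix."""
    df = _read_table(path)
    return ReferenceMatrix.from_frame(df.astype(float))


def load_phenotypes(path) -> pd.DataFrame:
    df = _read_table(path)
    if df.index.has_duplicates or df.index.isna().any():
        raise ValueError(f"sample ids in {path} must be unique and non-missing")
    return df


def load_proportions(path) -> pd.DataFrame:
    df = _read_table(path).astype(float)
    if (df.to_numpy() < -1e-9).any():
        raise ValueError(f"negative proportion in {path}")
    return df


def write_report(report: dict, path) -> None:
    """Write a machine-readable JSON report (sorted keys: byte-reproducible)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    cohorts: list = field(default_factory=list)  # CohortConfig per emulated dataset
    filter_threshold: float = 0.05
    cv_folds: int = 10
    cv_repeats: int = 100
    k_mode: str | int = "auto"  # "auto" (bootstrap selection) or a fixed K
    k_range: tuple = (2, 6)
    n_boot: int = 3
    # None: use the top 2.5% most-variable CpGs of the analysis matrix (at
    # least 30), keeping the factorization subset at the same fraction of the
    # array as the full-scale protocol's absolute 10k rather than its size
    n_top_variable_cpgs: int | None = None
    alpha: float = 0.01
    n_permutations: int = 1000
    n_paired: int = 85
    seed: int = 0
    outdir: str = "benchmark_out"

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("pipeline needs at least one cohort")
        self.cohorts = [
            c if isinstance(c, CohortConfig) else CohortConfig(**c) for c in self.cohorts
        ]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for c in raw.get("cohorts", []):
            for key in ("ga_range", "cell_types", "custom_mean"):
                if key in c and c[key] is not None:
                    c[key] = tuple(c[key])
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


def default_pipeline_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Desk-scale default: the four study arms at n=150, 2000 CpGs each."""
    # GA trend strong where trophoblast mass allows it (CVS, BET), weak in the
    # term arms whose trophoblast mean is already near zero
    ga_effects = {"CVS-ITU": 0.02, "term-ITU": 0.002, "term-PREDO": 0.002, "term-BET": 0.02}
    cohorts = [
        CohortConfig(n_samples=150, study_preset=name, ga_effect_size=ga_effects[name],
                     seed=seed + 11 * (i + 1))
        for i, name in enumerate(["CVS-ITU", "term-ITU", "term-PREDO", "term-BET"])
    ]
    kw = dict(cohorts=cohorts, seed=seed)
    kw.update(overrides)
    return PipelineConfig(**kw)


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------

def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # tag failures with the stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def generate_paired_design(config: PipelineConfig, reference: ReferenceMatrix,
                           base_profile: pd.Series) -> tuple:
    """Synthetic longitudinal pairs: the same individuals at CVS and at term.

    Each individual gets a first-trimester draw (CVS composition preset) and a
    term draw (term composition preset) under shared sample ids, emulating a
    within-individual repeated-sampling design.
    """
    seed = config.seed + 9001
    cvs_cfg = CohortConfig(n_samples=config.n_paired, study_preset="CVS-ITU",
                           n_cpgs=len(base_profile), n_markers=reference.n_markers, seed=seed)
    term_cfg = dataclasses.replace(cvs_cfg, study_preset="term-ITU", seed=seed + 1)
    ph = sample_phenotypes(cvs_cfg, seed)
    ids = [f"paired_s{i:04d}" for i in range(1, config.n_paired + 1)]
    ph.index = pd.Index(ids, name="sample_id")
    p_cvs = sample_proportions(cvs_cfg, ph, seed + 2)
    p_term = sample_proportions(term_cfg, ph, seed + 3)
    b_cvs = synthesize_betas(reference, base_profile, p_cvs, cvs_cfg.noise_sd, seed=seed + 4)
    b_term = synthesize_betas(reference, base_profile, p_term, term_cfg.noise_sd, seed=seed + 5)
    return b_cvs, b_term, p_cvs, p_term


@_stage("run_benchmark")
def run_benchmark(config: PipelineConfig, outdir=None) -> dict:
    """Run the full benchmark; returns (and writes) the report dictionary."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # shared CpG universe and reference across cohorts
    first = config.cohorts[0]
    reference = make_reference_profiles(
        first.n_cpgs, first.n_markers, first.cell_types, config.seed + 101
    )
    base_profile = make_base_profile(first.n_cpgs, config.seed + 102)

    cohorts: dict[str, SyntheticCohort] = {}
    for cfg in config.cohorts:
        if cfg.n_cpgs != first.n_cpgs:
            raise ValueError("all cohorts must share n_cpgs (shared CpG universe)")
        cohort = generate_cohort(cfg, reference=reference, base_profile=base_profile)
        name = cfg.study_preset if cfg.study_preset != "custom" else f"custom{len(cohorts)}"
        cohorts[name] = cohort
        cohort.to_files(outdir / name)

    report: dict = {"config_seed": config.seed, "cohorts": {}}

    # marker exclusion + joint non-variable filter (intersection rule)
    no_marker = {n: filtering.exclude_reference_cpgs(c.betas, c.marker_ids)
                 for n, c in cohorts.items()}
    filt = filtering.nonvariable_cpgs(list(no_marker.values()), config.filter_threshold)
    report["n_nonvariable_cpgs"] = len(filt.nonvariable_ids)

    per_cohort_r2: dict[str, pd.DataFrame] = {}
    proportions_rb: dict[str, pd.DataFrame] = {}
    for cohort_i, (name, cohort) in enumerate(cohorts.items()):
        cdir = outdir / name
        entry: dict = {}
        analysis = no_marker[name].drop(index=list(filt.nonvariable_ids), errors="ignore")
        entry["n_cpgs_analysed"] = int(analysis.shape[0])
        ntop = (config.n_top_variable_cpgs if config.n_top_variable_cpgs is not None
                else max(30, round(0.025 * analysis.shape[0])))

        # PCA -> outlier exclusion -> recompute
        pcs = filtering.first_pcs(analysis, n_components=2)
        outliers = filtering.pc1_outliers(pcs.pc1)
        entry["n_pc1_outliers"] = len(outliers)
        if outliers:
            analysis = analysis.drop(columns=list(outliers))
            pcs = filtering.first_pcs(analysis, n_components=2)
        screen = filtering.sample_correlation_screen(analysis)
        entry["pc1_variance_explained"] = float(pcs.variance_explained[0])
        pcs.scores.to_csv(cdir / "pc_scores.csv", index_label="sample_id")
        screen.to_csv(cdir / "sample_correlation.csv", index_label="sample_id")

        kept = list(analysis.columns)
        betas_kept = cohort.betas[kept]
        phenos = cohort.phenotypes.loc[kept]

        # deconvolutions
        rb = reference_based.deconvolve_cohort(betas_kept, reference, method="rpc")
        rb.proportions.to_csv(cdir / "proportions_rpc.csv", index_label="sample_id")
        proportions_rb[name] = rb.proportions
        truth = cohort.true_proportions.loc[kept]
        entry["rpc_mean_abs_error_vs_truth"] = float(
            np.mean(np.abs(rb.proportions.to_numpy() - truth.to_numpy()))
        )

        if config.k_mode == "auto":
            K, ktable = reference_free.select_k(
                analysis, config.k_range, n_boot=config.n_boot,
                seed=config.seed + 300 + cohort_i,
                n_top_variable_cpgs=ntop,
            )
            ktable.to_csv(cdir / "k_selection.csv", index=False)
        else:
            K = int(config.k_mode)
        rf = reference_free.reffree_factorize(
            analysis, K, n_top_variable_cpgs=ntop, seed=config.seed + 400,
        )
        rf.Omega.to_csv(cdir / "omega.csv", index_label="sample_id")
        rf.M.to_csv(cdir / "latent_methylomes.tsv", sep="\t", index_label="cpg_id")
        entry["reffree_k"] = int(K)
        entry["reffree_deviance"] = rf.deviance

        # six-model CV on PC1
        specs = model_selection.default_model_specs()
        designs = {
            s.name: model_selection.build_model_matrix(
                s, rb.proportions, rf.Omega, phenos, samples=pcs.scores.index
            )
            for s in specs
        }
        cv = model_selection.repeated_cv(
            pcs.pc1, designs, folds=config.cv_folds, repeats=config.cv_repeats,
            seed=config.seed + 500,
        )
        entry["cv"] = {
            "winner": cv.winner,
            "winner_adjusted_r2": cv.winner_adjusted_r2,
            "wins": {k: int(v) for k, v in cv.wins.items()},
            "win_proportions": {k: float(v) for k, v in cv.win_proportions.items()},
            "mean_rmse": {k: float(v) for k, v in cv.mean_rmse.items()},
            "ci_rmse": {k: [float(cv.ci_rmse.loc[0.025, k]), float(cv.ci_rmse.loc[0.975, k])]
                        for k in cv.mean_rmse.index},
        }
        write_report(entry["cv"], cdir / "cvresult.json")

        # per-CpG variance decomposition
        r2 = model_selection.per_cpg_r2(
            analysis, designs["ref_based"], designs["ref_free"]
        )
        r2.to_csv(cdir / "per_cpg_r2.csv", index_label="cpg_id")
        per_cohort_r2[name] = r2
        entry["per_cpg_r2_mean"] = {c: float(r2[c].mean()) for c in r2.columns}
        entry["per_cpg_r2_sd"] = {c: float(r2[c].std()) for c in r2.columns}

        # GA / sex associations
        assoc = composition.ga_sex_associations(rb.proportions, phenos, alpha=config.alpha)
        assoc.table.to_csv(cdir / "ga_sex_associations.csv")
        entry["ga_sex"] = {
            ct: {"ga_rho": float(row["ga_rho"]),
                 "ga_p_bonferroni": float(row["ga_p_bonferroni"]),
                 "sex_p_bonferroni": float(row["sex_p_bonferroni"])}
            for ct, row in assoc.table.iterrows()
        }
        report["cohorts"][name] = entry

    # cross-cohort: high-R2 intersection
    for which in ("ref_based", "ref_free"):
        inter = model_selection.high_r2_intersection(
            [r2[which] for r2 in per_cohort_r2.values()], threshold=0.30
        )
        report[f"n_high_r2_cpgs_{which}"] = len(inter)

    # cross-cohort: global rank comparison of term studies
    term = {n: p for n, p in proportions_rb.items() if not n.startswith("CVS")}
    if len(term) >= 2 and all(len(p) >= 3 for p in term.values()):
        stacked = pd.concat(term.values())
        labels = np.concatenate([[n] * len(p) for n, p in term.items()])
        stacked.index = pd.Index(
            [f"{l}_{i}" for i, l in enumerate(labels)], name="sample_id"
        )
        g = composition.global_rank_manova(
            stacked, labels, n_permutations=config.n_permutations, seed=config.seed + 600
        )
        report["term_group_comparison"] = {
            "anova_type_statistic": g.anova_type_statistic,
            "p_permutation": g.p_permutation,
            "relative_effects": {
                str(grp): {ct: float(v) for ct, v in row.items()}
                for grp, row in g.relative_effects.iterrows()
            },
        }

    # paired CVS -> term design on the same synthetic individuals
    if config.n_paired >= 6:
        b_cvs, b_term, _, _ = generate_paired_design(config, reference, base_profile)
        rb_cvs = reference_based.deconvolve_cohort(b_cvs, reference, method="rpc")
        rb_term = reference_based.deconvolve_cohort(b_term, reference, method="rpc")
        paired = composition.paired_celltype_tests(
            rb_cvs.proportions, rb_term.proportions, alpha=config.alpha
        )
        paired.table.to_csv(outdir / "paired_cvs_term.csv")
        report["paired_cvs_term"] = {
            ct: {"median_difference_pct": float(row["median_difference_pct"]),
                 "Z": float(row["Z"]),
                 "p_bonferroni": float(row["p_bonferroni"])}
            for ct, row in paired.table.iterrows()
        }

    write_report(report, outdir / "report.json")
    logger.info("run_benchmark: report written to %s", outdir / "report.json")
    return report
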