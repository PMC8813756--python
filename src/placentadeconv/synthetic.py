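"""Synthetic placental methylation cohorts with known cell-type composition.

Bulk placental DNA methylation is modelled as a convex mixture of cell-type
methylomes: for CpG j and sample i, ``beta[j, i] = sum_k p[i, k] * profile[j, k]``
plus measurement noise, clipped to the unit interval.  Six placental cell types
are emulated (trophoblasts, stromal, Hofbauer, endothelial, nucleated red blood
cells, syncytiotrophoblasts) with study presets matching the mean compositions
reported for first-trimester chorionic villus samples (CVS) and three term
cohorts.  Each cohort carries its ground-truth proportion matrix so that
deconvolution can be scored by parameter recovery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical order of the six placental cell types
PLACENTA_CELL_TYPES = (
    "Trophoblasts",
    "Stromal",
    "Hofbauer",
    "Endothelial",
    "nRBC",
    "Syncytiotrophoblasts",
)

#: floor applied to Dirichlet mean entries so every concentration is positive
MEAN_FLOOR = 1e-4


def _normalized(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / v.sum()


@dataclass(frozen=True)
class StudyPreset:
    """Mean cell composition and gestational-age distribution of one study arm."""

    name: str
    mean_composition: tuple  # per PLACENTA_CELL_TYPES, sums to 1 after renorm
    n_samples: int
    ga_mean: float  # weeks, fetal-ultrasound scale
    ga_sd: float
    ga_range: tuple
    male_fraction: float = 0.51


# Mean (SD) compositions of the four study arms; zero-mean types are floored
# before Dirichlet sampling so occasional small positive fractions occur, as in
# real cohorts where only a handful of samples show Hofbauer/nRBC signal.
STUDY_PRESETS = {
    "CVS-ITU": StudyPreset(
        "CVS-ITU", (0.26, 0.17, 0.00, 0.00, 0.00, 0.57), 264, 12.79, 0.82, (10.0, 15.0), 0.53
    ),
    "term-ITU": StudyPreset(
        "term-ITU", (0.01, 0.01, 0.00, 0.01, 0.04, 0.93), 470, 39.99, 1.55, (36.0, 43.0), 0.51
    ),
    "term-PREDO": StudyPreset(
        "term-PREDO", (0.04, 0.04, 0.00, 0.08, 0.00, 0.83), 139, 39.89, 1.43, (36.0, 43.0), 0.48
    ),
    "term-BET": StudyPreset(
        "term-BET", (0.13, 0.11, 0.00, 0.11, 0.00, 0.66), 137, 38.16, 1.95, (32.0, 42.0), 0.51
    ),
}


@dataclass
class ReferenceMatrix:
    """Marker CpG x cell type matrix of expected beta values for purified cells."""

    marker_ids: list
    cell_types: list
    values: np.ndarray  # (n_markers, K), entries in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids in reference")
        if self.values.shape != (len(self.marker_ids), len(self.cell_types)):
            raise ValueError("reference shape does not match id lists")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("reference beta values outside [0, 1]")
        K = len(self.cell_types)
        for a in range(K):
            for b in range(a + 1, K):
                if np.allclose(self.values[:, a], self.values[:, b]):
                    raise ValueError(
                        f"cell types {self.cell_types[a]!r} and {self.cell_types[b]!r} "
                        "have identical profiles"
                    )

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.marker_ids, columns=self.cell_types)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``ga_effect_size`` is the per-week shift of the mean trophoblast fraction
    (moved into syncytiotrophoblasts), emulating placental maturation where
    trophoblasts decline and syncytiotrophoblasts expand with gestation.
    """

    n_samples: int = 150
    n_cpgs: int = 2000
    n_markers: int = 600
    study_preset: str = "CVS-ITU"
    cell_types: tuple = PLACENTA_CELL_TYPES
    custom_mean: tuple | None = None  # required when study_preset == "custom"
    dirichlet_concentration: float = 150.0
    noise_sd: float = 0.02
    ga_range: tuple | None = None  # defaults to the preset's range
    ga_effect_size: float = 0.0  # fraction per week
    sex_effect_cpg_fraction: float = 0.0
    sex_effect_size: float = 0.03
    celltype_cpg_fraction: float = 0.5  # non-marker CpGs with mild cell-type signal
    celltype_effect_sd: float = 0.2
    heavy_tail_fraction: float = 0.0  # fraction of CpGs with inflated noise
    heavy_tail_sd: float = 0.2
    n_ancestry_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers > self.n_cpgs:
            raise ValueError("n_markers must be <= n_cpgs")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.study_preset != "custom" and self.study_preset not in STUDY_PRESETS:
            raise ValueError(f"unknown study preset {self.study_preset!r}")
        if self.study_preset == "custom" and self.custom_mean is None:
            raise ValueError("custom preset requires custom_mean")
        if self.ga_range is not None and not self.ga_range[0] < self.ga_range[1]:
            raise ValueError("ga_range lower bound must be below upper bound")

    @property
    def mean_composition(self) -> np.ndarray:
        if self.study_preset == "custom":
            m = np.asarray(self.custom_mean, dtype=float)
            if len(m) != len(self.cell_types):
                raise ValueError("custom_mean length must match cell_types")
            if not np.isclose(m.sum(), 1.0, atol=0.02):
                raise ValueError("custom_mean must sum to 1")
        else:
            m = np.asarray(STUDY_PRESETS[self.study_preset].mean_composition, dtype=float)
        return _normalized(np.maximum(m, MEAN_FLOOR))

    @property
    def effective_ga_range(self) -> tuple:
        if self.ga_range is not None:
            return self.ga_range
        if self.study_preset == "custom":
            return (10.0, 15.0)
        return STUDY_PRESETS[self.study_preset].ga_range


@dataclass
class SyntheticCohort:
    """A generated cohort bundling betas, ground truth and phenotypes."""

    betas: pd.DataFrame  # CpG x sample
    true_proportions: pd.DataFrame  # sample x cell type, rows on the simplex
    phenotypes: pd.DataFrame  # sample-indexed covariates
    reference: ReferenceMatrix
    marker_ids: list
    config: CohortConfig

    def __post_init__(self) -> None:
        v = self.betas.to_numpy()
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("beta values outside [0, 1]")
        rs = self.true_proportions.to_numpy().sum(axis=1)
        if np.any(np.abs(rs - 1.0) > 1e-12):
            raise ValueError("true proportion rows must sum to 1")
        if list(self.betas.columns) != list(self.phenotypes.index):
            raise ValueError("phenotype rows must align with beta columns")

    def to_files(self, outdir) -> None:
        """Write the TSV/CSV fixture set used by the command-line stages."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.betas.to_csv(outdir / "betas.tsv", sep="\t", index_label="cpg_id")
        self.reference.to_frame().to_csv(outdir / "reference.tsv", sep="\t", index_label="cpg_id")
        self.phenotypes.to_csv(outdir / "phenotypes.csv", index_label="sample_id")
        self.true_proportions.to_csv(outdir / "true_proportions.csv", index_label="sample_id")


def cpg_ids(n_cpgs: int) -> list:
    return [f"cg{i:08d}" for i in range(1, n_cpgs + 1)]


def make_base_profile(n_cpgs: int, seed) -> pd.Series:
    """Trimodal beta-value landscape shared by all cell types at non-marker CpGs.

    Mixture of Beta(0.5, 5) (unmethylated), Beta(5, 5) (intermediate) and
    Beta(5, 0.5) (methylated) components, mimicking the characteristic
    three-mode histogram of array beta values.
    """
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n_cpgs, p=[0.4, 0.2, 0.4])
    ab = np.array([[0.5, 5.0], [5.0, 5.0], [5.0, 0.5]])
    vals = rng.beta(ab[comp, 0], ab[comp, 1])
    return pd.Series(np.clip(vals, 0.0, 1.0), index=cpg_ids(n_cpgs), name="base")


def make_reference_profiles(n_cpgs: int, n_markers: int, cell_types, seed) -> ReferenceMatrix:
    """Generate cell-type-distinct beta profiles at a random marker CpG subset.

    Markers are split round-robin across cell types; each marker is uniquely
    hypo- or hypermethylated in its target type with a between-type spread of
    at least 0.5, the property reference-based deconvolution relies on.
    """
    cell_types = list(cell_types)
    K = len(cell_types)
    if K == 0:
        raise ValueError("cell_types must be non-empty")
    if K >= 2 and n_markers < 10 * K:
        raise ValueError(f"invalid design: need n_markers >= 10*K ({10 * K}), got {n_markers}")
    if n_markers > n_cpgs:
        raise ValueError("n_markers must be <= n_cpgs")
    rng = np.random.default_rng(seed)
    ids = cpg_ids(n_cpgs)
    marker_idx = np.sort(rng.choice(n_cpgs, size=n_markers, replace=False))
    marker_ids = [ids[i] for i in marker_idx]

    values = np.empty((n_markers, K))
    if K == 1:
        # degenerate single-type reference: markers follow the base landscape
        values[:, 0] = np.clip(rng.beta(2, 2, size=n_markers), 0.0, 1.0)
        return ReferenceMatrix(marker_ids, cell_types, values)

    target = np.arange(n_markers) % K
    hyper = (np.arange(n_markers) // K) % 2 == 0
    low = rng.uniform(0.03, 0.20, size=(n_markers, K))
    high = rng.uniform(0.75, 0.95, size=(n_markers, K))
    # hypermethylated marker: target high, others low; hypomethylated: reverse
    values = np.where(hyper[:, None], low, high)
    values[np.arange(n_markers), target] = np.where(
        hyper, high[np.arange(n_markers), target], low[np.arange(n_markers), target]
    )
    return ReferenceMatrix(marker_ids, cell_types, np.clip(values, 0.0, 1.0))


def sample_phenotypes(config: CohortConfig, seed) -> pd.DataFrame:
    """Draw gestational age (truncated normal), sex and ancestry components."""
    rng = np.random.default_rng(seed)
    n = config.n_samples
    lo, hi = config.effective_ga_range
    if config.study_preset != "custom":
        preset = STUDY_PRESETS[config.study_preset]
        mu, sd, male_frac, label = preset.ga_mean, preset.ga_sd, preset.male_fraction, preset.name
    else:
        mu, sd, male_frac, label = (lo + hi) / 2.0, (hi - lo) / 6.0, 0.5, "custom"
    a, b = (lo - mu) / sd, (hi - mu) / sd
    ga = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    sex = (rng.random(n) < male_frac).astype(int)  # 1 = male
    anc = rng.standard_normal((n, config.n_ancestry_components))
    idx = [f"{label}_s{i:04d}" for i in range(1, n + 1)]
    df = pd.DataFrame({"gestational_age": ga, "sex": sex}, index=idx)
    for j in range(config.n_ancestry_components):
        df[f"ancestry_pc{j + 1}"] = anc[:, j]
    df["study"] = label
    df.index.name = "sample_id"
    return df


def sample_proportions(config: CohortConfig, phenotypes: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Draw per-sample cell-type fractions from a gestational-age-shifted Dirichlet.

    The Dirichlet mean is the preset composition with ``ga_effect_size`` per week
    (relative to the mid-range gestational age) moved from trophoblasts into
    syncytiotrophoblasts; alpha = mean x concentration.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mean = config.mean_composition
    names = list(config.cell_types)
    n = len(phenotypes)
    ga = phenotypes["gestational_age"].to_numpy(dtype=float)
    lo, hi = config.effective_ga_range
    ga_centered = ga - (lo + hi) / 2.0

    means = np.tile(mean, (n, 1))
    if config.ga_effect_size != 0.0 and {"Trophoblasts", "Syncytiotrophoblasts"} <= set(names):
        it,is_ = names.index("Trophoblasts"), names.index("Syncytiotrophoblasts")
        shift = config.ga_effect_size * ga_centered
        means[:, it] -= shift
        means[:, is_] += shift
        if np.any(means <= 0):
            warnings.warn("GA-shifted mean left the simplex; clipping at 1e-4", stacklevel=2)
            logger.warning("sample_proportions: clipped %d shifted means", int((means <= 0).sum()))
        means = np.maximum(means, MEAN_FLOOR)
        means /= means.sum(axis=1, keepdims=True)

    alpha = means * config.dirichlet_concentration
    # vectorized Dirichlet with per-row alpha via normalized gammas
    g = rng.gamma(alpha)
    g = np.maximum(g, 1e-300)
    props = g / g.sum(axis=1, keepdims=True)
    return pd.DataFrame(props, index=phenotypes.index, columns=names)


def synthesize_betas(
    reference: ReferenceMatrix,
    base_profile: pd.Series,
    true_proportions: pd.DataFrame,
    noise_sd: float,
    sex=None,
    sex_effect_cpg_fraction: float = 0.0,
    sex_effect_size: float = 0.03,
    heavy_tail_fraction: float = 0.0,
    heavy_tail_sd: float = 0.2,
    celltype_cpg_fraction: float = 0.0,
    celltype_effect_sd: float = 0.1,
    seed=0,
) -> pd.DataFrame:
    """Mix cell-type profiles into bulk beta values, add noise, clip to [0, 1].

    With ``celltype_cpg_fraction=0`` non-marker CpGs share the common
    ``base_profile`` across cell types, so mixing leaves them at the base
    value up to noise; marker CpGs take the reference profile of each cell
    type.  A positive ``celltype_cpg_fraction`` gives that share of non-marker
    CpGs mild cell-type-dependent offsets (Gaussian, sd ``celltype_effect_sd``,
    clipped) around the base value — the genome-wide composition-sensitive
    CpGs that make cell composition the dominant axis of bulk methylation
    variance without being clean deconvolution markers.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    all_ids = list(base_profile.index)
    n_cpgs, K = len(all_ids), len(reference.cell_types)
    profiles = np.tile(base_profile.to_numpy(dtype=float)[:, None], (1, K))
    pos = {c: i for i, c in enumerate(all_ids)}
    marker_rows = np.array([pos[m] for m in reference.marker_ids])
    if celltype_cpg_fraction > 0:
        non_marker = np.setdiff1d(np.arange(n_cpgs), marker_rows)
        n_ct = int(round(celltype_cpg_fraction * len(non_marker)))
        ct_rows = rng.choice(non_marker, size=n_ct, replace=False)
        profiles[ct_rows, :] = np.clip(
            profiles[ct_rows, :] + rng.standard_normal((n_ct, K)) * celltype_effect_sd, 0.0, 1.0
        )
    profiles[marker_rows, :] = reference.values

    P = true_proportions[list(reference.cell_types)].to_numpy(dtype=float)
    betas = profiles @ P.T  # (n_cpgs, n_samples)

    if sex is not None and sex_effect_cpg_fraction > 0:
        n_sex = int(round(sex_effect_cpg_fraction * n_cpgs))
        sex_rows = rng.choice(n_cpgs, size=n_sex, replace=False)
        signs = np.where(rng.random(n_sex) < 0.5, 1.0, -1.0)
        male = np.asarray(sex, dtype=float)
        betas[sex_rows, :] += np.outer(signs * sex_effect_size, male)

    if noise_sd > 0 or heavy_tail_fraction > 0:
        sd = np.full(n_cpgs, noise_sd)
        if heavy_tail_fraction > 0:
            n_ht = int(round(heavy_tail_fraction * n_cpgs))
            sd[rng.choice(n_cpgs, size=n_ht, replace=False)] = heavy_tail_sd
        betas += rng.standard_normal(betas.shape) * sd[:, None]

    return pd.DataFrame(
        np.clip(betas, 0.0, 1.0), index=all_ids, columns=list(true_proportions.index)
    )


def generate_cohort(
    config: CohortConfig,
    reference: ReferenceMatrix | None = None,
    base_profile: pd.Series | None = None,
) -> SyntheticCohort:
    """Generate a full cohort; deterministic given ``config.seed``.

    A shared ``reference``/``base_profile`` may be supplied so that several
    cohorts live on the same CpG universe (as cohorts measured on the same
    array against the same purified-cell reference would).
    """
    ss = np.random.SeedSequence(config.seed)
    s_ref, s_base, s_ph, s_prop, s_beta = ss.spawn(5)
    if reference is None:
        reference = make_reference_profiles(
            config.n_cpgs, config.n_markers, config.cell_types, s_ref
        )
    if base_profile is None:
        base_profile = make_base_profile(config.n_cpgs, s_base)
    phenotypes = sample_phenotypes(config, s_ph)
    props = sample_proportions(config, phenotypes, s_prop)
    betas = synthesize_betas(
        reference,
        base_profile,
        props,
        config.noise_sd,
        sex=phenotypes["sex"].to_numpy(),
        sex_effect_cpg_fraction=config.sex_effect_cpg_fraction,
        sex_effect_size=config.sex_effect_size,
        heavy_tail_fraction=config.heavy_tail_fraction,
        heavy_tail_sd=config.heavy_tail_sd,
        celltype_cpg_fraction=config.celltype_cpg_fraction,
        celltype_effect_sd=config.celltype_effect_sd,
        seed=s_beta,
    )
    logger.info(
        "generated cohort %s: n=%d, cpgs=%d, markers=%d",
        config.study_preset,
        config.n_samples,
        config.n_cpgs,
        reference.n_markers,
    )
    return SyntheticCohort(betas, props, phenotypes, reference, list(reference.marker_ids), config)


def preset_config(name: str, **overrides) -> CohortConfig:
    """Convenience constructor: a CohortConfig sized like the named study arm."""
    preset = STUDY_PRESETS[name]
    cfg = CohortConfig(n_samples=preset.n_samples, study_preset=name)
    return replace(cfg, **overrides) if overrides else cfg
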