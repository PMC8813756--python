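"""Nonparametric analyses of estimated cell-type composition.

Covers the composition-level questions asked of placental cohorts: Spearman
association matrices with Bonferroni control, paired signed-rank comparisons
of the same individuals sampled at two times (first-trimester CVS versus term
placenta), nonparametric relative effects (the probability that a random
observation of one study exceeds one drawn from the others), and a global
rank-based multivariate group comparison whose null distribution is obtained
by permuting group labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def bonferroni(p_raw, n_tests: int):
    """min(1, p * n_tests) — pure function of raw p and test count."""
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * n_tests)


@dataclass
class AssociationResult:
    rho: pd.DataFrame  # Spearman coefficients, rows x cols of the two inputs
    p_raw: pd.DataFrame
    p_bonferroni: pd.DataFrame
    n_tests: int
    alpha: float = 0.01


@dataclass
class PairedTestResult:
    table: pd.DataFrame  # per cell type: medians (%), difference, Z, p values
    n_pairs: int
    alpha: float = 0.01


@dataclass
class GroupComparisonResult:
    relative_effects: pd.DataFrame  # groups x cell types, in [0, 1]
    anova_type_statistic: float
    p_permutation: float
    n_permutations: int

    def __post_init__(self) -> None:
        re = self.relative_effects
        if ((re.to_numpy() < -1e-12) | (re.to_numpy() > 1 + 1e-12)).any():
            raise ValueError("relative effects outside [0, 1]")


def _spearman_matrix(A: np.ndarray, B: np.ndarray):
    """Mid-rank Spearman rho and two-sided t-approximation p for all pairs."""
    n = A.shape[0]
    RA = np.apply_along_axis(stats.rankdata, 0, A)
    RB = np.apply_along_axis(stats.rankdata, 0, B)
    RA = (RA - RA.mean(axis=0)) / np.maximum(RA.std(axis=0), 1e-300)
    RB = (RB - RB.mean(axis=0)) / np.maximum(RB.std(axis=0), 1e-300)
    rho = np.clip(RA.T @ RB / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    return rho, p


def spearman_associations(A: pd.DataFrame, B: pd.DataFrame,
                          alpha: float = 0.01) -> AssociationResult:
    """All-pairs Spearman correlations between the columns of two tables."""
    common = A.index.intersection(B.index)
    if len(common) < 5:
        raise ValueError(f"need at least 5 shared samples, have {len(common)}")
    rho, p = _spearman_matrix(
        A.loc[common].to_numpy(dtype=float), B.loc[common].to_numpy(dtype=float)
    )
    n_tests = rho.size
    return AssociationResult(
        rho=pd.DataFrame(rho, index=A.columns, columns=B.columns),
        p_raw=pd.DataFrame(p, index=A.columns, columns=B.columns),
        p_bonferroni=pd.DataFrame(bonferroni(p, n_tests), index=A.columns, columns=B.columns),
        n_tests=n_tests,
        alpha=alpha,
    )


def signed_rank_z(d: np.ndarray):
    """Wilcoxon signed-rank Z with mid-ranks and tie-corrected variance.

    Zero differences are dropped; positive Z means the first condition tends
    to exceed the second.  Returns ``(z, p_two_sided, n_nonzero)``.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 0
    r = stats.rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(r, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        return 0.0, 1.0, n
    z = (w_plus - mu) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z))), n


def paired_celltype_tests(props_t1: pd.DataFrame, props_t2: pd.DataFrame,
                          alpha: float = 0.01) -> PairedTestResult:
    """Paired signed-rank comparison of cell proportions at two time points.

    Rows must be the same individuals in the same order; medians are reported
    on the percentage scale; Bonferroni over the number of cell types.
    """
    if list(props_t1.index) != list(props_t2.index):
        raise ValueError("paired tests require identical, aligned sample ids")
    if list(props_t1.columns) != list(props_t2.columns):
        raise ValueError("paired tests require identical cell-type columns")
    if len(props_t1) < 6:
        raise ValueError("need at least 6 pairs")
    rows = []
    for ct in props_t1.columns:
        a = props_t1[ct].to_numpy(dtype=float)
        b = props_t2[ct].to_numpy(dtype=float)
        z, p, n_nz = signed_rank_z(a - b)
        if n_nz == 0:
            logger.info("paired_celltype_tests[%s]: all differences zero", ct)
        rows.append({
            "cell_type": ct,
            "median_t1_pct": 100.0 * float(np.median(a)),
            "median_t2_pct": 100.0 * float(np.median(b)),
            "median_difference_pct": 100.0 * float(np.median(a - b)),
            "Z": z,
            "p_raw": p,
        })
    table = pd.DataFrame(rows).set_index("cell_type")
    table["p_bonferroni"] = bonferroni(table["p_raw"], len(table))
    return PairedTestResult(table=table, n_pairs=len(props_t1), alpha=alpha)


def relative_effects(props: pd.DataFrame, groups) -> pd.DataFrame:
    """Nonparametric relative effect of each group for each cell type.

    Mid-ranks are taken over all N samples; a group's effect is
    ``(mean group rank - (N+1)/2)/N + 1/2`` — the probability that a random
    member of the group exceeds a random member of the pooled sample.  The
    sample-size-weighted mean across groups is exactly 0.5.
    """
    groups = pd.Series(np.asarray(groups), index=props.index)
    N = len(props)
    labels = groups.unique()
    out = pd.DataFrame(index=pd.Index(labels, name="group"), columns=props.columns, dtype=float)
    for ct in props.columns:
        r = stats.rankdata(props[ct].to_numpy(dtype=float))
        for g in labels:
            mask = (groups == g).to_numpy()
            out.loc[g, ct] = (r[mask].mean() - (N + 1) / 2.0) / N + 0.5
    return out


def _rank_anova_statistic(R: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Between-group share of total variance of the rank-transformed matrix."""
    total = np.sum((R - R.mean(axis=0)) ** 2)
    if total <= 0:
        return 0.0
    between = 0.0
    gbar = R.mean(axis=0)
    for g in range(n_groups):
        Rg = R[codes == g]
        between += len(Rg) * np.sum((Rg.mean(axis=0) - gbar) ** 2)
    return float(between / total)


def global_rank_manova(props: pd.DataFrame, groups, n_permutations: int = 2000,
                       seed: int = 0) -> GroupComparisonResult:
    """Global multivariate comparison of composition across groups.

    Each cell type is mid-rank transformed over all samples; the ANOVA-type
    statistic is the between-group fraction of the total rank variance, and
    its p-value comes from permuting group labels (add-one convention).
    """
    groups = pd.Series(np.asarray(groups), index=props.index)
    labels, codes = np.unique(groups.to_numpy(), return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 3:
        raise ValueError(f"every group needs >= 3 samples, smallest has {sizes.min()}")

    R = np.apply_along_axis(stats.rankdata, 0, props.to_numpy(dtype=float))
    obs = _rank_anova_statistic(R, codes, len(labels))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _rank_anova_statistic(R, perm, len(labels)) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    eff = relative_effects(props, groups)
    eff = eff.loc[list(labels)]
    logger.info("global_rank_manova: statistic=%.4f p=%.4g (%d permutations)",
                obs, p, n_permutations)
    return GroupComparisonResult(eff, obs, float(p), n_permutations)


@dataclass
class GASexAssociationResult:
    table: pd.DataFrame  # per cell type: GA rho/p and sex rank-sum p
    alpha: float = 0.01


def ga_sex_associations(props: pd.DataFrame, phenotypes: pd.DataFrame,
                        alpha: float = 0.01) -> GASexAssociationResult:
    """Per-cell-type Spearman vs gestational age and rank-sum test between sexes.

    Bonferroni is applied over the cell types within each family of tests,
    matching a per-analysis correction across the six placental cell types.
    """
    common = props.index.intersection(phenotypes.index)
    P = props.loc[common]
    ga = phenotypes.loc[common, "gestational_age"].to_numpy(dtype=float)
    sex = phenotypes.loc[common, "sex"].to_numpy()
    rows = []
    for ct in P.columns:
        v = P[ct].to_numpy(dtype=float)
        rho, p_ga = stats.spearmanr(ga, v)
        male, female = v[sex == 1], v[sex == 0]
        if len(male) and len(female):
            p_sex = float(stats.mannwhitneyu(male, female, alternative="two-sided").pvalue)
        else:
            p_sex = 1.0
        rows.append({"cell_type": ct, "ga_rho": float(rho), "ga_p_raw": float(p_ga),
                     "sex_p_raw": p_sex})
    table = pd.DataFrame(rows).set_index("cell_type")
    k = len(table)
    table["ga_p_bonferroni"] = bonferroni(table["ga_p_raw"], k)
    table["sex_p_bonferroni"] = bonferroni(table["sex_p_raw"], k)
    return GASexAssociationResult(table=table, alpha=alpha)
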