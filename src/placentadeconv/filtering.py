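"""Non-variable CpG filtering, methylation PCA and sample screening.

Implements the pre-analysis reductions applied to bulk methylation matrices:
flagging CpGs whose 10th-90th percentile beta range is below a threshold in
every supplied cohort, removing the deconvolution marker CpGs to avoid
circularity, extracting principal components of the (row-centered) beta
matrix by SVD, excluding samples whose PC1 score falls outside three
inter-quartile ranges of the quartiles, and screening samples by their mean
Spearman correlation with all other samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Input matrix carries no variance to decompose."""


@dataclass
class FilterReport:
    nonvariable_ids: set
    variable_ids: set
    threshold: float
    excluded_samples: set = field(default_factory=set)
    per_sample_mean_correlation: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.nonvariable_ids & self.variable_ids:
            raise ValueError("non-variable and variable CpG sets must be disjoint")


@dataclass
class PCResult:
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fraction per component, non-increasing
    center: pd.Series  # per-CpG means removed before the SVD

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained)
        if np.any(ve < -1e-12) or np.any(ve > 1 + 1e-12):
            raise ValueError("variance_explained outside [0, 1]")
        if np.any(np.diff(ve) > 1e-12):
            raise ValueError("variance_explained must be non-increasing")

    @property
    def pc1(self) -> pd.Series:
        return self.scores.iloc[:, 0]


def nonvariable_cpgs(betas_list, threshold: float = 0.05) -> FilterReport:
    """Flag CpGs with a 10-90 percentile beta range below ``threshold``.

    A CpG is non-variable only if its range is below the threshold in *every*
    supplied matrix (intersection rule over cohorts); only CpGs present in
    all matrices are assessed, the rest stay variable.
    """
    if isinstance(betas_list, pd.DataFrame):
        betas_list = [betas_list]
    if not betas_list:
        raise ValueError("at least one beta matrix required")
    common = set(betas_list[0].index)
    all_ids = set()
    for b in betas_list:
        common &= set(b.index)
        all_ids |= set(b.index)
        if b.shape[1] < 10:
            warnings.warn(
                f"matrix with {b.shape[1]} samples: 10/90 percentiles are unstable", stacklevel=2
            )
    if not common:
        raise ValueError("no CpG shared by all supplied matrices")

    common_idx = sorted(common)
    nonvar = np.ones(len(common_idx), dtype=bool)
    for b in betas_list:
        X = b.loc[common_idx].to_numpy(dtype=float)
        q10, q90 = np.percentile(X, [10, 90], axis=1)  # linear interpolation
        nonvar &= (q90 - q10) < threshold
    nonvariable = {c for c, f in zip(common_idx, nonvar) if f}
    logger.info("nonvariable_cpgs: %d of %d shared CpGs non-variable (threshold %.3f)",
                len(nonvariable), len(common_idx), threshold)
    return FilterReport(nonvariable, all_ids - nonvariable, threshold)


def exclude_reference_cpgs(betas: pd.DataFrame, marker_ids) -> pd.DataFrame:
    """Drop deconvolution marker CpGs from a beta matrix (anti-circularity)."""
    marker_set = set(marker_ids)
    keep = [c for c in betas.index if c not in marker_set]
    removed = betas.shape[0] - len(keep)
    logger.info("exclude_reference_cpgs: removed %d marker CpGs, %d remain", removed, len(keep))
    if not keep:
        raise ValueError("all CpGs are reference markers; nothing left to analyse")
    return betas.loc[keep]


def first_pcs(betas: pd.DataFrame, n_components: int = 1) -> PCResult:
    """Principal components of the beta matrix by row-centered SVD.

    Rows (CpGs) are mean-centered but not scaled — beta values share a scale.
    Scores are right-singular vectors times singular values.  PC1's sign is
    fixed so its scores correlate non-negatively with per-sample mean beta
    (tie: positive first loading); higher components get a deterministic
    largest-|loading|-positive convention.
    """
    X = betas.to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("beta matrix contains missing or non-finite values")
    center = X.mean(axis=1)
    Xc = X - center[:, None]
    if np.allclose(Xc, 0):
        raise DegenerateInputError("beta matrix has zero variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, len(s))
    var_exp = s**2 / np.sum(s**2)

    scores = (s[:, None] * Vt)[:n_components].T  # (samples, n_components)
    loadings = U[:, :n_components]
    mean_beta = X.mean(axis=0)
    for i in range(n_components):
        if i == 0:
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(scores[:, 0], mean_beta)[0, 1]
            flip = (c < 0) if np.isfinite(c) and c != 0 else (loadings[0, 0] < 0)
        else:
            j = np.argmax(np.abs(loadings[:, i]))
            flip = loadings[j, i] < 0
        if flip:
            scores[:, i] *= -1
            loadings[:, i] *= -1
    return PCResult(
        scores=pd.DataFrame(
            scores, index=betas.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
        ),
        variance_explained=var_exp[:n_components],
        center=pd.Series(center, index=betas.index, name="center"),
    )


def pc1_outliers(scores: pd.Series) -> set:
    """Samples whose PC1 score lies beyond 3 x IQR outside the quartiles."""
    if len(scores) < 8:
        raise ValueError("need at least 8 samples for stable quartile fences")
    v = scores.to_numpy(dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 3 * iqr, q3 + 3 * iqr
    flagged = {s for s, x in scores.items() if x < lo or x > hi}
    logger.info("pc1_outliers: flagged %d of %d samples (fences %.4g, %.4g)",
                len(flagged), len(scores), lo, hi)
    return flagged


def sample_correlation_screen(betas: pd.DataFrame) -> pd.Series:
    """Mean Spearman correlation of each sample's betas with every other sample."""
    X = betas.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    ranks = np.apply_along_axis(rankdata, 0, X)
    C = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(C, np.nan)
    return pd.Series(np.nanmean(C, axis=0), index=betas.columns, name="mean_spearman")
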