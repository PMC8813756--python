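"""Repeated cross-validation comparison of six models predicting PC1.

The competing models regress the first principal component of methylation on
(1) an intercept only, (2) phenotypes (gestational age, child sex, ancestry
components), (3) reference-based estimated cell types, (4) reference-based
cell types + phenotypes, (5) reference-free components, and (6) reference-free
components + phenotypes.  Out-of-sample root-mean-square error is computed by
k-fold cross-validation repeated many times with the *same* fold partition
shared by all models in a repeat; the winner of a repeat is the model with the
smallest pooled out-of-fold RMSE.  The winning model is additionally refit on
all data and summarized by its adjusted R².

A per-CpG variant regresses every CpG's beta values on the reference-based or
reference-free composition and records the adjusted R², from which the set of
CpGs strongly driven by cell composition (adjusted R² above a threshold in
every cohort) is extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical model ordering; ties in a repeat go to the earlier model
MODEL_NAMES = (
    "intercept",
    "phenotypes",
    "ref_based",
    "ref_based+phenotypes",
    "ref_free",
    "ref_free+phenotypes",
)


@dataclass(frozen=True)
class ModelSpec:
    name: str
    uses_ref_based: bool = False
    uses_ref_free: bool = False
    uses_phenotypes: bool = False


def default_model_specs() -> list:
    """The six-model comparison set in canonical order."""
    return [
        ModelSpec("intercept"),
        ModelSpec("phenotypes", uses_phenotypes=True),
        ModelSpec("ref_based", uses_ref_based=True),
        ModelSpec("ref_based+phenotypes", uses_ref_based=True, uses_phenotypes=True),
        ModelSpec("ref_free", uses_ref_free=True),
        ModelSpec("ref_free+phenotypes", uses_ref_free=True, uses_phenotypes=True),
    ]


@dataclass
class CVResult:
    rmse: pd.DataFrame  # repeats x models
    wins: pd.Series  # per-model counts, sums to repeats
    win_proportions: pd.Series
    mean_rmse: pd.Series
    ci_rmse: pd.DataFrame  # 2.5 / 97.5 percentiles of the repeat RMSE distribution
    winner: str
    winner_adjusted_r2: float
    folds: int
    repeats: int
    seed: int

    def __post_init__(self) -> None:
        if int(self.wins.sum()) != self.repeats:
            raise ValueError("win counts must sum to the number of repeats")
        if abs(float(self.win_proportions.sum()) - 1.0) > 1e-9:
            raise ValueError("win proportions must sum to 1")
        if (self.rmse.to_numpy() < 0).any():
            raise ValueError("RMSE must be non-negative")


def _proportion_block(props: pd.DataFrame, prefix: str) -> pd.DataFrame:
    """Cell-type predictors with the largest-mean column dropped.

    Proportions sum to one, so keeping all columns plus an intercept would be
    rank-deficient; the most abundant type becomes the baseline.
    """
    drop = props.mean().idxmax()
    block = props.drop(columns=[drop])
    return block.add_prefix(prefix)


def build_model_matrix(
    spec: ModelSpec,
    proportions_rb: pd.DataFrame | None = None,
    omega_rf: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
    samples=None,
) -> pd.DataFrame:
    """Design matrix for one model spec; complete cases only.

    Always includes an intercept column; sex is coded 0/1; ancestry columns
    are every phenotype column whose name starts with ``ancestry``.
    """
    parts = []
    if spec.uses_ref_based:
        if proportions_rb is None:
            raise ValueError(f"model {spec.name!r} needs reference-based proportions")
        parts.append(_proportion_block(proportions_rb, "rb_"))
    if spec.uses_ref_free:
        if omega_rf is None:
            raise ValueError(f"model {spec.name!r} needs reference-free components")
        parts.append(_proportion_block(omega_rf, "rf_"))
    if spec.uses_phenotypes:
        if phenotypes is None:
            raise ValueError(f"model {spec.name!r} needs phenotypes")
        cols = ["gestational_age", "sex"] + [
            c for c in phenotypes.columns if c.startswith("ancestry")
        ]
        ph = phenotypes[cols].copy()
        if ph["sex"].dtype == object:
            ph["sex"] = (ph["sex"].astype(str).str.lower().isin(["male", "m", "1"])).astype(int)
        parts.append(ph)

    if samples is None:
        pools = [p.index for p in parts]
        samples = pools[0] if pools else (
            (proportions_rb if proportions_rb is not None else
             omega_rf if omega_rf is not None else phenotypes).index
        )
        for p in pools[1:]:
            samples = samples.intersection(p)
    X = pd.DataFrame({"intercept": 1.0}, index=samples)
    for p in parts:
        X = X.join(p, how="inner")
    complete = X.dropna()
    if len(complete) < len(X):
        logger.info("build_model_matrix[%s]: dropped %d incomplete rows",
                    spec.name, len(X) - len(complete))
    return complete.astype(float)


def _ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.info("singular design (rank %d < %d); ridge fallback", rank, X.shape[1])
        G = X.T @ X + 1e-8 * np.eye(X.shape[1])
        coef = np.linalg.solve(G, X.T @ y)
    return coef


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list:
    perm = rng.permutation(n)
    return np.array_split(perm, folds)


def repeated_cv(
    y: pd.Series,
    designs: dict,
    folds: int = 10,
    repeats: int = 500,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold CV of several designs against the same outcome.

    ``designs`` maps model name -> design matrix; all are aligned to the
    samples shared with ``y``.  Within a repeat every model sees the identical
    fold partition.  RMSE pools out-of-fold residuals across folds.
    """
    names = list(designs)
    common = y.index
    for X in designs.values():
        common = common.intersection(X.index)
    yv = y.loc[common].to_numpy(dtype=float)
    if not np.all(np.isfinite(yv)):
        raise ValueError("outcome contains non-finite values")
    n = len(common)
    if n < 2 * folds:
        raise ValueError(f"need at least {2 * folds} samples for {folds}-fold CV, have {n}")
    Xs = {m: designs[m].loc[common].to_numpy(dtype=float) for m in names}

    rng = np.random.default_rng(seed)
    rmse = np.empty((repeats, len(names)))
    for r in range(repeats):
        fold_idx = _fold_indices(n, folds, rng)
        for mi, m in enumerate(names):
            X = Xs[m]
            resid = np.empty(n)
            for te in fold_idx:
                tr = np.setdiff1d(np.arange(n), te)
                coef = _ols_fit(X[tr], yv[tr])
                resid[te] = yv[te] - X[te] @ coef
            rmse[r, mi] = np.sqrt(np.mean(resid**2))
    winners = np.argmin(rmse, axis=1)  # argmin takes the first minimum: tie rule
    wins = pd.Series(np.bincount(winners, minlength=len(names)), index=names, name="wins")
    win_prop = wins / repeats
    winner = names[int(wins.to_numpy().argmax())]
    w_adj = adjusted_r2(pd.Series(yv, index=common), designs[winner].loc[common])
    rmse_df = pd.DataFrame(rmse, columns=names)
    logger.info("repeated_cv: winner=%s (%.0f%% of %d repeats)",
                winner, 100 * win_prop[winner], repeats)
    return CVResult(
        rmse=rmse_df,
        wins=wins,
        win_proportions=win_prop,
        mean_rmse=rmse_df.mean(),
        ci_rmse=rmse_df.quantile([0.025, 0.975]),
        winner=winner,
        winner_adjusted_r2=w_adj,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


def adjusted_r2(y: pd.Series, design: pd.DataFrame) -> float:
    """1 - (1 - R²)(n - 1)/(n - p - 1) with p = non-intercept predictor count."""
    common = y.index.intersection(design.index)
    yv = y.loc[common].to_numpy(dtype=float)
    X = design.loc[common].to_numpy(dtype=float)
    coef = _ols_fit(X, yv)
    resid = yv - X @ coef
    sst = np.sum((yv - yv.mean()) ** 2)
    if sst == 0:
        return 1.0 if np.allclose(resid, 0) else 0.0
    r2 = 1.0 - np.sum(resid**2) / sst
    n = len(yv)
    p = sum(1 for c in design.columns if c != "intercept")
    if n - p - 1 <= 0:
        raise ValueError("too few samples for adjusted R² with this many predictors")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def _adjusted_r2_matrix(Y: np.ndarray, X: np.ndarray, p: int) -> np.ndarray:
    """Vectorized adjusted R² of each column of ``Y`` on the shared design ``X``."""
    n = X.shape[0]
    Q, _ = np.linalg.qr(X)
    fitted = Q @ (Q.T @ Y)
    ssr = np.sum((Y - fitted) ** 2, axis=0)
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - ssr / np.maximum(sst, 1e-300), 0.0)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def per_cpg_r2(betas: pd.DataFrame, design_rb: pd.DataFrame,
               design_rf: pd.DataFrame) -> pd.DataFrame:
    """Adjusted R² of every CpG under the two composition designs.

    Returns a CpG-indexed frame with columns ``ref_based`` and ``ref_free``.
    """
    out = {}
    for label, design in [("ref_based", design_rb), ("ref_free", design_rf)]:
        common = betas.columns.intersection(design.index)
        Y = betas[common].to_numpy(dtype=float).T  # samples x CpGs
        X = design.loc[common].to_numpy(dtype=float)
        p = sum(1 for c in design.columns if c != "intercept")
        out[label] = _adjusted_r2_matrix(Y, X, p)
    return pd.DataFrame(out, index=betas.index)


def high_r2_intersection(r2_tables, threshold: float = 0.30) -> set:
    """CpGs with adjusted R² strictly above ``threshold`` in every table."""
    if not r2_tables:
        raise ValueError("need at least one R² table")
    result = None
    for t in r2_tables:
        s = t if isinstance(t, pd.Series) else pd.Series(t)
        ids = set(s.index[s > threshold])
        result = ids if result is None else result & ids
    return result
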