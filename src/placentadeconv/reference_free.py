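"""Reference-free decomposition of a beta matrix into latent methylomes.

Factorizes bulk methylation ``B (CpG x samples)`` as ``B ~ M @ Omega.T`` where
``M`` holds K latent component methylomes with entries in [0, 1] and ``Omega``
holds per-sample component proportions on the probability simplex.  The fit is
alternating constrained least squares on the most-variable CpGs:

* Omega update — per sample, exact least squares constrained to the simplex
  (non-negative, summing to one), solved by a small active-set quadratic
  program with KKT verification;
* M update — per CpG, box-constrained least squares via exact coordinate
  descent with clipping to [0, 1].

Both updates exactly minimize the reconstruction deviance over their block,
so the objective is non-increasing across iterations.  Initialization is a
Ward-linkage hierarchical clustering of samples, cluster mean profiles
seeding M.  The number of components K is chosen by bootstrap out-of-bag
deviance, mirroring protocols that select K where held-out reconstruction
error is minimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)


class InvalidKError(ValueError):
    """Requested component count is outside [1, n_samples - 1]."""


@dataclass
class FactorizationResult:
    M: pd.DataFrame  # CpG x K latent methylomes, entries in [0, 1]
    Omega: pd.DataFrame  # samples x K proportions, rows on the simplex
    K: int
    deviance: float  # mean squared reconstruction error on the fitted CpGs
    n_iter: int
    converged: bool
    deviance_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        Mv, Ov = self.M.to_numpy(), self.Omega.to_numpy()
        if np.any(Mv < -1e-12) or np.any(Mv > 1 + 1e-12):
            raise ValueError("latent methylome entries outside [0, 1]")
        if np.any(Ov < -1e-12):
            raise ValueError("negative component proportion")
        if np.any(np.abs(Ov.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("Omega rows must sum to 1 within 1e-9")
        if self.deviance < 0:
            raise ValueError("deviance must be non-negative")


def simplex_lstsq(M: np.ndarray, b: np.ndarray, max_active_set_iter: int = 200) -> np.ndarray:
    """Exact ``argmin ||b - M w||`` subject to ``w >= 0`` and ``sum(w) = 1``.

    Active-set method on the non-negativity constraints; the equality
    constraint is handled through the KKT system.  Terminates at a point
    satisfying the KKT conditions (verified, not assumed).
    """
    K = M.shape[1]
    if K == 1:
        return np.array([1.0])
    G = M.T @ M
    h = M.T @ b
    support = np.ones(K, dtype=bool)
    w = np.zeros(K)
    for _ in range(max_active_set_iter):
        idx = np.flatnonzero(support)
        k = len(idx)
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = G[np.ix_(idx, idx)]
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.append(h[idx], 1.0)
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        w_s = sol[:k]
        if np.any(w_s < -1e-12):
            if k == 1:
                break
            support[idx[np.argmin(w_s)]] = False
            continue
        w = np.zeros(K)
        w[idx] = np.maximum(w_s, 0.0)
        w /= w.sum()
        # KKT check for zeroed coordinates: gradient must not favour re-entry
        g = G @ w - h
        mu = g[idx].mean()
        off = ~support
        viol = off & (g < mu - 1e-10)
        if not viol.any():
            return w
        support[np.argmin(np.where(viol, g, np.inf))] = True
    # fall back to the best feasible point found
    if w.sum() <= 0:
        w = np.full(K, 1.0 / K)
    return w / w.sum()


def simplex_lstsq_batch(M: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Simplex-constrained least squares of every column of ``B`` on ``M``.

    Solves the full-support KKT system once for all columns (shared design);
    columns whose unconstrained-on-the-simplex solution has negative entries
    are re-solved individually by the active-set routine.
    """
    K, n = M.shape[1], B.shape[1]
    if K == 1:
        return np.ones((n, 1))
    G = M.T @ M
    kkt = np.zeros((K + 1, K + 1))
    kkt[:K, :K] = G
    kkt[:K, K] = 1.0
    kkt[K, :K] = 1.0
    rhs = np.vstack([M.T @ B, np.ones(n)])
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    W = sol[:K, :].T  # (n, K)
    bad = np.any(W < -1e-12, axis=1)
    W = np.maximum(W, 0.0)
    W /= W.sum(axis=1, keepdims=True)
    for j in np.flatnonzero(bad):
        W[j] = simplex_lstsq(M, B[:, j])
    return W


def top_variable_cpgs(betas: pd.DataFrame, n: int) -> pd.DataFrame:
    """Rows of the beta matrix with the largest variance (stable order)."""
    v = betas.to_numpy().var(axis=1)
    order = np.argsort(-v, kind="stable")[: min(n, len(v))]
    return betas.iloc[np.sort(order)]


def _update_m(X: np.ndarray, M: np.ndarray, O: np.ndarray, n_passes: int = 2) -> np.ndarray:
    """Box-constrained M update by exact per-coordinate descent with clipping."""
    K = M.shape[1]
    E = X - M @ O.T
    for _ in range(n_passes):
        for k in range(K):
            ok = O[:, k]
            denom = ok @ ok
            if denom < 1e-30:
                continue
            Rk = E @ ok + M[:, k] * denom
            new = np.clip(Rk / denom, 0.0, 1.0)
            E += np.outer(M[:, k] - new, ok)
            M[:, k] = new
    return M


def _ward_init(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Initial latent methylomes: Ward-cluster samples, take cluster means."""
    n = X.shape[1]
    if K == 1:
        return X.mean(axis=1, keepdims=True)
    Z = linkage(X.T, method="ward")
    labels = fcluster(Z, t=K, criterion="maxclust")
    uniq = np.unique(labels)
    M0 = np.empty((X.shape[0], K))
    for i in range(K):
        if i < len(uniq):
            M0[:, i] = X[:, labels == uniq[i]].mean(axis=1)
        else:  # duplicate-heavy data produced fewer clusters: jitter a copy
            M0[:, i] = np.clip(M0[:, i - len(uniq)] + 0.01 * rng.standard_normal(X.shape[0]), 0, 1)
    return M0


def reffree_factorize(
    betas: pd.DataFrame,
    K: int,
    n_top_variable_cpgs: int = 10000,
    tol: float = 1e-6,
    max_iter: int = 100,
    seed: int = 0,
    row_normalize: bool = True,
) -> FactorizationResult:
    """Fit a K-component reference-free decomposition of a beta matrix.

    With ``row_normalize=False`` the Omega update drops the sum-to-one
    constraint (non-negativity only, via per-sample NNLS-style solves) and the
    returned Omega is normalized only for reporting.
    """
    n_samples = betas.shape[1]
    if not 1 <= K < n_samples:
        raise InvalidKError(f"K={K} outside [1, n_samples-1={n_samples - 1}]")
    X_full = betas.to_numpy(dtype=float)
    if not np.all(np.isfinite(X_full)):
        raise ValueError("beta matrix contains non-finite values")
    sub = top_variable_cpgs(betas, n_top_variable_cpgs)
    X = sub.to_numpy(dtype=float)

    if K == 1:
        M = X.mean(axis=1, keepdims=True)
        Omega = np.ones((n_samples, 1))
        dev = float(np.mean((X - M @ Omega.T) ** 2))
        return FactorizationResult(
            pd.DataFrame(M, index=sub.index, columns=["C1"]),
            pd.DataFrame(Omega, index=betas.columns, columns=["C1"]),
            1, dev, 0, True, [dev],
        )

    rng = np.random.default_rng(seed)
    M = np.clip(_ward_init(X, K, rng), 0.0, 1.0)
    trace: list = []
    prev = np.inf
    converged = False
    n_iter = 0
    Omega = None
    for n_iter in range(1, max_iter + 1):
        if row_normalize:
            W = simplex_lstsq_batch(M, X)
            if Omega is not None:
                # monotone safeguard: on ill-conditioned (near-collinear M)
                # instances the QP solve can be numerically worse than the
                # incumbent row — never accept a worsening update
                r_new = ((X - M @ W.T) ** 2).sum(axis=0)
                r_old = ((X - M @ Omega.T) ** 2).sum(axis=0)
                worse = r_new > r_old
                if worse.any():
                    W[worse] = Omega[worse]
            Omega = W
        else:
            from scipy.optimize import nnls as _nnls

            Omega = np.vstack([_nnls(M, X[:, j])[0] for j in range(n_samples)])
        M = _update_m(X, M, Omega)
        dev = float(np.mean((X - M @ Omega.T) ** 2))
        if row_normalize and trace and dev > trace[-1] * (1 + 1e-9) + 1e-15:
            raise AssertionError(f"deviance increased: {trace[-1]} -> {dev}")
        trace.append(dev)
        if prev - dev < tol * max(prev, 1e-30):
            converged = True
            break
        prev = dev
    if not row_normalize:
        s = Omega.sum(axis=1, keepdims=True)
        Omega = np.where(s > 0, Omega / np.maximum(s, 1e-300), 1.0 / K)

    cols = [f"C{i + 1}" for i in range(K)]
    logger.info("reffree_factorize: K=%d converged=%s iters=%d deviance=%.3e",
                K, converged, n_iter, trace[-1])
    return FactorizationResult(
        pd.DataFrame(np.clip(M, 0, 1), index=sub.index, columns=cols),
        pd.DataFrame(Omega, index=betas.columns, columns=cols),
        K, trace[-1], n_iter, converged, trace,
    )


def oob_deviance(M: pd.DataFrame, betas: pd.DataFrame) -> float:
    """Reconstruction deviance of held-out samples given fitted methylomes."""
    X = betas.loc[M.index].to_numpy(dtype=float)
    Mv = M.to_numpy(dtype=float)
    Omega = simplex_lstsq_batch(Mv, X)
    return float(np.mean((X - Mv @ Omega.T) ** 2))


def select_k(
    betas: pd.DataFrame,
    k_range: tuple,
    n_boot: int = 5,
    seed: int = 0,
    n_top_variable_cpgs: int = 10000,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple:
    """Choose K by average out-of-bag bootstrap deviance.

    For each candidate K and each bootstrap resample of samples, the model is
    fitted on the resample and scored on the out-of-bag samples; the K with
    the smallest mean out-of-bag deviance wins (ties broken towards smaller K).
    Returns ``(selected_k, table)`` where the table has one row per candidate.
    """
    kmin, kmax = k_range
    n = betas.shape[1]
    if not (2 <= kmin <= kmax <= n - 1):
        raise InvalidKError(f"k_range {k_range} outside [2, n_samples-1]")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)

    draws = []
    for _ in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if len(oob) > 0:
                break
            logger.info("select_k: empty out-of-bag set, redrawing resample")
        draws.append((idx, oob))

    rows = []
    for K in range(kmin, kmax + 1):
        devs = []
        for b, (idx, oob) in enumerate(draws):
            fit = reffree_factorize(
                betas.iloc[:, idx], K,
                n_top_variable_cpgs=n_top_variable_cpgs,
                tol=tol, max_iter=max_iter,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            devs.append(oob_deviance(fit.M, betas.iloc[:, oob]))
        rows.append({"K": K, "mean_oob_deviance": float(np.mean(devs)),
                     "sd_oob_deviance": float(np.std(devs))})
    table = pd.DataFrame(rows)
    selected = int(table.loc[table["mean_oob_deviance"].idxmin(), "K"])
    logger.info("select_k: selected K=%d from %s", selected, list(range(kmin, kmax + 1)))
    return selected, table
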