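"""Inference on canonical modes: permutation test, cross-validation, jackknife.

Mode matching across permutations, folds and delete-one refits is by index
(k-th against k-th) after sign alignment, the convention of the underlying
resampling methodology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cca import CCAResult, fit_cca, project, sign_align

__all__ = [
    "PermutationResult",
    "CVResult",
    "JackknifeResult",
    "permutation_test",
    "cross_validate",
    "jackknife_loadings",
]


@dataclass
class PermutationResult:
    n_perm: int
    observed: np.ndarray          # (K,) observed canonical correlations
    null_distribution: np.ndarray  # (n_perm, K)
    p_values: np.ndarray          # (K,) add-one permutation p-values


@dataclass
class CVResult:
    n_folds: int
    n_reps: int
    mean_train: np.ndarray  # (K,)
    mean_test: np.ndarray   # (K,)
    records: pd.DataFrame   # per (rep, fold, mode): train/test correlations


@dataclass
class JackknifeResult:
    x_loadings: np.ndarray  # (n, p, K) delete-one structure loadings
    y_loadings: np.ndarray  # (n, q, K)
    x_sd: np.ndarray        # (p, K)
    y_sd: np.ndarray
    x_range: tuple[np.ndarray, np.ndarray]  # (min, max), each (p, K)
    y_range: tuple[np.ndarray, np.ndarray]


def _blocks(X, Y):
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Ym = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    return Xm, Ym


def permutation_test(X, Y, n_perm: int = 10_000, seed: int = 0) -> PermutationResult:
    """Permutation significance of all canonical modes.

    The rows of the marker block ``Y`` are shuffled (``X`` fixed) and the
    CCA refit for each permutation; row shuffling leaves the within-block
    covariances untouched, so each refit reuses the observed whitening
    matrices and recomputes only the cross-covariance — numerically
    identical to a full refit.  p_k compares the k-th observed correlation
    with the k-th null correlations (add-one rule).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    result = fit_cca(X, Y)
    Xm, Ym = _blocks(X, Y)
    n = Xm.shape[0]
    Xc = Xm - Xm.mean(axis=0)
    Yc = Ym - Ym.mean(axis=0)
    # whitening matrices recovered from the fitted weights are not exposed;
    # recompute them once here
    from .cca import RIDGE_EPS, _inv_sqrt

    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Wx = _inv_sqrt(Sxx, result.x_names, RIDGE_EPS * np.trace(Sxx) / result.p)
    Wy = _inv_sqrt(Syy, result.y_names, RIDGE_EPS * np.trace(Syy) / result.q)

    K = result.n_modes
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, K))
    for b in range(n_perm):
        perm = rng.permutation(n)
        M = Wx @ (Xc.T @ Yc[perm] / (n - 1)) @ Wy
        null[b] = np.clip(np.linalg.svd(M, compute_uv=False)[:K], 0.0, 1.0)
    p = (1.0 + (null >= result.correlations).sum(axis=0)) / (n_perm + 1.0)
    return PermutationResult(
        n_perm=n_perm, observed=result.correlations.copy(),
        null_distribution=null, p_values=p,
    )


def cross_validate(
    X, Y, n_folds: int = 10, n_reps: int = 100, seed: int = 0,
    anchor: str = "verbal_learning",
) -> CVResult:
    """Repeated k-fold out-of-sample validation of the canonical modes.

    Per repetition, rows are partitioned into ``n_folds`` folds; each fold
    in turn is held out, the CCA fit on the remainder, and the held-out
    rows projected through the training weights.  The test statistic per
    mode is the Pearson correlation between the projected variate pair on
    the held-out rows; generalizing modes keep most of their training
    correlation, overfit modes collapse toward zero.
    """
    Xm, Ym = _blocks(X, Y)
    n = Xm.shape[0]
    if n < 5 * n_folds:
        raise ValueError(f"need n >= 5*n_folds rows, got {n}")
    x_cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    rng = np.random.default_rng(seed)
    rows = []
    K = min(Xm.shape[1], Ym.shape[1])
    for rep in range(n_reps):
        order = rng.permutation(n)
        folds = np.array_split(order, n_folds)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(order, test_idx, assume_unique=True)
            Xtr = pd.DataFrame(Xm[train_idx], columns=x_cols) if x_cols else Xm[train_idx]
            res = sign_align(fit_cca(Xtr, Ym[train_idx]), anchor)
            xs_t, ys_t = project(res, Xm[test_idx], Ym[test_idx])
            for k in range(K):
                x, y = xs_t[:, k], ys_t[:, k]
                sx, sy = x.std(), y.std()
                r_test = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else 0.0
                rows.append((rep, f, k, float(res.correlations[k]), r_test))
    records = pd.DataFrame(rows, columns=["rep", "fold", "mode", "r_train", "r_test"])
    grouped = records.groupby("mode")
    return CVResult(
        n_folds=n_folds, n_reps=n_reps,
        mean_train=grouped["r_train"].mean().to_numpy(),
        mean_test=grouped["r_test"].mean().to_numpy(),
        records=records,
    )


def jackknife_loadings(X, Y, anchor: str = "verbal_learning") -> JackknifeResult:
    """Delete-one jackknife distributions of the structure loadings.

    Each row is removed in turn and the CCA refit; every refit's modes are
    sign-matched to the full-sample solution (a mode is flipped when the
    dot product of its cognitive loading vector with the full-sample one is
    negative).  Spread summaries (SD, min–max envelope) quantify loading
    stability.
    """
    Xm, Ym = _blocks(X, Y)
    n, p = Xm.shape
    q = Ym.shape[1]
    if n < p + q + 2:
        raise ValueError("too few rows for a delete-one jackknife")
    x_cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    full = sign_align(fit_cca(X, Y), anchor)
    K = full.n_modes
    xl = np.empty((n, p, K))
    yl = np.empty((n, q, K))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi = pd.DataFrame(Xm[mask], columns=x_cols) if x_cols else Xm[mask]
        res = fit_cca(Xi, Ym[mask])
        for k in range(K):
            if res.x_loadings[:, k] @ full.x_loadings[:, k] < 0:
                res.x_loadings[:, k] *= -1
                res.y_loadings[:, k] *= -1
        xl[i] = res.x_loadings
        yl[i] = res.y_loadings
        mask[i] = True
    return JackknifeResult(
        x_loadings=xl, y_loadings=yl,
        x_sd=xl.std(axis=0, ddof=1), y_sd=yl.std(axis=0, ddof=1),
        x_range=(xl.min(axis=0), xl.max(axis=0)),
        y_range=(yl.min(axis=0), yl.max(axis=0)),
    )
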