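"""Classical canonical correlation analysis between two variable blocks.

Implements CCA through the singular value decomposition of the whitened
cross-covariance: with block covariances ``Sxx``, ``Syy`` and
cross-covariance ``Sxy``, the singular values of
``Sxx^{-1/2} Sxy Syy^{-1/2}`` are the canonical correlations and the
singular vectors, back-transformed through the whitening matrices, are the
canonical weights.  Scores are scaled to sample SD 1 so that distances in
variate space are commensurate across modes.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CCAResult", "fit_cca", "variance_explained", "sign_align", "project"]

#: ridge added to each block covariance, relative to trace/p; numerical only
RIDGE_EPS = 1e-10


@dataclass
class CCAResult:
    """Fitted canonical correlation model.

    Attributes
    ----------
    correlations : (K,) canonical correlations, non-increasing in k.
    x_weights, y_weights : (p, K) and (q, K) maps from centered data to scores.
    x_loadings, y_loadings : structure correlations of each variable with its
        own block's variate.
    x_scores, y_scores : (n, K) participant variate scores, sample SD 1.
    x_mean, y_mean : training column means (used by :func:`project`).
    x_names, y_names : column labels.
    """

    correlations: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_names: list
    y_names: list

    @property
    def n(self) -> int:
        return self.x_scores.shape[0]

    @property
    def p(self) -> int:
        return self.x_weights.shape[0]

    @property
    def q(self) -> int:
        return self.y_weights.shape[0]

    @property
    def n_modes(self) -> int:
        return len(self.correlations)


def _as_matrix(block) -> tuple[np.ndarray, list]:
    if isinstance(block, pd.DataFrame):
        return block.to_numpy(dtype=float), list(block.columns)
    arr = np.asarray(block, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _inv_sqrt(S: np.ndarray, names: list, ridge: float) -> np.ndarray:
    S = S + ridge * np.eye(S.shape[0])
    vals, vecs = np.linalg.eigh(S)
    rel_tol = 1e-9 * vals.max()
    if vals.min() < rel_tol:
        bad = [names[j] for j in np.argsort(np.abs(vecs[:, 0]))[::-1][:3]]
        raise np.linalg.LinAlgError(
            "block covariance is rank deficient beyond ridge tolerance; "
            f"columns most involved in the null direction: {bad}"
        )
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def fit_cca(X, Y) -> CCAResult:
    """Fit classical CCA between blocks ``X`` (n×p) and ``Y`` (n×q).

    Both blocks must be complete (no missing cells) with non-degenerate
    columns; a warning is issued when n ≤ p + q, where canonical
    correlations are heavily inflated.
    """
    Xm, x_names = _as_matrix(X)
    Ym, y_names = _as_matrix(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if np.isnan(Xm).any() or np.isnan(Ym).any():
        raise ValueError("CCA requires complete data; impute missing cells first")
    n, p = Xm.shape
    q = Ym.shape[1]
    for M, names in ((Xm, x_names), (Ym, y_names)):
        sd = M.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = [names[j] for j in np.where(sd == 0)[0]]
            raise ValueError(f"zero-variance column(s): {zero}")
    if n <= p + q:
        warnings.warn(
            f"n = {n} <= p + q = {p + q}: canonical correlations will be "
            "strongly overfit", stacklevel=2,
        )

    x_mean = Xm.mean(axis=0)
    y_mean = Ym.mean(axis=0)
    Xc = Xm - x_mean
    Yc = Ym - y_mean
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)

    Wx = _inv_sqrt(Sxx, x_names, RIDGE_EPS * np.trace(Sxx) / p)
    Wy = _inv_sqrt(Syy, y_names, RIDGE_EPS * np.trace(Syy) / q)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    K = min(p, q)
    corrs = np.clip(s[:K], 0.0, 1.0)

    x_weights = Wx @ U[:, :K]
    y_weights = Wy @ Vt.T[:, :K]
    x_scores = Xc @ x_weights
    y_scores = Yc @ y_weights
    # scale scores (and weights) to sample SD 1
    for scores, weights in ((x_scores, x_weights), (y_scores, y_weights)):
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        scores /= sd
        weights /= sd

    x_loadings = _structure_loadings(Xc, x_scores)
    y_loadings = _structure_loadings(Yc, y_scores)
    return CCAResult(
        correlations=corrs,
        x_weights=x_weights, y_weights=y_weights,
        x_loadings=x_loadings, y_loadings=y_loadings,
        x_scores=x_scores, y_scores=y_scores,
        x_mean=x_mean, y_mean=y_mean,
        x_names=x_names, y_names=y_names,
    )


def _structure_loadings(centered: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Correlation of each (centered) variable with each score column."""
    var_sd = centered.std(axis=0, ddof=1)
    sc_sd = scores.std(axis=0, ddof=1)
    cov = centered.T @ scores / (centered.shape[0] - 1)
    return cov / np.outer(var_sd, sc_sd)


def variance_explained(r: float) -> float:
    """Percent shared variance of a mode: 100·r²."""
    if not 0 <= r <= 1:
        raise ValueError(f"canonical correlation must lie in [0, 1], got {r}")
    return 100.0 * r * r


def sign_align(result: CCAResult, anchor_x_variable: str = "verbal_learning") -> CCAResult:
    """Fix the arbitrary reflection of each mode.

    Per mode: flip the X side so the anchor variable's structure loading is
    positive (tie-break on the largest-|loading| variable when the anchor
    loading is exactly zero), then flip the Y side so the score correlation
    is non-negative.  Canonical correlations are unchanged.
    """
    if anchor_x_variable in result.x_names:
        anchor = result.x_names.index(anchor_x_variable)
    else:
        anchor = int(np.argmax(np.abs(result.x_loadings[:, 0])))

    out = dataclasses.replace(
        result,
        x_weights=result.x_weights.copy(), y_weights=result.y_weights.copy(),
        x_loadings=result.x_loadings.copy(), y_loadings=result.y_loadings.copy(),
        x_scores=result.x_scores.copy(), y_scores=result.y_scores.copy(),
    )
    for k in range(out.n_modes):
        a = anchor
        if out.x_loadings[a, k] == 0:
            a = int(np.argmax(np.abs(out.x_loadings[:, k])))
        if out.x_loadings[a, k] < 0:
            _flip(out, "x", k)
        xy = out.x_scores[:, k] @ out.y_scores[:, k]
        if xy < 0:
            _flip(out, "y", k)
    return out


def _flip(res: CCAResult, side: str, k: int) -> None:
    for attr in (f"{side}_weights", f"{side}_loadings", f"{side}_scores"):
        getattr(res, attr)[:, k] *= -1.0


def project(result: CCAResult, X_new, Y_new) -> tuple[np.ndarray, np.ndarray]:
    """Apply training centering and weights to new data.

    Projected scores are deliberately not re-standardized, so shrinkage of
    the canonical correlation on held-out data remains measurable.
    """
    Xm, x_names = _as_matrix(X_new)
    Ym, y_names = _as_matrix(Y_new)
    if isinstance(X_new, pd.DataFrame) and list(x_names) != list(result.x_names):
        raise ValueError("X_new columns do not match the training X block")
    if isinstance(Y_new, pd.DataFrame) and list(y_names) != list(result.y_names):
        raise ValueError("Y_new columns do not match the training Y block")
    if Xm.shape[1] != result.p or Ym.shape[1] != result.q:
        raise ValueError("new blocks have wrong width")
    if np.isnan(Xm).any() or np.isnan(Ym).any():
        raise ValueError("projection requires complete data")
    return (Xm - result.x_mean) @ result.x_weights, (Ym - result.y_mean) @ result.y_weights
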