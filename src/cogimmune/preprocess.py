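"""Preprocessing: complete-case filtering, z-scoring, IQR fencing, PMM imputation.

The marker pipeline mirrors a standard clinical-biomarker workflow:
standardize, replace cells beyond the 1.5×IQR fences with missing, then
impute by chained equations with predictive mean matching (m = 5 completed
tables).  Standardization is applied once, before fencing, so the fences
are not silently moved by later steps; the fence rule is applied once, not
iteratively.  Cognitive columns only pass through the complete-case filter
and z-scoring — never the fence/imputation path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessReport",
    "complete_case_filter",
    "zscore_columns",
    "iqr_outlier_to_missing",
    "mice_pmm_impute",
    "preprocess_cohort",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    n_dropped_complete_case: int = 0
    outliers_flagged: dict = field(default_factory=dict)
    missing_before: dict = field(default_factory=dict)
    missing_after: dict = field(default_factory=dict)
    imputation_m: int = 5
    pooled_strategy: str = "cellwise_mean"

    def to_dict(self) -> dict:
        return {
            "n_dropped_complete_case": self.n_dropped_complete_case,
            "outliers_flagged": self.outliers_flagged,
            "missing_before": self.missing_before,
            "missing_after": self.missing_after,
            "imputation_m": self.imputation_m,
            "pooled_strategy": self.pooled_strategy,
        }


def complete_case_filter(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Drop rows with any missing value in ``columns``; other missingness stays."""
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    keep = table[columns].notna().all(axis=1)
    if not keep.any():
        raise ValueError("complete-case filter dropped every row")
    return table.loc[keep].reset_index(drop=True)


def zscore_columns(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Standardize each column to mean 0, sample SD 1 over non-missing entries."""
    out = table.copy()
    for c in columns:
        vals = out[c]
        nonmiss = vals.dropna()
        if len(nonmiss) < 2:
            raise ValueError(f"column {c!r} has fewer than 2 non-missing values")
        sd = nonmiss.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {c!r} has zero variance; cannot z-score")
        out[c] = (vals - nonmiss.mean()) / sd
    return out


def iqr_outlier_to_missing(
    table: pd.DataFrame, columns: list[str], k: float = 1.5
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Set cells beyond ``k``×IQR fences to missing; return per-column counts.

    Quartiles use linear interpolation between order statistics (R type-7 /
    numpy default).  The fence boundary itself is inside: a constant column
    (IQR = 0) flags nothing.
    """
    if k <= 0:
        raise ValueError("fence multiplier k must be positive")
    out = table.copy()
    counts: dict[str, int] = {}
    for c in columns:
        vals = out[c].to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size == 0:
            counts[c] = 0
            continue
        q1, q3 = np.quantile(obs, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        flag = (vals < lo) | (vals > hi)
        flag &= ~np.isnan(vals)
        counts[c] = int(flag.sum())
        vals[flag] = np.nan
        out[c] = vals
    return out, counts


def mice_pmm_impute(
    table: pd.DataFrame,
    columns: list[str],
    m: int = 5,
    n_iter: int = 10,
    n_donors: int = 5,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Multiple imputation by chained equations with predictive mean matching.

    For each of ``m`` imputations: initialize missing cells with random
    draws from the observed values of their column, then cycle ``n_iter``
    times over the incomplete columns, regressing each on all other columns
    (ordinary least squares among rows observed for the target) and
    replacing each missing cell with the observed value of one of the
    ``n_donors`` rows whose predictions are closest (donor chosen at
    random).  Imputed values therefore always come from the observed
    support of their column.

    Returns the ``m`` completed tables and the pooled table (cell-wise mean
    of the completed values) whose non-imputed cells equal the input.
    """
    sub = table[columns]
    frac = sub.isna().mean()
    if (frac == 1.0).any():
        fully = list(frac.index[frac == 1.0])
        raise ValueError(f"column(s) with 100% missingness cannot be imputed: {fully}")
    if (frac > 0.15).any():
        logger.warning(
            "columns exceed 15%% missingness: %s",
            list(frac.index[frac > 0.15]),
        )
    data = sub.to_numpy(dtype=float)
    miss_mask = np.isnan(data)
    if not miss_mask.any():
        pooled = table.copy()
        return [table.copy() for _ in range(m)], pooled

    rng = np.random.default_rng(seed)
    completed_arrays = []
    for _ in range(m):
        completed_arrays.append(
            _chained_pmm_once(data, miss_mask, n_iter, n_donors, rng)
        )

    completed_tables = []
    for arr in completed_arrays:
        t = table.copy()
        t[columns] = arr
        completed_tables.append(t)
    pooled = table.copy()
    pooled[columns] = np.mean(completed_arrays, axis=0)
    return completed_tables, pooled


def _chained_pmm_once(data, miss_mask, n_iter, n_donors, rng) -> np.ndarray:
    work = data.copy()
    n, p = work.shape
    # initialize holes with random observed draws
    for j in range(p):
        holes = miss_mask[:, j]
        if holes.any():
            obs = data[~miss_mask[:, j], j]
            work[holes, j] = rng.choice(obs, size=holes.sum(), replace=True)
    incomplete = [j for j in range(p) if miss_mask[:, j].any()]
    for _ in range(n_iter):
        for j in incomplete:
            obs_rows = ~miss_mask[:, j]
            mis_rows = miss_mask[:, j]
            predictors = np.delete(work, j, axis=1)
            A = np.column_stack([np.ones(n), predictors])
            coef, _, rank, _ = np.linalg.lstsq(A[obs_rows], work[obs_rows, j], rcond=None)
            if rank < A.shape[1]:
                logger.info("singular regression for column %d; prediction uses pseudoinverse", j)
            pred = A @ coef
            if not np.all(np.isfinite(pred)):
                # fall back to column-mean prediction
                logger.warning("non-finite predictions for column %d; using column mean", j)
                pred = np.full(n, work[obs_rows, j].mean())
            obs_pred = pred[obs_rows]
            obs_vals = work[obs_rows, j]
            for i in np.where(mis_rows)[0]:
                d = np.abs(obs_pred - pred[i])
                k = min(n_donors, d.size)
                donors = np.argpartition(d, k - 1)[:k]
                work[i, j] = obs_vals[donors[rng.integers(0, k)]]
    return work


def preprocess_cohort(
    table: pd.DataFrame,
    cognitive_columns: list[str],
    marker_columns: list[str],
    m: int = 5,
    n_iter: int = 10,
    n_donors: int = 5,
    fence_k: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full preprocessing: complete-case → z-score → fence → impute (pooled).

    Returns the pooled analysis table (both blocks complete and
    standardized) and a :class:`PreprocessReport`.
    """
    report = PreprocessReport(imputation_m=m)
    n0 = len(table)
    table = complete_case_filter(table, cognitive_columns)
    report.n_dropped_complete_case = n0 - len(table)

    table = zscore_columns(table, cognitive_columns)
    table = zscore_columns(table, marker_columns)
    table, counts = iqr_outlier_to_missing(table, marker_columns, k=fence_k)
    report.outliers_flagged = counts
    report.missing_before = table[marker_columns].isna().mean().round(6).to_dict()

    _, pooled = mice_pmm_impute(
        table, marker_columns, m=m, n_iter=n_iter, n_donors=n_donors, seed=seed
    )
    report.missing_after = pooled[marker_columns].isna().mean().round(6).to_dict()
    return pooled, report
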