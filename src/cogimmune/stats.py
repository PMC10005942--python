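"""Permutation-based group comparisons and covariate-adjusted score models.

Continuous variables are compared with permutation t-tests (Welch statistic,
label-shuffle null, add-one p) or permutation one-way ANOVA; categorical
variables with Pearson chi-squared tests.  Confidence intervals for mean
differences are Monte-Carlo percentile intervals from a within-group
bootstrap (a label-permutation distribution is centered at zero and cannot
interval-estimate the difference itself).  Multiplicity control is
Bonferroni with configurable family sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "AdjustedModelResult",
    "permutation_t_test",
    "permutation_anova",
    "chi_square_test",
    "bonferroni",
    "adjusted_score_model",
    "cluster_profile_compare",
]


@dataclass
class GroupTestResult:
    statistic: float
    p_perm: float
    n_perm: int
    ci95: tuple[float, float] | None = None
    p_adjusted: float | None = None
    comparison: str = ""


@dataclass
class AdjustedModelResult:
    model: str                 # "cognitive" or "immune"
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    covariates: list[str] = None


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / a.size + vb / b.size)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def permutation_t_test(
    x_a, x_b, n_perm: int = 10_000, seed: int = 0, n_boot: int | None = None,
    exact: bool = False,
) -> GroupTestResult:
    """Two-sided Welch t-test with a label-shuffle null.

    ``exact=True`` enumerates every label split instead of sampling (small
    samples only).  The bootstrap percentile CI resamples within each group
    (``n_boot`` defaults to ``n_perm`` draws).
    """
    a = np.asarray(pd.Series(x_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(x_b).dropna(), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    t_obs = _welch_t(a, b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return GroupTestResult(0.0, 1.0, n_perm, (0.0, 0.0))
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na = a.size
    exceed = 0
    if exact:
        from itertools import combinations

        from math import comb

        n_perm = comb(pooled.size, na)
        if n_perm > 200_000:
            raise ValueError("too many splits for exact enumeration")
        idx = np.arange(pooled.size)
        for chosen in combinations(idx, na):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(chosen)] = True
            if abs(_welch_t(pooled[mask], pooled[~mask])) >= abs(t_obs) - 1e-12:
                exceed += 1
    else:
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(_welch_t(perm[:na], perm[na:])) >= abs(t_obs):
                exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    n_boot = n_perm if n_boot is None else n_boot
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        diffs[i] = (
            rng.choice(a, a.size, replace=True).mean()
            - rng.choice(b, b.size, replace=True).mean()
        )
    ci = tuple(np.percentile(diffs, [2.5, 97.5]))
    return GroupTestResult(t_obs, float(p), n_perm, ci)


def _f_stat(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        sub = values[codes == g]
        ss_between += sub.size * (sub.mean() - grand) ** 2
        ss_within += ((sub - sub.mean()) ** 2).sum()
    df1 = n_groups - 1
    df2 = values.size - n_groups
    if ss_within == 0:
        return 0.0 if ss_between == 0 else np.inf
    return float((ss_between / df1) / (ss_within / df2))


def permutation_anova(values, groups, n_perm: int = 10_000, seed: int = 0) -> GroupTestResult:
    """One-way ANOVA F statistic with a label-shuffle null."""
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    codes, uniq = pd.factorize(df["g"])
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 values")
    v = df["v"].to_numpy(dtype=float)
    f_obs = _f_stat(v, codes, len(uniq))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if _f_stat(v, rng.permutation(codes), len(uniq)) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return GroupTestResult(f_obs, float(p), n_perm)


def chi_square_test(table, correction: bool = False) -> GroupTestResult:
    """Pearson chi-squared test of independence on a 2-way count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=correction)
    return GroupTestResult(float(stat), float(p), 0)


def bonferroni(p_values, m_tests: int | None = None):
    """Bonferroni adjustment: min(1, p·m).  Monotone, capped at 1."""
    arr = np.atleast_1d(np.asarray(p_values, dtype=float))
    m = len(arr) if m_tests is None else m_tests
    if m < 1:
        raise ValueError("m_tests must be >= 1")
    adj = np.minimum(1.0, arr * m)
    return float(adj[0]) if np.isscalar(p_values) or np.ndim(p_values) == 0 else adj


# default Bonferroni family sizes: 5 sample-characteristic tests and
# 15 clinical-characteristic tests
FAMILY_SAMPLE = 5
FAMILY_CLINICAL = 15


def adjusted_score_model(
    scores,
    diagnosis,
    covariates: pd.DataFrame,
    model: str = "cognitive",
) -> AdjustedModelResult:
    """OLS of a mode-1 variate score on diagnosis plus covariates.

    Diagnosis enters as BD/SZ indicators with HC as reference; sex as a
    male indicator.  The cognitive model adjusts for age, sex and the four
    medication DDD columns; the immune model additionally for CRP, BMI and
    freezer storage time.
    """
    base_covs = ["age", "sex", "ddd_antipsychotics", "ddd_antidepressants",
                 "ddd_antiepileptics", "ddd_lithium"]
    if model == "cognitive":
        covs = base_covs
    elif model == "immune":
        covs = base_covs + ["crp", "bmi", "freezer_time"]
    else:
        raise ValueError("model must be 'cognitive' or 'immune'")
    X = pd.DataFrame(index=pd.RangeIndex(len(scores)))
    diagnosis = pd.Series(np.asarray(diagnosis), name="diagnosis")
    X["BD"] = (diagnosis == "BD").astype(float)
    X["SZ"] = (diagnosis == "SZ").astype(float)
    cov = covariates.reset_index(drop=True)
    for c in covs:
        if c == "sex":
            X["sex_male"] = (cov["sex"] == "m").astype(float)
        else:
            X[c] = cov[c].astype(float)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(np.asarray(scores, dtype=float), X, missing="raise").fit()
    return AdjustedModelResult(
        model=model, params=fit.params, bse=fit.bse,
        tvalues=fit.tvalues, pvalues=fit.pvalues, covariates=covs,
    )


def cluster_profile_compare(
    table: pd.DataFrame,
    labels,
    marker_columns: list[str],
    cognitive_columns: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise cluster-1 vs cluster-2 comparisons in the subgroup-table layout.

    Markers and cognitive domains are compared on all rows (their own
    Bonferroni family), demographics on all rows (family of 5, sex by
    chi-squared), clinical variables on SMI rows only (family of 15).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 cluster labels, got {list(uniq)}")
    for lab in uniq:
        if (labels == lab).sum() < 2:
            raise ValueError(f"cluster {lab} has fewer than 2 members")
    in1 = labels == uniq[0]
    is_smi = table["group"].isin(["SZ", "BD"]).to_numpy()

    demographic = ["age", "education", "iq", "bmi", "crp"]
    clinical = [
        "panss_negative", "panss_positive", "panss_disorganized",
        "panss_excited", "panss_depressed", "ymrs", "gaf_s", "gaf_f",
        "age_at_onset", "duration_of_illness",
        "ddd_antipsychotics", "ddd_antidepressants", "ddd_antiepileptics",
        "ddd_lithium",
    ]
    clinical = [c for c in clinical if c in table.columns]

    rows = []
    rng = np.random.default_rng(seed)

    def compare(var, mask, family):
        a = table.loc[mask & in1, var]
        b = table.loc[mask & ~in1, var]
        res = permutation_t_test(a, b, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rows.append({
            "variable": var, "family": family,
            "mean_1": a.mean(), "sd_1": a.std(ddof=1),
            "mean_2": b.mean(), "sd_2": b.std(ddof=1),
            "statistic": res.statistic, "p_perm": res.p_perm,
            "ci_low": res.ci95[0], "ci_high": res.ci95[1],
        })

    all_rows = np.ones(len(table), dtype=bool)
    feature_family = cognitive_columns + [c for c in marker_columns if c in table.columns]
    for var in feature_family:
        compare(var, all_rows, "features")
    for var in demographic:
        if var in table.columns:
            compare(var, all_rows, "sample")
    for var in clinical:
        compare(var, is_smi, "clinical")

    out = pd.DataFrame(rows)
    fam_sizes = {"features": len(feature_family), "sample": FAMILY_SAMPLE,
                 "clinical": FAMILY_CLINICAL}
    out["p_adjusted"] = [
        bonferroni(p, fam_sizes[f]) for p, f in zip(out["p_perm"], out["family"])
    ]

    if "sex" in table.columns:
        counts = pd.crosstab(table["sex"], in1)
        chi = chi_square_test(counts.to_numpy())
        out = pd.concat([out, pd.DataFrame([{
            "variable": "sex", "family": "sample",
            "statistic": chi.statistic, "p_perm": chi.p_perm,
            "p_adjusted": bonferroni(chi.p_perm, FAMILY_SAMPLE),
        }])], ignore_index=True)
    return out
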