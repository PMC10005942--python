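import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogimmune.preprocess import (
    complete_case_filter,
    iqr_outlier_to_missing,
    mice_pmm_impute,
    preprocess_cohort,
    zscore_columns,
)
from cogimmune.synthetic import COGNITIVE_DOMAINS, MARKERS, generate_cohort

from conftest import small_config


class TestCompleteCase:
    def test_identity_when_complete(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = complete_case_filter(df, ["a", "b"])
        pd.testing.assert_frame_equal(out, df)

    def test_drops_rows_with_missing_cognitive(self):
        df = pd.DataFrame({"attention": [1.0, np.nan, 3.0], "other": [1, 2, 3]})
        out = complete_case_filter(df, ["attention"])
        assert len(out) == 2

    def test_all_dropped_is_error(self):
        df = pd.DataFrame({"a": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="every row"):
            complete_case_filter(df, ["a"])

    def test_generator_cognitive_block_passes_untouched(self, small_cohort):
        out = complete_case_filter(small_cohort, COGNITIVE_DOMAINS)
        assert len(out) == len(small_cohort)


class TestZScore:
    def test_symmetric_three_values(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = zscore_columns(df, ["a"])
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])

    def test_hand_computed_sample_sd(self):
        vals = [2.0, 4.0, 4.0, 4.0, 5.0, 5.0, 7.0, 9.0]
        out = zscore_columns(pd.DataFrame({"a": vals}), ["a"])
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["a"].std(ddof=1) == pytest.approx(1.0)
        sd = np.std(vals, ddof=1)  # 2.138...
        assert out["a"].iloc[0] == pytest.approx((2.0 - 5.0) / sd)

    def test_idempotent(self):
        df = pd.DataFrame({"a": np.random.default_rng(0).normal(size=50)})
        once = zscore_columns(df, ["a"])
        twice = zscore_columns(once, ["a"])
        np.testing.assert_allclose(once["a"], twice["a"], atol=1e-12)

    def test_missing_cells_stay_missing(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0, 5.0]})
        out = zscore_columns(df, ["a"])
        assert out["a"].isna().sum() == 1

    def test_zero_variance_error_names_column(self):
        with pytest.raises(ValueError, match="myvar"):
            zscore_columns(pd.DataFrame({"myvar": [2.0, 2.0, 2.0]}), ["myvar"])


class TestIQRFence:
    def test_hand_computed_fences(self):
        col = list(range(1, 10)) + [100]
        out, counts = iqr_outlier_to_missing(pd.DataFrame({"a": col}), ["a"])
        # Q1 = 3.25, Q3 = 7.75, IQR = 4.5 -> upper fence 14.5
        assert counts["a"] == 1
        assert out["a"].isna().sum() == 1
        assert np.isnan(out["a"].iloc[-1])

    def test_constant_column_flags_nothing(self):
        out, counts = iqr_outlier_to_missing(pd.DataFrame({"a": [5.0] * 10}), ["a"])
        assert counts["a"] == 0
        assert out["a"].notna().all()

    def test_fence_boundary_is_inside(self):
        # value exactly at the fence must not be flagged
        col = [1.0, 2.0, 3.0, 4.0]
        q1, q3 = np.quantile(col, [0.25, 0.75])
        fence = q3 + 1.5 * (q3 - q1)
        out, counts = iqr_outlier_to_missing(pd.DataFrame({"a": col + [fence]}), ["a"])
        assert counts["a"] == 0

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            iqr_outlier_to_missing(pd.DataFrame({"a": [1.0, 2.0]}), ["a"], k=0)

    def test_injected_outliers_are_flagged(self):
        # every injected cell must trip the rule; genuinely Gaussian tails
        # add a small extra fraction (~0.7% per column for normal data)
        cfg = small_config(seed=3, missing_rate=0.0, outlier_rate=0.02)
        table = generate_cohort(cfg)
        n_cells = len(table) * len(MARKERS)
        clean_cfg = small_config(seed=3, missing_rate=0.0, outlier_rate=0.0)
        clean = generate_cohort(clean_cfg)
        injected = int((table[MARKERS].to_numpy() != clean[MARKERS].to_numpy()).sum())
        _, counts = iqr_outlier_to_missing(table, MARKERS)
        flagged = sum(counts.values())
        assert flagged >= 0.9 * injected
        natural = 0.007 * n_cells
        assert flagged <= injected + 3 * natural


class TestMicePMM:
    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        tables, pooled = mice_pmm_impute(df, ["a", "b"], m=3, seed=0)
        assert len(tables) == 3
        for t in tables:
            pd.testing.assert_frame_equal(t, df)
        pd.testing.assert_frame_equal(pooled, df)

    def test_perfectly_correlated_columns_recover_truth(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.normal(size=200))
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        truth = df["b"].copy()
        holes = rng.random(200) < 0.1
        df.loc[holes, "b"] = np.nan
        _, pooled = mice_pmm_impute(df, ["a", "b"], m=5, seed=2)
        # with corr 1 the prediction equals truth; PMM error bounded by
        # local donor spacing
        spacing = np.diff(np.sort(truth)).max() * 5
        err = (pooled.loc[holes, "b"] - truth[holes]).abs()
        assert (err <= spacing).all()

    def test_imputed_values_come_from_observed_support(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        mask = rng.random(100) < 0.12
        truth_obs = df.loc[~mask, "a"]
        df.loc[mask, "a"] = np.nan
        tables, _ = mice_pmm_impute(df, list("abc"), m=4, seed=4)
        observed = set(np.round(truth_obs, 12))
        for t in tables:
            imputed = np.round(t.loc[mask, "a"], 12)
            assert set(imputed) <= observed

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0], "c": [2.0, 1.0]})
        with pytest.raises(ValueError, match="100%"):
            mice_pmm_impute(df, ["a", "b", "c"])

    def test_mcar_pooled_means_unbiased(self):
        # pooled marker means stay within 0.1 SD of the pre-masking means
        deltas = []
        for seed in range(3):
            cfg = small_config(seed=seed, missing_rate=0.10, outlier_rate=0.0)
            masked = generate_cohort(cfg)
            full = generate_cohort(
                small_config(seed=seed, missing_rate=0.0, outlier_rate=0.0))
            _, pooled = mice_pmm_impute(masked, MARKERS, m=5, seed=seed + 50)
            d = (pooled[MARKERS].mean() - full[MARKERS].mean()) / full[MARKERS].std()
            deltas.append(d.abs().max())
        assert np.mean(deltas) < 0.12

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        df.loc[rng.random(60) < 0.15, "b"] = np.nan
        _, p1 = mice_pmm_impute(df, list("abc"), m=3, seed=9)
        _, p2 = mice_pmm_impute(df, list("abc"), m=3, seed=9)
        pd.testing.assert_frame_equal(p1, p2)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40, unique=True))
def test_zscore_always_unit_sample_sd(values):
    out = zscore_columns(pd.DataFrame({"a": values}), ["a"])
    assert out["a"].mean() == pytest.approx(0.0, abs=1e-6)
    assert out["a"].std(ddof=1) == pytest.approx(1.0, rel=1e-6)


def test_full_preprocess_leaves_blocks_complete(small_cohort):
    clean, report = preprocess_cohort(small_cohort, COGNITIVE_DOMAINS, MARKERS, seed=0)
    assert clean[MARKERS].notna().all().all()
    assert clean[COGNITIVE_DOMAINS].notna().all().all()
    assert all(v == 0.0 for v in report.missing_after.values())
    assert report.n_dropped_complete_case == 0
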