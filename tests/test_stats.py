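import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cogimmune.stats import (
    adjusted_score_model,
    bonferroni,
    chi_square_test,
    cluster_profile_compare,
    permutation_anova,
    permutation_t_test,
)
from cogimmune.synthetic import COGNITIVE_DOMAINS, MARKERS, generate_cohort

from conftest import small_config


class TestPermutationTTest:
    def test_identical_groups_p_one(self):
        a = [1.0, 2.0, 3.0]
        res = permutation_t_test(a, a, n_perm=200, seed=0)
        assert res.statistic == 0.0
        assert res.p_perm == 1.0

    def test_exhaustive_enumeration_example(self):
        # only the observed split and its mirror reach |t|max among C(6,3)
        res = permutation_t_test([1, 2, 3], [101, 102, 103], exact=True)
        assert res.p_perm == pytest.approx(3 / 21, abs=1e-12)

    def test_power_at_planted_shift(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_mc = 50
        for i in range(n_mc):
            a = rng.normal(size=200)
            b = rng.normal(loc=0.8, size=200)
            res = permutation_t_test(a, b, n_perm=199, seed=i, n_boot=10)
            hits += res.p_perm <= 0.05
        assert hits >= 0.99 * n_mc

    def test_agrees_with_welch_p_on_gaussian_data(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=500)
        b = rng.normal(loc=0.12, size=500)
        res = permutation_t_test(a, b, n_perm=10_000, seed=3, n_boot=100)
        welch_p = sps.ttest_ind(a, b, equal_var=False).pvalue
        assert res.p_perm == pytest.approx(welch_p, abs=0.01)

    def test_ci_covers_true_difference(self):
        rng = np.random.default_rng(4)
        a = rng.normal(loc=1.0, size=300)
        b = rng.normal(loc=0.0, size=300)
        res = permutation_t_test(a, b, n_perm=200, seed=5, n_boot=2000)
        assert res.ci95[0] <= 1.0 <= res.ci95[1] or abs(res.ci95[0] - 1.0) < 0.2
        assert res.ci95[0] < res.ci95[1]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_t_test([1.0], [2.0, 3.0])


class TestPermutationAnova:
    def test_identical_groups_f_zero_p_one(self):
        v = [1.0, 2.0, 3.0] * 3
        g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permutation_anova(v, g, n_perm=100, seed=0)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_perm == 1.0

    def test_two_groups_agrees_with_t_test(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=40)
        b = rng.normal(loc=0.5, size=40)
        t_res = permutation_t_test(a, b, n_perm=2000, seed=7, n_boot=10)
        f_res = permutation_anova(
            np.concatenate([a, b]), ["a"] * 40 + ["b"] * 40, n_perm=2000, seed=8)
        assert f_res.statistic == pytest.approx(t_res.statistic**2, rel=1e-9)
        assert f_res.p_perm == pytest.approx(t_res.p_perm, abs=0.03)

    def test_group_ordering_from_planted_age_means(self):
        # age means follow the demographic table: SZ youngest, HC ~ BD
        table = generate_cohort(small_config(seed=10, n_per_group=(343, 289, 770),
                                             cluster_sizes=(625, 777),
                                             cluster_diag_counts={
                                                 "SZ": (264, 79), "BD": (160, 129),
                                                 "HC": (201, 569)}))
        res = permutation_anova(table["age"], table["group"], n_perm=500, seed=11)
        assert res.p_perm < 0.05
        means = table.groupby("group")["age"].mean()
        assert means["SZ"] < means["BD"] and means["SZ"] < means["HC"]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_anova([1.0, 2.0], ["a", "a"], n_perm=10)


class TestChiSquare:
    def test_independence_gives_zero(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_perm == pytest.approx(1.0)

    def test_perfect_association_hand_computed(self):
        res = chi_square_test([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)

    def test_sex_by_diagnosis_at_printed_counts(self):
        res = chi_square_test([[188, 155], [114, 175], [423, 347]])
        assert res.p_perm < 0.001

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_test([[0, 0], [5, 5]])


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [
        (0.01, 5, 0.05), (0.5, 15, 1.0), (0.003, 15, 0.045)])
    def test_values(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 50))
    def test_monotone_and_capped(self, p1, p2, m):
        a1, a2 = bonferroni(p1, m), bonferroni(p2, m)
        if p1 <= p2:
            assert a1 <= a2
        assert 0 <= a1 <= 1


class TestAdjustedScoreModel:
    def _cohort(self, seed=12):
        return generate_cohort(small_config(seed=seed))

    def test_exact_linear_recovery(self):
        table = self._cohort()
        scores = 2.0 * table["age"].to_numpy()
        res = adjusted_score_model(scores, table["group"], table, model="cognitive")
        assert res.params["age"] == pytest.approx(2.0, abs=1e-8)
        assert res.params["SZ"] == pytest.approx(0.0, abs=1e-8)
        assert res.params["BD"] == pytest.approx(0.0, abs=1e-8)

    def test_null_effects_covered(self):
        # no group effect planted in the scores: estimates within +-2 SE most
        # of the time
        rng = np.random.default_rng(13)
        table = self._cohort()
        inside = 0
        n_mc = 100
        for _ in range(n_mc):
            scores = rng.normal(size=len(table))
            res = adjusted_score_model(scores, table["group"], table, model="immune")
            ok = all(abs(res.params[g]) <= 2 * res.bse[g] for g in ("SZ", "BD"))
            inside += ok
        assert inside >= 0.88 * n_mc

    def test_diagnosis_ordering_on_planted_cohort(self, study_runs):
        """SZ scores more negative than BD, both below HC (cognitive model)."""
        run = study_runs[0]
        clean = run["clean"]
        res = adjusted_score_model(
            run["result"].x_scores[:, 0], clean["group"], clean, model="cognitive")
        assert res.params["SZ"] < res.params["BD"] < 0
        assert res.tvalues["SZ"] < -2

    def test_unknown_model_rejected(self):
        table = self._cohort()
        with pytest.raises(ValueError):
            adjusted_score_model(np.zeros(len(table)), table["group"], table, model="x")


class TestClusterProfile:
    def test_identical_labels_rejected(self, small_cohort):
        labels = np.ones(len(small_cohort), dtype=int)
        with pytest.raises(ValueError, match="2 cluster labels"):
            cluster_profile_compare(small_cohort, labels, MARKERS, COGNITIVE_DOMAINS)

    def test_planted_contrast_recovered(self, study_runs):
        """Cluster 1 is low on verbal learning/psychomotor speed, high on
        IL-18 system markers and BD-2, low on VCAM-1."""
        from cogimmune.cluster import cut_tree_labels, linkage_tree, order_labels_by_score

        run = study_runs[0]
        pts = run["points"]
        labels = order_labels_by_score(
            pts, cut_tree_labels(linkage_tree(pts, "ward"), 2))
        # n_perm = 1000 puts the attainable adjusted-p floor (Bonferroni
        # family of 33 features) at 33/1001 = 0.033, below the threshold
        prof = cluster_profile_compare(
            run["clean"], labels, MARKERS, COGNITIVE_DOMAINS,
            n_perm=1000, seed=14).set_index("variable")
        for var in ("verbal_learning", "psychomotor_processing_speed"):
            assert prof.loc[var, "mean_1"] < prof.loc[var, "mean_2"]
            assert prof.loc[var, "p_adjusted"] < 0.05
        for var in ("IL-18", "IL-18BP", "BD-2"):
            assert prof.loc[var, "mean_1"] > prof.loc[var, "mean_2"]
            assert prof.loc[var, "p_adjusted"] < 0.05
        assert prof.loc["VCAM-1", "mean_1"] < prof.loc["VCAM-1", "mean_2"]

    def test_null_separation_calibrated(self):
        # separation 0: planted clusters coincide; adjusted significance rare
        table = generate_cohort(small_config(seed=15, separation=0.0))
        rng = np.random.default_rng(16)
        labels = rng.integers(1, 3, size=len(table))
        while len(np.unique(labels)) < 2:
            labels = rng.integers(1, 3, size=len(table))
        prof = cluster_profile_compare(
            table.dropna(subset=MARKERS).reset_index(drop=True),
            labels[table[MARKERS].notna().all(axis=1).to_numpy()],
            MARKERS, COGNITIVE_DOMAINS, n_perm=200, seed=17)
        frac = (prof["p_adjusted"].dropna() < 0.05).mean()
        assert frac <= 0.1
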