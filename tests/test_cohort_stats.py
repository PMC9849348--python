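"""Cohort statistics: group tests, regression, clustering, survival."""

import numpy as np
import pandas as pd
import pytest

from pmihub.cohort_stats import (
    adjusted_regression,
    cluster_markers,
    group_difference_tests,
    marker_correlations,
    split_at_median_survival,
    survival_compare,
)
from pmihub.markers import MARKER_NAMES


def _cohort(n=40, seed=0, group_effect=0.0, group_col="grp"):
    """Synthetic marker table with optional group effect on every marker."""
    rng = np.random.default_rng(seed)
    g = np.repeat([0, 1], n // 2)
    df = pd.DataFrame({m: rng.normal(size=n) for m in MARKER_NAMES})
    for m in MARKER_NAMES:
        df[m] += group_effect * g
    df[group_col] = np.where(g == 0, "A", "B")
    df["age_years"] = rng.uniform(40, 80, n)
    df["sex"] = rng.choice(["M", "F"], n)
    df["survival_months"] = rng.exponential(12, n)
    df["event"] = 1
    df["subject_id"] = [f"s{i}" for i in range(n)]
    return df


class TestMedianSplit:
    def test_even_unique_times_split_in_half(self):
        t = pd.DataFrame({"survival_months": np.arange(1.0, 11.0)})
        out = split_at_median_survival(t)
        assert (out["survival_group"] == "short").sum() == 5
        assert (out["survival_group"] == "long").sum() == 5

    def test_median_subject_goes_to_short_group(self):
        times = np.array([3.0, 1.0, 5.0, 9.0, 7.0])  # median 5
        out = split_at_median_survival(pd.DataFrame({"survival_months": times}))
        # sorted-list oracle: times <= 5 are short
        expected = np.where(np.sort(times)[2] >= times, "short", "long")
        assert list(out["survival_group"]) == list(expected)

    def test_duplicated_cohort_gets_identical_labels(self):
        t = pd.DataFrame({"survival_months": [2.0, 4.0, 8.0]})
        t2 = pd.concat([t, t], ignore_index=True)
        out = split_at_median_survival(t2)
        assert list(out["survival_group"][:3]) == list(out["survival_group"][3:])

    def test_identical_times_is_hard_error(self):
        with pytest.raises(ValueError, match="identical"):
            split_at_median_survival(pd.DataFrame({"survival_months": [5.0, 5.0, 5.0]}))


class TestGroupTests:
    def test_identical_groups_give_null_statistics(self):
        half = _cohort(20, seed=1)
        dup = pd.concat([half, half], ignore_index=True)
        dup["grp"] = ["A"] * 20 + ["B"] * 20
        rep = group_difference_tests(dup, "grp", kind="t_test")
        assert np.allclose(rep.table["statistic"], 0.0, atol=1e-12)
        assert np.allclose(rep.table["p"], 1.0, atol=1e-12)

    def test_strong_shift_detected_by_t_test(self):
        t = _cohort(100, seed=2, group_effect=2.0)
        rep = group_difference_tests(t, "grp", kind="t_test")
        assert (rep.table["p"] < 0.001).all()

    def test_four_subject_t_matches_textbook_formula(self):
        t = pd.DataFrame({m: [0.0, 0.0, 0.0, 0.0] for m in MARKER_NAMES})
        t["n_hubs_norm"] = [1.0, 2.0, 4.0, 7.0]
        t["grp"] = ["A", "A", "B", "B"]
        rep = group_difference_tests(t, "grp", kind="t_test")
        row = rep.table.set_index("marker").loc["n_hubs_norm"]
        # hand arithmetic: means 1.5 / 5.5, pooled var = (0.5 + 4.5) / 2 = 2.5
        expected_t = (1.5 - 5.5) / np.sqrt(2.5 * (1 / 2 + 1 / 2))
        assert row["statistic"] == pytest.approx(expected_t, abs=1e-12)

    def test_ranksum_invariant_to_monotone_transform(self):
        t = _cohort(30, seed=3, group_effect=1.0)
        t2 = t.copy()
        for m in MARKER_NAMES:
            t2[m] = np.exp(t2[m])
        a = group_difference_tests(t, "grp", kind="ranksum").table
        b = group_difference_tests(t2, "grp", kind="ranksum").table
        np.testing.assert_allclose(a["statistic"], b["statistic"], atol=1e-12)

    def test_bonferroni_is_five_fold_capped(self):
        t = _cohort(30, seed=4, group_effect=0.5)
        rep = group_difference_tests(t, "grp")
        np.testing.assert_allclose(
            rep.table["p_adjusted"], np.minimum(1.0, 5.0 * rep.table["p"]), atol=1e-15
        )
        assert (rep.table["p_adjusted"] >= rep.table["p"]).all()

    def test_zero_variance_marker_flagged(self):
        t = _cohort(20, seed=5)
        t["shape_het"] = 0.5
        rep = group_difference_tests(t, "grp")
        row = rep.table.set_index("marker").loc["shape_het"]
        assert row["p"] == 1.0 and row["flag"] == "zero_variance"


class TestAdjustedRegression:
    def test_recovers_planted_group_effect(self):
        rng = np.random.default_rng(6)
        t = _cohort(200, seed=6)
        g = (t["grp"] == "B").astype(float)
        t["shape_het"] = 2.0 * g + 0.3 * rng.normal(size=len(t))
        rep = adjusted_regression(t, "grp").set_index("marker")
        assert rep.loc["shape_het", "coef"] == pytest.approx(2.0, abs=0.15)
        assert rep.loc["shape_het", "p"] < 1e-10

    def test_order_invariance(self):
        t = _cohort(50, seed=7, group_effect=0.5)
        a = adjusted_regression(t, "grp")
        b = adjusted_regression(t.sample(frac=1.0, random_state=1), "grp")
        np.testing.assert_allclose(a["coef"], b["coef"], atol=1e-10)

    def test_null_effect_p_values_are_uniform(self):
        # calibration: with no group effect the group p-value is U(0, 1)
        ps = []
        for seed in range(60):
            t = _cohort(40, seed=100 + seed)
            ps.append(adjusted_regression(t, "grp")["p"].iloc[0])
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_design_is_hard_error(self):
        t = _cohort(30, seed=8)
        t["sex"] = t["grp"].map({"A": "M", "B": "F"})  # sex == group
        with pytest.raises(ValueError, match="rank deficient"):
            adjusted_regression(t, "grp")


class TestClustering:
    @staticmethod
    def _blob_table(seed, n=60, sep=6.0):
        rng = np.random.default_rng(seed)
        g = np.repeat([0, 1], n // 2)
        data = rng.normal(size=(n, 5)) + sep * g[:, None]
        df = pd.DataFrame(data, columns=MARKER_NAMES)
        return df, g

    def test_recovers_planted_two_clusters(self):
        for seed in range(3):
            df, g = self._blob_table(seed)
            rep = cluster_markers(df, seed=seed)
            assert rep.chosen_k == 2
            acc = max(np.mean(rep.labels_k2 == g), np.mean(rep.labels_k2 != g))
            assert acc >= 0.95

    def test_k_range_default_scans_one_to_nine(self):
        df, _ = self._blob_table(0, n=40)
        rep = cluster_markers(df, seed=0)
        assert set(rep.ch_scores) == set(range(1, 10))

    def test_single_blob_has_weak_structure(self):
        df, _ = self._blob_table(1, sep=0.0)
        rep = cluster_markers(df, seed=0)
        assert rep.ch_ratio < 2.0  # no dominant k

    def test_two_cluster_naming_by_directional_heterogeneity(self):
        df, g = self._blob_table(2)
        rep = cluster_markers(df, seed=0)
        named = rep.named_labels()
        hi = df.loc[named == "high-PMI", "dir_het"].mean()
        lo = df.loc[named == "low-PMI", "dir_het"].mean()
        assert hi > lo

    def test_nan_markers_rejected(self):
        df, _ = self._blob_table(3)
        df.loc[0, "dir_het"] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cluster_markers(df)


class TestSurvival:
    @staticmethod
    def _surv_frame(n, hr, seed, censor_rate=0.3):
        rng = np.random.default_rng(seed)
        g = np.repeat([0, 1], n // 2)
        lam = (1 / 12.0) * np.where(g == 1, hr, 1.0)
        t_event = rng.exponential(1 / lam)
        mu = censor_rate / (1 - censor_rate) * lam.mean()
        t_cens = rng.exponential(1 / mu, size=n) if censor_rate > 0 else np.full(n, np.inf)
        return pd.DataFrame(
            {
                "survival_months": np.minimum(t_event, t_cens),
                "event": (t_event <= t_cens).astype(int),
                "grp": np.where(g == 1, "high", "low"),
            }
        )

    def test_identical_groups_give_unit_hazard_ratio(self):
        half = self._surv_frame(40, 1.0, 1).drop(columns="grp")
        dup = pd.concat([half, half], ignore_index=True)
        dup["grp"] = ["a"] * 40 + ["b"] * 40
        rep = survival_compare(dup, "grp")
        assert rep.hazard_ratio == pytest.approx(1.0, abs=1e-6)
        assert rep.logrank_statistic == pytest.approx(0.0, abs=1e-9)

    def test_km_curve_starts_at_one_and_never_increases(self):
        rep = survival_compare(self._surv_frame(60, 2.0, 2), "grp")
        for curve in rep.km_curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()

    def test_detects_planted_hazard_ratio(self):
        rep = survival_compare(self._surv_frame(300, 2.0, 3), "grp")
        # "high" sorts after "low"... levels sorted alphabetically
        hr = rep.hazard_ratio if rep.levels[1] == "high" else 1 / rep.hazard_ratio
        assert 1.5 < hr < 2.7
        assert rep.logrank_p < 0.001
        assert rep.hr_ci[0] < rep.hazard_ratio < rep.hr_ci[1]

    def test_no_events_is_hard_error(self):
        df = self._surv_frame(20, 1.0, 4)
        df["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            survival_compare(df, "grp")


class TestCorrelations:
    def test_self_r_squared_is_one(self):
        t = _cohort(30, seed=9)
        r, r2 = marker_correlations(t)
        np.testing.assert_allclose(np.diag(r2), 1.0, atol=1e-12)

    def test_exact_linear_pair_has_unit_correlation(self):
        t = _cohort(30, seed=10)
        t["dir_het"] = 2.0 * t["shape_het"]
        r, r2 = marker_correlations(t)
        assert r.loc["dir_het", "shape_het"] == pytest.approx(1.0, abs=1e-12)
        assert r2.loc["dir_het", "shape_het"] == pytest.approx(1.0, abs=1e-12)

    def test_independent_markers_nearly_uncorrelated(self):
        t = _cohort(200, seed=11)
        r, _ = marker_correlations(t)
        off = r.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.abs(off).mean() < 0.15

    def test_zero_variance_marker_flagged_nan(self):
        t = _cohort(30, seed=12)
        t["spatial_het"] = 1.0
        r, _ = marker_correlations(t)
        assert r.loc["spatial_het"].isna().all()
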