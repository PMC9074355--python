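import numpy as np
import pandas as pd
import pytest

import ki67flow as kf


def _df(times, events, **cols):
    df = pd.DataFrame({"time_years": times, "event": events})
    for k, v in cols.items():
        df[k] = v
    return df


class TestPearsonChi2:
    def test_independent_table_gives_zero(self):
        stat, df, p = kf.pearson_chi2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association_hand_value(self):
        stat, df, p = kf.pearson_chi2([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert df == 1

    def test_permutation_invariance(self):
        t = np.array([[5, 9, 2], [7, 1, 6]])
        s1, _, _ = kf.pearson_chi2(t)
        s2, _, _ = kf.pearson_chi2(t[::-1, ::-1])
        assert s1 == pytest.approx(s2)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            kf.pearson_chi2([[0, 0], [3, 4]])


class TestBlandAltman:
    def test_identity_has_zero_bias_and_sd(self):
        x = np.array([1.0, 5.0, 9.0])
        r = kf.bland_altman(x, x)
        assert r.bias == 0.0 and r.sd_diff == 0.0

    def test_constant_offset(self):
        x = np.array([10.0, 20.0, 30.0])
        r = kf.bland_altman(x, x + 5)
        assert r.bias == pytest.approx(5.0)
        assert r.sd_diff == pytest.approx(0.0)
        assert r.loa_low == pytest.approx(5.0)

    def test_proportional_bias_has_positive_slope(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(5, 60, 200)
        comp = ref * 1.2
        r = kf.bland_altman(ref, comp)
        assert r.slope_diff_on_mean > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kf.bland_altman([1, 2], [1, 2, 3])


class TestCumulativeIncidence:
    def test_hand_computed_three_subjects(self):
        df = _df([1.0, 2.0, 3.0], ["bc_death", "other_death", "censored"])
        cif_bc = kf.cumulative_incidence(df)[None]
        assert cif_bc.at(1.0) == pytest.approx(1 / 3)
        assert cif_bc.at(3.0) == pytest.approx(1 / 3)
        cif_other = kf.cumulative_incidence(
            df, event_of_interest="other_death")[None]
        assert cif_other.at(2.0) == pytest.approx(1 / 3)

    def test_no_events_gives_zero_curve(self):
        df = _df([1.0, 2.0, 3.0], ["censored"] * 3)
        cif = kf.cumulative_incidence(df)[None]
        assert cif.at(10.0) == 0.0

    def test_reduces_to_one_minus_km_without_competing_events(self):
        rng = np.random.default_rng(5)
        n = 200
        t = rng.exponential(5, n)
        cens = rng.uniform(0, 12, n)
        time = np.minimum(t, cens)
        event = np.where(t <= cens, "bc_death", "censored")
        df = _df(time, event)
        cif = kf.cumulative_incidence(df)[None]

        from lifelines import KaplanMeierFitter
        km = KaplanMeierFitter().fit(time, event == "bc_death")
        for tt in cif.times:
            assert cif.at(tt) == pytest.approx(
                1 - float(km.survival_function_at_times(tt).iloc[0]),
                abs=1e-12)

    def test_matches_lifelines_aalen_johansen(self, cohort_df):
        df = cohort_df
        cif = kf.cumulative_incidence(df)[None]
        from lifelines import AalenJohansenFitter
        codes = df["event"].map({"censored": 0, "bc_death": 1,
                                 "other_death": 2})
        aj = AalenJohansenFitter(calculate_variance=False, seed=0)
        aj.fit(df["time_years"], codes, event_of_interest=1)
        grid = [1.0, 2.0, 5.0, 10.0, 20.0]
        ours = [cif.at(t) for t in grid]
        theirs = [float(aj.cumulative_density_.loc[
            aj.cumulative_density_.index <= t].iloc[-1, 0]) for t in grid]
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_sum_of_cause_curves_bounded_by_one(self, cohort_df):
        bc = kf.cumulative_incidence(cohort_df)[None]
        other = kf.cumulative_incidence(
            cohort_df, event_of_interest="other_death")[None]
        for t in np.linspace(0, 30, 40):
            assert bc.at(t) + other.at(t) <= 1.0 + 1e-12
        assert np.all(np.diff(bc.cif) >= -1e-12)

    def test_empty_group_rejected(self):
        df = _df([1.0], ["bc_death"], g=["a"])
        with pytest.raises(ValueError):
            kf.cumulative_incidence(df[df["g"] == "b"])


class TestGrayTest:
    def test_identical_groups_not_rejected(self):
        rng = np.random.default_rng(7)
        n = 120
        t = rng.exponential(5, n)
        ev = rng.choice(["bc_death", "other_death", "censored"], n)
        base = _df(np.concatenate([t, t]), np.concatenate([ev, ev]),
                   g=["a"] * n + ["b"] * n)
        stat, df_, p = kf.gray_test(base, "g")
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_label_swap_invariance(self, cohort_df):
        df = cohort_df.copy()
        df["g"] = np.where(df["true_ki67"] > df["true_ki67"].median(),
                           "hi", "lo")
        s1, _, p1 = kf.gray_test(df, "g")
        df["g"] = np.where(df["g"] == "hi", "lo", "hi")
        s2, _, p2 = kf.gray_test(df, "g")
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_separated_hazards_rejected(self):
        rng = np.random.default_rng(8)
        n = 500
        lam = np.concatenate([np.full(n, 0.05), np.full(n, 0.15)])  # HR 3
        t_bc = rng.exponential(1 / lam)
        t_ot = rng.exponential(1 / 0.05, 2 * n)
        time = np.minimum(np.minimum(t_bc, t_ot), 25.0)
        event = np.where((t_bc <= t_ot) & (t_bc < 25), "bc_death",
                         np.where(t_ot < 25, "other_death", "censored"))
        df = _df(time, event, g=["lo"] * n + ["hi"] * n)
        stat, df_, p = kf.gray_test(df, "g")
        assert df_ == 1
        assert p < 0.01


def _grid_search_cox(time, event, x):
    """Brute-force partial-likelihood maximizer (no ties)."""
    time = np.asarray(time, float)
    x = np.asarray(x, float)
    event = np.asarray(event, bool)

    def neg_pl(beta):
        ll = 0.0
        for i in np.where(event)[0]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return -ll

    grid = np.arange(-4.0, 4.0, 1e-4)
    vals = [neg_pl(b) for b in grid]
    return grid[int(np.argmin(vals))]


class TestCoxPh:
    def test_matches_grid_search_oracle_on_four_subjects(self):
        df = _df([1.0, 2.0, 3.0, 4.0],
                 ["bc_death", "bc_death", "other_death", "bc_death"],
                 x=[1.0, 0.0, 1.0, 0.0])
        res = kf.cox_ph(df, ["x"])
        status = (df["event"] == "bc_death").to_numpy()
        oracle = _grid_search_cox(df["time_years"], status, df["x"])
        assert res.loc["x", "coef"] == pytest.approx(oracle, abs=1e-4)

    def test_matches_lifelines_on_simulated_cohort(self, cohort_df):
        df = cohort_df.copy()
        df["hi"] = (df["true_ki67"] > df["true_ki67"].median()).astype(float)
        res = kf.cox_ph(df, ["hi"])
        from lifelines import CoxPHFitter
        ll = df[["time_years", "hi"]].copy()
        ll["e"] = (df["event"] == "bc_death").astype(int)
        cph = CoxPHFitter().fit(ll, "time_years", "e")
        assert res.loc["hi", "coef"] == pytest.approx(
            float(cph.params_["hi"]), abs=1e-6)

    def test_known_log_hazard_ratio_recovered(self):
        rng = np.random.default_rng(9)
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        lam = 0.08 * np.exp(np.log(2.0) * x)
        t = rng.exponential(1 / lam)
        time = np.minimum(t, 20.0)
        event = np.where(t < 20, "bc_death", "censored")
        res = kf.cox_ph(_df(time, event, x=x), ["x"])
        # within sampling error of the true log-HR, and close in absolute
        # terms at this sample size
        assert abs(res.loc["x", "coef"] - np.log(2)) < 3 * res.loc["x", "se"]
        assert res.loc["x", "coef"] == pytest.approx(np.log(2), rel=0.15)

    def test_event_free_data_rejected(self):
        with pytest.raises(ValueError):
            kf.cox_ph(_df([1.0, 2.0], ["censored", "censored"],
                          x=[0.0, 1.0]), ["x"])


class TestHarrellC:
    def test_perfect_risk_ordering(self):
        df = _df([5.0, 4.0, 3.0, 2.0, 1.0], ["bc_death"] * 5)
        assert kf.harrell_c(df, [1, 2, 3, 4, 5]) == 1.0

    def test_constant_scores_give_half(self):
        df = _df([1.0, 2.0, 3.0, 4.0], ["bc_death"] * 4)
        assert kf.harrell_c(df, [7.0] * 4) == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(10)
        n = 1000
        t = rng.exponential(5, n)
        df = _df(t, ["bc_death"] * n)
        c = kf.harrell_c(df, rng.normal(size=n))
        sd = 1 / np.sqrt(12 * n)  # rough null scale
        assert abs(c - 0.5) < 5 * sd

    def test_no_events_rejected(self):
        df = _df([1.0, 2.0], ["censored", "censored"])
        with pytest.raises(ValueError):
            kf.harrell_c(df, [1.0, 2.0])


class TestBuildTable1:
    def test_single_category_cohort_fills_one_column(self):
        df = pd.DataFrame({"grade": [1, 2, 3, 2],
                           "cat": ["High"] * 4})
        tables, pvals = kf.build_table1(df, "cat", ["grade"])
        tab = tables["grade"]
        # percentages are within-column: the single category holds the
        # whole cohort, split across grades
        assert tab.loc[1, "High"] == "1 (25.0)"
        assert tab.loc[2, "High"] == "2 (50.0)"
        total = sum(int(tab.loc[g, "High"].split(" ")[0]) for g in (1, 2, 3))
        assert total == len(df)

    def test_reported_grade_distribution_percentages(self):
        """Re-entering the printed grade x category counts reproduces the
        printed within-column percentages to 0.1 pp."""
        rows = []
        counts = {("I", "Low"): 5, ("I", "Intermediate"): 11,
                  ("I", "High"): 0,
                  ("II", "Low"): 34, ("II", "Intermediate"): 67,
                  ("II", "High"): 30,
                  ("III", "Low"): 5, ("III", "Intermediate"): 26,
                  ("III", "High"): 70}
        for (g, c), n in counts.items():
            rows += [{"grade": g, "cat": c}] * n
        df = pd.DataFrame(rows)
        tables, pvals = kf.build_table1(df, "cat", ["grade"])
        tab = tables["grade"]
        assert tab.loc["III", "Low"] == "5 (11.4)"
        assert tab.loc["III", "Intermediate"] == "26 (25.0)"
        assert tab.loc["III", "High"] == "70 (70.0)"
        assert pvals["grade"] < 0.001

    def test_column_sums_equal_category_totals(self, cohort_df):
        df = cohort_df.copy()
        df["cat"] = pd.qcut(df["true_ki67"], 3,
                            labels=["Low", "Intermediate", "High"])
        tables, _ = kf.build_table1(df, "cat", ["grade"])
        tab = tables["grade"]
        for cat in ("Low", "Intermediate", "High"):
            total = sum(int(tab.loc[g, cat].split(" ")[0])
                        for g in tab.index)
            assert total == (df["cat"] == cat).sum()

    def test_mitoses_quartile_bins_partition(self, cohort_df):
        bins = kf.stats.mitoses_quartile_bins(cohort_df["mitoses_10hpf"])
        assert bins.notna().all()
        assert bins.nunique() == 4
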