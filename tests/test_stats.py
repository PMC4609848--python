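import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pdcest.stats import (
    anova_from_summary,
    anova_oneway,
    games_howell,
    levene,
    run_paper_analysis,
    summarize,
    ttest_from_summary,
    ttest_independent,
    tukey_hsd,
)

from _oracles import (
    anova_regression,
    games_howell_hand,
    levene_hand,
    permutation_ttest_pvalue,
)


class TestSummarize:
    def test_constant_samples_zero_halfwidth(self):
        s = summarize([3.0, 3.0, 3.0, 3.0])
        assert s.mean == 3.0 and s.ci95_halfwidth == 0.0

    def test_two_sample_closed_form(self):
        s = summarize([0.0, 2.0])
        assert s.mean == pytest.approx(1.0)
        # t(0.975, 1) * sd / sqrt(2) with sd = sqrt(2)
        assert s.ci95_halfwidth == pytest.approx(12.706, abs=5e-4)

    def test_sd_round_trip_from_halfwidth(self):
        """The CI formula inverts: sd = ci * sqrt(n) / t(0.975, n-1)."""
        rng = np.random.default_rng(0)
        x = rng.normal(1.25, 0.6, 46)
        s = summarize(x)
        sd = s.ci95_halfwidth * np.sqrt(46) / sps.t.ppf(0.975, 45)
        assert sd == pytest.approx(x.std(ddof=1), rel=1e-12)
        assert s.sd == pytest.approx(x.std(ddof=1), rel=1e-12)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            summarize([1.0])


class TestTtest:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0]
        t, _, p = ttest_independent(x, x)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_zero_variance_equal_means_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, _, p = ttest_independent([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.0, 1.0, 9)
        b = rng.normal(0.8, 1.0, 8)
        _, _, p = ttest_independent(a, b, variant="student")
        p_perm = permutation_ttest_pvalue(a, b, n_perm=20_000, seed=1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / 20_000)
        assert abs(p - p_perm) < max(0.02, mc_err + 0.01)

    def test_welch_variant_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.3, 8)
        b = rng.normal(0.4, 3.0, 30)
        _, df_s, _ = ttest_independent(a, b, variant="student")
        _, df_w, _ = ttest_independent(a, b, variant="welch")
        assert df_s == 36 and df_w != 36


class TestTtestFromSummary:
    @pytest.mark.parametrize("n", [46, 23])
    def test_nigral_aptw_row_reproduces_p_003(self, n):
        _, _, p = ttest_from_summary(1.25, 0.18, n, 0.89, 0.15, n)
        assert round(p, 3) == 0.003

    @pytest.mark.parametrize("n", [46, 23])
    def test_putamen_aptw_row_reproduces_p_010(self, n):
        _, _, p = ttest_from_summary(0.83, 0.13, n, 1.06, 0.12, n)
        assert round(p, 3) == 0.010

    def test_equal_means_give_p_one(self):
        t, _, p = ttest_from_summary(1.0, 0.2, 20, 1.0, 0.3, 20)
        assert t == 0.0 and p == 1.0

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            ttest_from_summary(1.0, 0.2, 1, 1.0, 0.3, 20)
        with pytest.raises(ValueError):
            ttest_from_summary(1.0, 0.0, 20, 1.0, 0.3, 20)

    def test_consistent_with_raw_welch_on_real_samples(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 15), rng.normal(0.7, 2, 12)
        sa, sb = summarize(a), summarize(b)
        t_sum, df_sum, p_sum = ttest_from_summary(
            sa.mean, sa.ci95_halfwidth, sa.n, sb.mean, sb.ci95_halfwidth, sb.n
        )
        t_raw, df_raw, p_raw = ttest_independent(a, b, variant="welch")
        assert t_sum == pytest.approx(t_raw, rel=1e-10)
        assert df_sum == pytest.approx(df_raw, rel=1e-10)
        assert p_sum == pytest.approx(p_raw, rel=1e-10)


class TestAnovaFromSummary:
    def test_matches_raw_anova(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 20), (0.5, 1.5, 14), (1, 0.7, 9))]
        summaries = [summarize(g) for g in groups]
        _, f_sum, p_sum = anova_from_summary(
            [s.mean for s in summaries],
            [s.ci95_halfwidth for s in summaries],
            [s.n for s in summaries],
        )
        _, f_raw, p_raw = anova_oneway(groups)
        assert f_sum == pytest.approx(f_raw, rel=1e-10)
        assert p_sum == pytest.approx(p_raw, rel=1e-10)


class TestLevene:
    def test_identical_groups_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            w, p = levene([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert w == 0.0 and p == 1.0

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(0, s, n) for s, n in ((1, 12), (2.5, 9), (0.7, 15))]
        w, p = levene(groups)
        w_ref, p_ref = levene_hand(groups)
        assert w == pytest.approx(w_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_type_one_error_near_nominal(self):
        """Equal-variance normal groups: rejection rate ~ alpha."""
        rng = np.random.default_rng(100)
        rejections = 0
        reps = 10_000
        for _ in range(reps):
            g = rng.normal(0.0, 1.0, (3, 30))
            _, p = sps.levene(*g, center="mean")
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.01)


class TestAnova:
    def test_identical_groups(self):
        with pytest.warns(UserWarning, match="constant"):
            dfb, f, p = anova_oneway([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert dfb == 2 and f == 0.0 and p == 1.0

    def test_df_between_is_k_minus_one(self):
        rng = np.random.default_rng(0)
        dfb, _, _ = anova_oneway([rng.normal(size=8) for _ in range(3)])
        assert dfb == 2

    def test_two_groups_reduce_to_squared_t(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 13)
        t, _, p_t = ttest_independent(a, b, variant="student")
        _, f, p_f = anova_oneway([a, b])
        assert f == pytest.approx(t**2, rel=1e-12)
        assert p_f == pytest.approx(p_t, rel=1e-12)

    def test_matches_regression_oracle(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(m, 1, n) for m, n in ((0, 11), (0.4, 17), (0.9, 7))]
        _, f, p = anova_oneway(groups)
        f_ref, p_ref = anova_regression(groups)
        assert f == pytest.approx(f_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestTukey:
    def test_identical_groups_all_null(self):
        g = [np.array([1.0, 2.0, 3.0])] * 3
        for r in tukey_hsd(g):
            assert r.p_value == pytest.approx(1.0)
            assert r.ci95[0] == pytest.approx(-r.ci95[1])

    def test_studentized_range_quantile_matches_published_table(self):
        assert sps.studentized_range.ppf(0.95, 3, 10) == pytest.approx(3.88, abs=0.01)

    def test_two_groups_reduce_to_pooled_t(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(0, 1, 9), rng.normal(0.6, 1, 12)
        _, _, p_t = ttest_independent(a, b, variant="student")
        r = tukey_hsd([a, b])[0]
        assert r.p_value == pytest.approx(p_t, abs=1e-10)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        g = [rng.normal(0, 1, 12), rng.normal(0.5, 2.5, 9), rng.normal(1.0, 0.5, 15)]
        mine = tukey_hsd(g)
        ref = sps.tukey_hsd(*g)
        ci = ref.confidence_interval(0.95)
        for k, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
            assert mine[k].p_value == pytest.approx(ref.pvalue[i, j], abs=1e-8)
            assert mine[k].ci95[0] == pytest.approx(ci.low[i, j], abs=1e-8)
            assert mine[k].ci95[1] == pytest.approx(ci.high[i, j], abs=1e-8)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(30)
        g = [rng.normal(m, 1, 10) for m in (0, 1, 2)]
        for r in tukey_hsd(g):
            assert r.ci95[0] <= r.diff <= r.ci95[1]


class TestGamesHowell:
    def test_identical_groups_all_null(self):
        g = [np.array([1.0, 2.0, 3.0])] * 3
        assert all(r.p_value == pytest.approx(1.0) for r in games_howell(g))

    def test_matches_hand_computation_oracle(self):
        """Heteroscedastic three-group data against the long-form
        definitional computation (explicit q and per-pair df)."""
        rng = np.random.default_rng(17)
        g = [rng.normal(0, 0.5, 8), rng.normal(0.5, 2.0, 14), rng.normal(1.2, 1.0, 11)]
        mine = games_howell(g)
        ref = games_howell_hand(g)
        for r, (diff, p, _) in zip(mine, ref):
            assert r.diff == pytest.approx(diff, abs=1e-12)
            assert r.p_value == pytest.approx(p, abs=1e-8)

    def test_agrees_with_tukey_for_homoscedastic_balanced_data(self):
        """Asymptotic agreement: with equal variances and generous equal n
        the per-pair Welch df approaches the pooled df."""
        rng = np.random.default_rng(23)
        g = [rng.normal(m, 1.0, 60) for m in (0.0, 0.2, 0.4)]
        gh = games_howell(g)
        tk = tukey_hsd(g)
        for a, b in zip(gh, tk):
            assert abs(a.p_value - b.p_value) < 0.02

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        g = [rng.normal(0, 1, 12), rng.normal(0.5, 2.5, 9), rng.normal(1.0, 0.5, 15)]
        df = pd.DataFrame(
            {"v": np.concatenate(g), "g": ["a"] * 12 + ["b"] * 9 + ["c"] * 15}
        )
        ref = pg.pairwise_gameshowell(data=df, dv="v", between="g")
        mine = games_howell(g, labels=["a", "b", "c"])
        for r, (_, row) in zip(mine, ref.iterrows()):
            assert r.diff == pytest.approx(row["diff"], abs=1e-10)
            assert r.p_value == pytest.approx(row["pval"], abs=1e-6)


def make_table(rng, shift=0.0, scale_advanced=1.0):
    rows = []
    for stage, group, n in (("control", "control", 10), ("early", "pd", 6), ("advanced", "pd", 6)):
        for i in range(n):
            for hemi in ("left", "right"):
                sd = scale_advanced if stage == "advanced" else 1.0
                mu = shift if group == "pd" else 0.0
                rows.append(
                    dict(subject_id=f"{stage}{i}", group=group, stage=stage,
                         region="substantia_nigra", hemisphere=hemi,
                         metric="apt_weighted", value=rng.normal(mu, sd))
                )
    return pd.DataFrame(rows)


class TestRunPaperAnalysis:
    def test_gate_selects_games_howell_under_heteroscedasticity(self):
        rng = np.random.default_rng(2)
        table = make_table(rng, scale_advanced=8.0)
        res = run_paper_analysis(table)
        assert res["anova"]["posthoc_method"].iloc[0] == "games_howell"
        assert res["anova"]["levene_p"].iloc[0] < 0.05
        assert set(res["posthoc"]["method"]) == {"games_howell"}

    def test_gate_selects_tukey_under_homoscedasticity(self):
        rng = np.random.default_rng(4)
        table = make_table(rng)
        res = run_paper_analysis(table)
        assert res["anova"]["posthoc_method"].iloc[0] == "tukey"

    def test_gate_is_deterministic_function_of_levene_p(self):
        for seed in range(6):
            table = make_table(np.random.default_rng(seed), scale_advanced=1 + seed)
            res = run_paper_analysis(table)
            row = res["anova"].iloc[0]
            expected = "tukey" if row["levene_p"] >= 0.05 else "games_howell"
            assert row["posthoc_method"] == expected

    def test_missing_stage_labels_fall_back_to_two_group(self):
        rng = np.random.default_rng(1)
        table = make_table(rng)
        table = table[table["stage"] != "advanced"]
        with pytest.warns(UserWarning, match="stage labels incomplete"):
            res = run_paper_analysis(table)
        assert "anova" not in res
        assert len(res["ttests"]) == 1

    def test_subject_unit_halves_sample_count(self):
        rng = np.random.default_rng(6)
        table = make_table(rng)
        hemi = run_paper_analysis(table)["summaries"]
        subj = run_paper_analysis(table, sample_unit="subject")["summaries"]
        n_h = hemi[hemi["stage"] == "control"]["n"].iloc[0]
        n_s = subj[subj["stage"] == "control"]["n"].iloc[0]
        assert n_h == 2 * n_s

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            run_paper_analysis(pd.DataFrame({"value": [1.0]}))

    def test_all_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(8)
        res = run_paper_analysis(make_table(rng, shift=1.0))
        assert res["ttests"]["p"].between(0, 1).all()
        assert res["anova"]["p"].between(0, 1).all()
        assert res["posthoc"]["p"].between(0, 1).all()
        ph = res["posthoc"]
        assert ((ph["ci_low"] <= ph["diff"]) & (ph["diff"] <= ph["ci_high"])).all()
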