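import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from shgfb import (
    assign_quartiles, cox_fit, generate_cohort, group_summary_tests,
    km_estimate, logrank_trend, records_to_frame, run_prognostic_analysis,
)
from shgfb.survival import QUARTILE_LABELS, CoxConvergenceError
from shgfb.synthetic import CohortSpec

from _oracles import cox_partial_loglik, cox_score_test_oracle, km_survival_oracle


class TestQuartiles:
    def test_eight_distinct_values_split_in_pairs(self):
        vals = [(f"P{i}", float(i)) for i in range(1, 9)]
        qs = {q.patient_id: q.quartile for q in assign_quartiles(vals)}
        assert [qs[f"P{i}"] for i in range(1, 9)] == \
            ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_all_equal_values_collapse_to_q1(self):
        qs = assign_quartiles([(f"P{i}", 2.0) for i in range(6)])
        assert {q.quartile for q in qs} == {"Q1"}

    def test_125_values_sizes_and_ordering(self, rng):
        vals = [(f"P{i}", float(v)) for i, v in enumerate(rng.normal(size=125))]
        qs = assign_quartiles(vals)
        by_q = {lab: [] for lab in QUARTILE_LABELS}
        for (pid, v), q in zip(vals, qs):
            by_q[q.quartile].append(v)
        sizes = sorted(len(by_q[lab]) for lab in QUARTILE_LABELS)
        assert sizes == [31, 31, 31, 32]
        for lo, hi in zip(QUARTILE_LABELS, QUARTILE_LABELS[1:]):
            assert max(by_q[lo]) <= min(by_q[hi])
        # partition: every patient in exactly one group
        assert sum(len(v) for v in by_q.values()) == 125

    def test_fewer_than_four_values_rejected(self):
        with pytest.raises(ValueError):
            assign_quartiles([("a", 1.0), ("b", 2.0), ("c", 3.0)])


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        [curve] = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(2.5) == pytest.approx(2 / 3)
        assert curve.survival_at(3.0) == pytest.approx(0.0)

    def test_no_events_flat_at_one(self):
        [curve] = km_estimate([5.0, 7.0, 9.0], [0, 0, 0])
        assert curve.survival_at(9.0) == 1.0

    def test_uncensored_km_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=60).round(3) + 0.001
        [curve] = km_estimate(t, np.ones(60, dtype=int))
        for u in [1.0, 5.0, 15.0]:
            assert curve.survival_at(u) == pytest.approx((t > u).mean(), abs=1e-12)

    def test_matches_loop_oracle_with_censoring(self, rng):
        t = rng.exponential(10, size=40).round(2) + 0.01
        e = rng.integers(0, 2, size=40)
        if e.sum() == 0:
            e[0] = 1
        [curve] = km_estimate(t, e)
        ot, os_ = km_survival_oracle(t.tolist(), e.tolist())
        for u, s in zip(ot, os_):
            assert curve.survival_at(u) == pytest.approx(s, abs=1e-12)

    def test_exponential_median_recovery(self):
        # mean KM median over replicates of 200 exponential survivors
        lam = 0.01
        medians = []
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            t = rng.exponential(1 / lam, size=200)
            [curve] = km_estimate(t, np.ones(200, dtype=int))
            medians.append(curve.times[np.searchsorted(-curve.survival, -0.5)])
        assert np.mean(medians) == pytest.approx(np.log(2) / lam, rel=0.10)

    def test_at_risk_counts_on_grid(self):
        [curve] = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1],
                              at_risk_grid=[0, 2.5, 5])
        np.testing.assert_array_equal(curve.at_risk, [4, 2, 0])


class TestLogrankTrend:
    def test_identical_groups_give_null_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0] * 2
        e = [1, 0, 1, 1] * 2
        g = ["A"] * 4 + ["B"] * 4
        res = logrank_trend(t, e, g, ["A", "B"])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_with_01_scores_reduce_to_standard_logrank(self, rng):
        n = 60
        t = np.concatenate([rng.exponential(10, n // 2), rng.exponential(20, n // 2)])
        e = rng.integers(0, 2, size=n)
        e[:4] = 1
        g = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        res = logrank_trend(t, e, g, ["A", "B"], scores=[0, 1])
        ref = logrank_test(t[g == "A"], t[g == "B"], e[g == "A"], e[g == "B"])
        assert res.chi_square == pytest.approx(ref.test_statistic, abs=1e-9)

    def test_matches_cox_score_test_oracle_untied(self, rng):
        t = rng.exponential(10, size=30)  # continuous: no ties
        e = rng.integers(0, 2, size=30)
        e[:5] = 1
        groups = rng.integers(0, 4, size=30)
        labels = np.array([f"Q{i+1}" for i in groups])
        res = logrank_trend(t, e, labels, QUARTILE_LABELS)
        oracle = cox_score_test_oracle(t.tolist(), e.tolist(),
                                       (groups + 1.0).tolist())
        assert res.chi_square == pytest.approx(oracle, abs=1e-6)

    def test_power_against_monotone_hazard(self):
        # HR 1.5 per ordered group, 4 groups of 100, ~30% admin censoring
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            t, e, g = [], [], []
            for grp in range(4):
                lam = 0.01 * 1.5**grp
                raw = rng.exponential(1 / lam, size=100)
                obs = np.minimum(raw, 120.0)
                t.extend(obs)
                e.extend((raw <= 120.0).astype(int))
                g.extend([QUARTILE_LABELS[grp]] * 100)
            if logrank_trend(t, e, g, QUARTILE_LABELS).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.8

    def test_degenerate_risk_sets_rejected(self):
        with pytest.raises(ValueError, match="trend test undefined"):
            logrank_trend([1.0, 2.0], [1, 1], ["A", "A"], ["A", "B"])


class TestCox:
    def test_null_two_group_recovery(self, rng):
        n = 500
        x = rng.integers(0, 2, size=n)
        t = rng.exponential(10, size=n)
        df = pd.DataFrame({"mfs_time": t, "mfs_event": 1, "ln_fb": x.astype(float)})
        fit = cox_fit(df, "MFS", ["ln_fb"])
        assert abs(fit.coef("ln_fb")) < 0.2
        assert fit.summary.loc["ln_fb", "ci_low"] < 1 < fit.summary.loc["ln_fb", "ci_high"]

    def test_matches_1d_grid_search_on_5_patient_fixture(self):
        t = [3.0, 5.0, 7.0, 11.0, 13.0]
        e = [1, 1, 0, 1, 1]
        x = [0.5, -0.2, 1.1, 0.0, -0.9]
        df = pd.DataFrame({"mfs_time": t, "mfs_event": e, "ln_fb": x})
        fit = cox_fit(df, "MFS", ["ln_fb"])
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda b: -cox_partial_loglik(b, t, e, x),
                              bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-8})
        assert fit.coef("ln_fb") == pytest.approx(res.x, abs=1e-4)

    def test_protective_marker_recovery(self):
        betas = []
        for rep in range(30):
            recs = generate_cohort(CohortSpec(n_patients=500, er_pos_frac=1.0,
                                              seed=5000 + rep))
            betas.append(cox_fit(recs, "MFS", ["ln_fb"]).coef("ln_fb"))
        assert np.mean(betas) == pytest.approx(-1.5, abs=0.3)

    def test_missing_covariates_dropped_and_counted(self):
        recs = generate_cohort(CohortSpec(n_patients=125, er_pos_frac=1.0, seed=3))
        n_missing = sum(r.grade is None for r in recs)
        assert n_missing > 0
        fit = cox_fit(recs, "MFS",
                      ["ln_fb", "age_band", "menopausal", "size_band",
                       "grade", "pgr", "her2"], model="multivariate")
        assert fit.n_dropped_missing == n_missing
        assert fit.n_used == 125 - n_missing
        assert fit.hr("ln_fb") > 0
        assert (fit.summary["ci_low"] <= fit.summary["hr"]).all()
        assert (fit.summary["hr"] <= fit.summary["ci_high"]).all()

    def test_efron_ties_available_and_close_to_breslow(self):
        recs = generate_cohort(CohortSpec(n_patients=200, er_pos_frac=1.0, seed=4))
        b = cox_fit(recs, "MFS", ["ln_fb"], tie_method="breslow")
        ef = cox_fit(recs, "MFS", ["ln_fb"], tie_method="efron")
        assert ef.tie_method == "efron"
        assert ef.coef("ln_fb") == pytest.approx(b.coef("ln_fb"), abs=0.05)

    def test_complete_separation_flagged(self):
        # covariate perfectly orders event times: coefficient diverges
        n = 12
        df = pd.DataFrame({
            "mfs_time": np.arange(1.0, n + 1),
            "mfs_event": 1,
            "ln_fb": np.arange(float(n)),
        })
        with pytest.raises(CoxConvergenceError):
            cox_fit(df, "MFS", ["ln_fb"])


class TestGroupSummaries:
    def _df(self, a, b):
        return pd.DataFrame({"er": ["pos"] * len(a) + ["neg"] * len(b),
                             "ln_fb": list(a) + list(b)})

    def test_identical_groups_p_near_one(self):
        table, p, name = group_summary_tests(self._df([1, 2, 3], [1, 2, 3]), "er")
        assert name == "wilcoxon_rank_sum"
        assert p > 0.9

    def test_exact_wilcoxon_enumeration(self):
        _, p, _ = group_summary_tests(self._df([1, 2, 3], [4, 5, 6]), "er")
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 orderings as extreme

    def test_median_and_iqr_convention(self):
        table, _, _ = group_summary_tests(self._df([1, 2, 3, 4], [5, 6]), "er")
        pos = table.set_index("group").loc["pos"]
        assert pos["median"] == pytest.approx(2.5)
        assert pos["iqr"] == pytest.approx(1.5)
        assert pos["n"] == 4 and pos["pct"] == pytest.approx(400 / 6)

    def test_three_plus_groups_use_kruskal_wallis(self, rng):
        df = pd.DataFrame({"grade": list("III" * 5 + "II" * 5) or None,
                           "ln_fb": 0.0})
        recs = generate_cohort(CohortSpec(n_patients=150, seed=9))
        table, p, name = group_summary_tests(records_to_frame(recs), "grade")
        assert name == "kruskal_wallis"
        assert len(table) == 3 and 0 < p <= 1


class TestPrognosticAnalysis:
    def test_er_positive_subset_count(self):
        recs = generate_cohort(CohortSpec(n_patients=200, seed=11))
        n_pos = sum(r.er == "pos" for r in recs)
        report = run_prognostic_analysis(recs, subset="er == 'pos'",
                                         endpoints=("MFS",))
        assert report.n == n_pos

    def test_small_subset_refused(self):
        recs = generate_cohort(CohortSpec(n_patients=200, seed=11))
        with pytest.raises(ValueError, match="too small"):
            run_prognostic_analysis(recs, subset="ln_fb > 99")

    def test_report_structure_and_outputs(self, tmp_path):
        recs = generate_cohort(CohortSpec(n_patients=160, er_pos_frac=1.0, seed=12))
        report = run_prognostic_analysis(recs, endpoints=("MFS", "OS"))
        assert set(report.km_curves) == {"MFS", "OS"}
        assert len(report.km_curves["MFS"]) == 4  # one curve per quartile
        assert report.trend_tests["MFS"].df == 1
        assert report.cox_univariate["MFS"].hr("ln_fb") > 0
        assert "MFS" in report.cox_multivariate
        report.write(tmp_path)
        for name in ("km_curves", "trend_tests", "cox_univariate", "cox_multivariate"):
            assert (tmp_path / f"{name}.csv").exists()
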