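"""Kaplan-Meier, log-rank/Cox-score identity, Cox PH, horizon mortality."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from sepstrat.survival import (
    compare_covariates,
    cox_fit,
    cox_score_statistic,
    km_estimate,
    logrank_test,
    mortality_at,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([2, 4, 6], [1, 1, 0])["all"]
        assert km.at(2) == pytest.approx(2 / 3)
        assert km.at(4) == pytest.approx(1 / 3)  # (2/3) * (1/2)
        assert km.at(6) == pytest.approx(1 / 3)  # censored at 6

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        t = rng.exponential(10, 200) + 0.01
        km = km_estimate(t, np.ones(200, int))["all"]
        grid = np.quantile(t, [0.1, 0.3, 0.5, 0.7, 0.9])
        for g in grid:
            assert km.at(g) == pytest.approx(np.mean(t > g), abs=1e-10)

    def test_all_censored_stays_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])["all"]
        assert np.all(km.survival == 1.0)

    def test_survival_is_monotone_with_valid_ci(self, rng):
        t = rng.exponential(5, 150) + 0.01
        e = rng.binomial(1, 0.7, 150)
        km = km_estimate(t, e)["all"]
        assert np.all(np.diff(km.survival) <= 1e-12)
        ok = ~np.isnan(km.ci_low) & ~np.isnan(km.ci_high)
        assert np.all(km.ci_low[ok] >= -1e-12) and np.all(km.ci_high[ok] <= 1 + 1e-12)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        e = np.array([1, 1, 0, 1] * 2)
        g = np.array(["a"] * 4 + ["b"] * 4)
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_equals_cox_score_statistic_without_ties(self, rng):
        t = rng.exponential(10, 120)
        t += rng.random(120) * 1e-6  # distinct event times
        e = rng.binomial(1, 0.8, 120)
        x = rng.binomial(1, 0.4, 120)
        g = np.where(x == 1, "a", "b")
        chi2, _ = logrank_test(t, e, g)
        score = cox_score_statistic(t, e, x)
        assert chi2 == pytest.approx(score, abs=1e-6)

    def test_power_at_planted_hazard_ratio(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = (r.random(265) < 0.41).astype(int)
            lam = 0.0075 * np.where(x == 1, 2.4, 1.0)
            raw = r.exponential(1 / lam)
            t = np.minimum(raw, 28.0)
            e = (raw < 28.0).astype(int)
            _, p = logrank_test(t, e, np.where(x == 1, "srs1", "srs2"))
            hits += p < 0.05
        assert hits / 20 > 0.7

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], ["a", "b"])


class TestCox:
    def test_matches_hand_maximized_partial_likelihood(self):
        """Two events, no ties, one binary covariate vs grid-search oracle."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 0, 1, 0, 0])
        x = np.array([1.0, 0.0, 0.0, 1.0, 0.0])  # one event in each covariate arm

        def neg_pll(beta):
            ll = 0.0
            for i in np.nonzero(e)[0]:
                risk = t >= t[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        beta_hat = optimize.minimize_scalar(neg_pll, bounds=(-5, 5),
                                            method="bounded").x
        res = cox_fit(t, e, pd.DataFrame({"x": x}))
        assert res.log_hr == pytest.approx(beta_hat, abs=1e-4)

    def test_estimator_consistency_at_true_hr(self):
        inside = 0
        for seed in range(25):
            r = np.random.default_rng(seed)
            x = r.binomial(1, 0.41, 1000).astype(float)
            lam = 0.0075 * np.where(x == 1, 2.4, 1.0)
            raw = r.exponential(1 / lam)
            t = np.minimum(raw, 180.0)
            e = (raw < 180.0).astype(int)
            res = cox_fit(t, e, pd.DataFrame({"x": x}))
            inside += 2.1 <= res.hr <= 2.8
        assert inside / 25 >= 0.9

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3], [1, 1, 0], pd.DataFrame({"x": [1.0, 1.0, 1.0]}))

    def test_monotone_likelihood_flagged_with_unbounded_ci(self):
        t = np.array([1, 2, 3, 4, 5, 6], float)
        e = np.array([1, 1, 1, 0, 0, 0])  # all events in group x=1
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        res = cox_fit(t, e, pd.DataFrame({"x": x}))
        assert res.monotone_flag
        assert np.isinf(res.ci_high)


class TestMortality:
    def test_printed_style_proportions(self):
        # 24 deaths by day 14 among 108 vs 16 among 157
        t = np.r_[np.full(24, 5.0), np.full(84, 30.0),
                  np.full(16, 7.0), np.full(141, 30.0)]
        e = np.r_[np.ones(24), np.zeros(84) + 1, np.ones(16), np.ones(141)]
        g = np.r_[["SRS1"] * 108, ["SRS2"] * 157]
        out = mortality_at(t, e.astype(int), g, 14).set_index("group")
        assert out.loc["SRS1", "deaths"] == 24
        assert round(100 * out.loc["SRS1", "proportion"]) == 22
        assert round(100 * out.loc["SRS2", "proportion"]) == 10
        assert out.loc["SRS1", "ci_low"] < 0.222 < out.loc["SRS1", "ci_high"]

    def test_zero_deaths(self):
        out = mortality_at([20, 30], [1, 1], ["a", "a"], 14)
        assert out["proportion"].iloc[0] == 0.0

    def test_horizon_beyond_all_event_times(self):
        out = mortality_at([1, 2, 3], [1, 1, 1], ["a"] * 3, 100)
        assert out["proportion"].iloc[0] == 1.0

    def test_incomplete_followup_switches_to_km(self):
        out = mortality_at([5, 20], [0, 1], ["a", "a"], 14)
        assert out["method"].iloc[0] == "kaplan-meier"

    def test_equals_event_fraction_at_max_time_without_censoring(self, rng):
        t = rng.exponential(9, 80) + 0.1
        e = np.ones(80, int)
        out = mortality_at(t, e, ["a"] * 80, t.max())
        assert out["proportion"].iloc[0] == 1.0


class TestCovariateComparison:
    def test_welch_on_severity_style_summary(self, rng):
        # means 7.9 vs 5.4, SDs 4.0 / 3.2, n 108 / 157: p far below 1e-6
        a = rng.normal(7.9, 4.0, 108)
        b = rng.normal(5.4, 3.2, 157)
        a = (a - a.mean()) / a.std(ddof=1) * 4.0 + 7.9
        b = (b - b.mean()) / b.std(ddof=1) * 3.2 + 5.4
        meta = pd.DataFrame({"sofa": np.r_[a, b]})
        group = pd.Series(["SRS1"] * 108 + ["SRS2"] * 157)
        out = compare_covariates(meta, group).set_index("covariate")
        assert out.loc["sofa", "test"] == "welch-t"
        assert out.loc["sofa", "p"] < 1e-6
        # closed-form Welch check
        tstat, p_ref = stats.ttest_ind(a, b, equal_var=False)
        assert out.loc["sofa", "p"] == pytest.approx(p_ref)

    def test_zero_cell_takes_fisher_branch(self):
        meta = pd.DataFrame({"flag": [1] * 3 + [0] * 17 + [0] * 20})
        group = pd.Series(["a"] * 20 + ["b"] * 20)
        out = compare_covariates(meta, group).set_index("covariate")
        assert out.loc["flag", "test"] == "fisher"

    def test_constant_column_skipped(self):
        meta = pd.DataFrame({"c": [1.0] * 10})
        group = pd.Series(["a"] * 5 + ["b"] * 5)
        out = compare_covariates(meta, group)
        assert "skipped" in out["test"].iloc[0]

    def test_null_continuous_covariate_p_not_extreme(self, rng):
        ps = []
        for _ in range(50):
            meta = pd.DataFrame({"v": rng.normal(size=60)})
            group = pd.Series(["a"] * 25 + ["b"] * 35)
            ps.append(compare_covariates(meta, group)["p"].iloc[0])
        assert 0.0 <= np.mean(np.array(ps) <= 0.05) <= 0.14
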