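import numpy as np
import pandas as pd
import pytest

from sigrisk.cohort import SurvivalCohort
from sigrisk.matrix import ExpressionMatrix
from sigrisk.survival import (
    ConvergenceError,
    cox_fit,
    cox_score_statistic,
    km_estimate,
    logrank_test,
    stratified_analysis,
    univariate_cox,
)


def brute_force_logrank(times, events, mask1):
    """Independent O-E/V accumulation with hypergeometric variance."""
    o1 = e1 = v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & mask1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & mask1).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


def brute_force_cox_loglik(beta, x, times, events):
    """Direct partial log-likelihood (no ties assumed)."""
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        est = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        assert np.allclose(est.survival, 1.0)

    def test_hand_product_limit(self):
        # times (1,2,3), events (1,0,1): S = 2/3 after t=1, unchanged at the
        # censoring at t=2, drops to 0 at t=3 (1 at risk, 1 event)
        est = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        assert est.survival_at(1.0) == pytest.approx(2 / 3)
        assert est.survival_at(2.5) == pytest.approx(2 / 3)
        assert est.survival_at(3.0) == pytest.approx(0.0)
        assert est.at_risk.tolist() == [3, 2, 1]

    def test_duplicating_patients_leaves_curve_unchanged(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 20)
        e = (rng.uniform(size=20) < 0.6).astype(int)
        a = km_estimate(t, e)
        b = km_estimate(np.r_[t, t], np.r_[e, e])
        assert np.allclose(a.survival, b.survival)

    def test_ordering_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 15)
        e = (rng.uniform(size=15) < 0.5).astype(int)
        perm = rng.permutation(15)
        a = km_estimate(t, e)
        b = km_estimate(t[perm], e[perm])
        assert np.allclose(a.survival, b.survival)

    def test_per_group_estimates(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        grp = np.array(["a", "a", "b", "b"])
        curves = km_estimate(t, e, grp)
        assert set(curves) == {"a", "b"}
        assert curves["a"].survival_at(1.0) == pytest.approx(0.5)


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        grp = np.array(["a"] * 3 + ["b"] * 3)
        res = logrank_test(t, e, grp)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.exponential(10, 10) + rng.uniform(0, 0.01, 10)  # tie-free
            e = (rng.uniform(size=10) < 0.7).astype(int)
            grp = rng.choice(["a", "b"], 10)
            if e[grp == "a"].sum() == 0 or e[grp == "b"].sum() == 0:
                continue
            res = logrank_test(t, e, grp)
            expected = brute_force_logrank(t, e, grp == "a")
            assert res.statistic == pytest.approx(expected, abs=1e-8)
            assert sum(res.observed.values()) == pytest.approx(sum(res.expected.values()))

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 30)
        e = np.ones(30, int)
        grp = rng.choice(["a", "b"], 30)
        r1 = logrank_test(t, e, grp)
        swapped = np.where(grp == "a", "b", "a")
        r2 = logrank_test(t, e, swapped)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test(np.array([1.0, 2.0]), np.array([1, 1]), np.array(["a", "a"]))


class TestUnivariateCox:
    def test_score_statistic_equals_logrank_when_tie_free(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 25
            g = (rng.uniform(size=n) < 0.5).astype(float)
            t = rng.exponential(np.exp(0.5 * g)) + rng.uniform(0, 1e-9, n)
            e = (rng.uniform(size=n) < 0.8).astype(int)
            if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
                continue
            stat, _ = cox_score_statistic(g, t, e)
            lr = logrank_test(t, e, np.where(g > 0, "hi", "lo"))
            assert stat == pytest.approx(lr.statistic, abs=1e-8)

    def test_beta_matches_grid_search_on_six_patient_toys(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.choice([0.0, 1.0], 6)
            t = rng.exponential(1, 6) + rng.uniform(0, 1e-9, 6)
            e = np.ones(6, int)
            if np.ptp(x) == 0:
                continue
            try:
                fit = univariate_cox(x, t, e)
            except ConvergenceError:
                continue
            grid = np.linspace(-5, 5, 100001)
            lls = np.array([brute_force_cox_loglik(b, x, t, e) for b in grid])
            assert fit.beta == pytest.approx(grid[np.argmax(lls)], abs=1e-4)

    def test_negating_covariate_negates_beta(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        t = rng.exponential(np.exp(-0.5 * x))
        e = np.ones(50, int)
        f1 = univariate_cox(x, t, e)
        f2 = univariate_cox(-x, t, e)
        assert f1.beta == pytest.approx(-f2.beta, rel=1e-8)
        assert f1.hr == pytest.approx(1 / f2.hr, rel=1e-8)
        assert abs(f1.z) == pytest.approx(abs(f2.z), rel=1e-8)

    def test_matches_lifelines_multivariate_with_one_covariate(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        t = rng.exponential(np.exp(-0.6 * x))
        e = (rng.uniform(size=80) < 0.75).astype(int)
        mine = univariate_cox(x, t, e)
        frame = pd.DataFrame({"time": t, "event": e, "x": x})
        theirs = cox_fit(frame, ["x"])
        assert mine.beta == pytest.approx(theirs.table.loc["x", "coef"], abs=1e-5)
        assert mine.se == pytest.approx(theirs.table.loc["x", "se"], abs=1e-5)

    def test_exponential_two_group_recovers_log_rate_ratio(self):
        # closed form: with exponential baselines, beta = log rate ratio
        rng = np.random.default_rng(9)
        betas = []
        for rep in range(30):
            g = np.r_[np.zeros(100), np.ones(100)]
            t = rng.exponential(np.where(g > 0, 1 / np.exp(0.7), 1.0))
            betas.append(univariate_cox(g, t, np.ones(200, int)).beta)
        assert np.mean(betas) == pytest.approx(0.7, abs=0.1)

    def test_complete_separation_detected(self):
        # group 1 all fails before any of group 0 is at risk of failing last
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6, int)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.raises(ConvergenceError):
            univariate_cox(x, t, e)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_cox(np.ones(5), np.arange(1.0, 6.0), np.ones(5, int))

    def test_efron_and_breslow_agree_without_ties(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=40)
        t = rng.exponential(1, 40)
        e = np.ones(40, int)
        fe = univariate_cox(x, t, e, ties="efron")
        fb = univariate_cox(x, t, e, ties="breslow")
        assert fe.beta == pytest.approx(fb.beta, rel=1e-9)


class TestCoxFitSurface:
    def test_requires_time_event_and_nonconstant_covariates(self):
        frame = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1], "x": [1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(frame, ["x"])
        with pytest.raises(ValueError, match="'event'"):
            cox_fit(frame.drop(columns="event"), ["x"])

    def test_ci_contains_hr_and_z_consistency(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=60)
        z2 = rng.normal(size=60)
        t = rng.exponential(np.exp(-0.5 * x))
        frame = pd.DataFrame({"time": t, "event": np.ones(60, int), "x": x, "z2": z2})
        fit = cox_fit(frame)
        tab = fit.table
        assert ((tab["ci_low"] <= tab["hr"]) & (tab["hr"] <= tab["ci_high"])).all()
        assert np.allclose(tab["z"], tab["coef"] / tab["se"], rtol=1e-6)


class TestStratifiedAnalysis:
    def _cohort(self, n=120, seed=12, beta=0.9):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(
            rng.normal(7, 1, size=(2, n)),
            index=["gX", "gY"],
            columns=[f"p{j}" for j in range(n)],
        )
        risk = rng.choice([0, 1], n)
        t = rng.exponential(np.exp(-beta * risk) * 20, n)
        cohort = SurvivalCohort(
            ExpressionMatrix(expr),
            pd.Series(t, index=expr.columns),
            pd.Series(np.ones(n, int), index=expr.columns),
        )
        return cohort, pd.Series(risk, index=expr.columns), rng

    def test_single_level_factor_reproduces_unstratified(self):
        cohort, risk, _ = self._cohort()
        factor = pd.Series("all", index=cohort.samples)
        results, skipped = stratified_analysis(cohort, factor, risk)
        assert not skipped
        whole = cox_fit(
            pd.DataFrame(
                {
                    "time": cohort.time.to_numpy(),
                    "event": cohort.event.to_numpy(),
                    "risk_positive": risk.to_numpy(),
                }
            ),
            ["risk_positive"],
        )
        assert results["all"].cox.table.loc["risk_positive", "coef"] == pytest.approx(
            whole.table.loc["risk_positive", "coef"], rel=1e-9
        )

    def test_age_dichotomized_at_60_gives_two_strata(self):
        cohort, risk, rng = self._cohort()
        age = pd.Series(rng.normal(60, 8, cohort.n_patients), index=cohort.samples)
        factor = np.where(age < 60, "<60", ">=60")
        results, skipped = stratified_analysis(cohort, pd.Series(factor, index=cohort.samples), risk)
        assert set(results) == {"<60", ">=60"}
        for res in results.values():
            assert res.cox.table.loc["risk_positive", "hr"] > 0

    def test_equal_effects_give_consistent_per_stratum_hr(self):
        cohort, risk, rng = self._cohort(n=400, beta=0.8)
        factor = pd.Series(rng.choice(["s1", "s2"], 400), index=cohort.samples)
        results, _ = stratified_analysis(cohort, factor, risk)
        whole = univariate_cox(risk.to_numpy().astype(float), cohort.time.to_numpy(),
                               cohort.event.to_numpy())
        for res in results.values():
            coef = res.cox.table.loc["risk_positive", "coef"]
            se = res.cox.table.loc["risk_positive", "se"]
            assert abs(coef - whole.beta) < 3 * se

    def test_stratum_without_events_in_a_group_skipped(self):
        cohort, risk, _ = self._cohort(n=40)
        # stratum "bad": all its positive-group patients censored
        factor = pd.Series("good", index=cohort.samples)
        bad = cohort.samples[:10]
        factor.loc[bad] = "bad"
        event = cohort.event.copy()
        event.loc[bad[risk.loc[bad] == 1]] = 0
        cohort2 = SurvivalCohort(cohort.expression, cohort.time, event)
        results, skipped = stratified_analysis(cohort2, factor, risk)
        assert "bad" in skipped
        assert "good" in results
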