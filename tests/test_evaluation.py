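import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pherskit.evaluation import (
    EffectEstimate,
    EvaluationError,
    auprc,
    compare_effects,
    concordance_index,
    correlation,
    fit_cox_per_sd,
    nagelkerke_r2,
    percentile_group_hr,
    residualize_score,
)
from pherskit.simulate import simulate_scored_survival


def survival_frame(time, event):
    return pd.DataFrame({"time_years": time, "event": event})


class TestResidualize:
    def make_data(self, n=10_000, seed=0, coupled=0.0):
        rng = np.random.default_rng(seed)
        cov = pd.DataFrame({"age": rng.integers(32, 71, n).astype(float),
                            "sex": rng.integers(0, 2, n).astype(float)})
        score = rng.normal(size=n) + coupled * (cov["age"] - 51) / 11
        return pd.Series(score), cov

    def test_independent_score_nearly_unchanged(self):
        score, cov = self.make_data()
        resid = residualize_score(score, cov)
        standardized = (score - score.mean()) / score.std(ddof=0)
        assert np.corrcoef(resid, standardized)[0, 1] > 0.999

    def test_orthogonal_to_covariates(self):
        score, cov = self.make_data(coupled=0.8)
        resid = residualize_score(score, cov)
        assert abs(np.corrcoef(resid, cov["age"])[0, 1]) < 1e-8
        assert abs(np.corrcoef(resid, cov["sex"])[0, 1]) < 1e-8
        assert resid.mean() == pytest.approx(0.0, abs=1e-10)
        assert resid.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_projection_idempotent(self):
        score, cov = self.make_data(coupled=0.5, n=2000)
        once = residualize_score(score, cov)
        twice = residualize_score(once, cov)
        assert np.allclose(once, twice, atol=1e-10)

    def test_degenerate_score_rejected(self):
        _, cov = self.make_data(n=200)
        exact = pd.Series(2.0 * cov["age"] - 1.0)
        with pytest.raises(EvaluationError):
            residualize_score(exact, cov)

    def test_collinear_covariates_warn(self):
        score, cov = self.make_data(n=500)
        cov["age2"] = cov["age"]
        with pytest.warns(UserWarning, match="rank-deficient"):
            residualize_score(score, cov)


class TestCoxPerSd:
    def test_null_score_covers_hr_one(self):
        df = simulate_scored_survival(5000, 1.0, seed=42)
        est = fit_cox_per_sd(df["score"], df)
        assert est.ci_low <= 0.0 <= est.ci_high

    def test_wald_matches_bruteforce_partial_likelihood(self):
        rng = np.random.default_rng(3)
        n = 30
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.2 * np.exp(0.5 * x)))
        c = rng.uniform(0, 8, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        est = fit_cox_per_sd(pd.Series(x), survival_frame(time, event))

        def neg_pl(beta):  # Efron partial likelihood, brute force
            eta = beta * x
            ll = 0.0
            for ut in np.unique(time[event == 1]):
                D = (time == ut) & (event == 1)
                R = time >= ut
                d = D.sum()
                sum_r, sum_d = np.exp(eta[R]).sum(), np.exp(eta[D]).sum()
                ll += eta[D].sum()
                for k in range(d):
                    ll -= np.log(sum_r - k / d * sum_d)
            return -ll

        grad = lambda b: (neg_pl(b + 1e-6) - neg_pl(b - 1e-6)) / 2e-6
        beta = optimize.brentq(grad, -3, 3, xtol=1e-13)
        h = 1e-4
        hess = (neg_pl(beta + h) - 2 * neg_pl(beta) + neg_pl(beta - h)) / h**2
        se = 1 / np.sqrt(hess)
        assert est.estimate / est.se == pytest.approx(beta / se, abs=1e-6)

    def test_zero_events_rejected(self):
        df = survival_frame(np.ones(50) * 8.0, np.zeros(50, int))
        with pytest.raises(EvaluationError):
            fit_cox_per_sd(pd.Series(np.random.default_rng(0).normal(size=50)), df)


class TestPercentileGroups:
    def test_band_sizes_on_distinct_scores(self):
        rng = np.random.default_rng(0)
        score = pd.Series(np.arange(100, dtype=float))
        event = np.zeros(100, int)
        event[rng.choice(100, 30, replace=False)] = 1
        out = survival_frame(np.full(100, 8.0) - event * 4, event)
        x = score.to_numpy()
        top = (x > np.quantile(x, 0.9))
        ref = (x > np.quantile(x, 0.4)) & (x <= np.quantile(x, 0.6))
        assert top.sum() == 10 and ref.sum() == 20

    def test_null_scores_cover_hr_one(self):
        df = simulate_scored_survival(4000, 1.0, seed=9)
        est = percentile_group_hr(df["score"], df)
        assert est.ci_low <= 0.0 <= est.ci_high

    def test_tail_contrast_exceeds_per_sd_effect(self):
        # convexity: top-10% vs mid-20% HR > per-SD HR for a Gaussian liability
        df = simulate_scored_survival(20_000, 1.5, seed=4)
        per_sd = fit_cox_per_sd(df["score"], df)
        grp = percentile_group_hr(df["score"], df)
        # brute-force expectation of the contrast: mean liability gap between bands
        x = df["score"].to_numpy()
        gap = (x[x > np.quantile(x, 0.9)].mean()
               - x[(x > np.quantile(x, 0.4)) & (x <= np.quantile(x, 0.6))].mean())
        assert grp.estimate > per_sd.estimate
        assert grp.estimate == pytest.approx(np.log(1.5) * gap, rel=0.15)

    def test_direction_agrees_with_per_sd(self):
        for seed in (1, 2, 3):
            df = simulate_scored_survival(6000, 1.4, seed=seed)
            a = fit_cox_per_sd(df["score"], df)
            b = percentile_group_hr(df["score"], df)
            assert np.sign(a.estimate) == np.sign(b.estimate)

    def test_empty_band_rejected(self):
        df = survival_frame(np.full(5, 8.0), np.array([1, 0, 0, 0, 1]))
        with pytest.raises(EvaluationError):
            percentile_group_hr(pd.Series(np.ones(5)), df)


class TestConcordance:
    def test_random_score_near_half(self):
        df = simulate_scored_survival(4000, 1.0, seed=13)
        est = concordance_index(df["score"], df)
        assert abs(est.estimate - 0.5) < 0.03

    def test_perfect_toy_ranking(self):
        score = pd.Series([1.0, 2, 3, 4, 5, 6])
        out = survival_frame([8, 8, 8, 4, 4, 4], [0, 0, 0, 1, 1, 1])
        assert concordance_index(score, out).estimate == 1.0

    def test_equals_auc_under_fixed_followup(self):
        rng = np.random.default_rng(5)
        n = 500
        score = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-score))).astype(int)
        out = survival_frame(np.full(n, 8.0), y)  # events tied at follow-up end
        est = concordance_index(pd.Series(score), out)
        # independent trapezoidal AUC
        from sklearn.metrics import roc_auc_score
        assert est.estimate == pytest.approx(roc_auc_score(y, score), abs=1e-10)

    def test_invariant_to_monotone_transform(self):
        df = simulate_scored_survival(2000, 1.5, seed=6)
        a = concordance_index(df["score"], df)
        b = concordance_index(np.exp(df["score"] * 2), df)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)

    def test_matches_independent_survival_implementation(self):
        from sksurv.metrics import concordance_index_censored
        df = simulate_scored_survival(800, 1.6, seed=21)
        est = concordance_index(df["score"], df)
        ref = concordance_index_censored(
            df["event"].astype(bool).to_numpy(), df["time_years"].to_numpy(),
            df["score"].to_numpy())[0]
        assert est.estimate == pytest.approx(ref, abs=1e-10)

    def test_no_usable_pairs_rejected(self):
        out = survival_frame([8.0, 8.0], [0, 0])
        with pytest.raises(EvaluationError):
            concordance_index(pd.Series([1.0, 2.0]), out)


class TestCompareEffects:
    def ee(self, est, se):
        return EffectEstimate("cindex", est, se, est - 1.96 * se, est + 1.96 * se)

    def test_identical_estimates(self):
        r2 = compare_effects(self.ee(0.7, 0.01), self.ee(0.7, 0.01))
        assert r2.z == 0.0 and r2.p == pytest.approx(1.0)
        r1 = compare_effects(self.ee(0.7, 0.01), self.ee(0.7, 0.01), sidedness="one_tailed")
        assert r1.p == pytest.approx(0.5)

    def test_1_96_pooled_se_gives_p05(self):
        pooled = np.hypot(0.01, 0.01)
        r = compare_effects(self.ee(0.7 + 1.959963985 * pooled, 0.01), self.ee(0.7, 0.01))
        assert r.p == pytest.approx(0.05, abs=1e-6)

    def test_bonferroni(self):
        r = compare_effects(self.ee(0.73, 0.01), self.ee(0.7, 0.01))
        assert r.p_adjusted == pytest.approx(min(1.0, r.p * 13))
        assert compare_effects(self.ee(0.7, 0.5), self.ee(0.7, 0.5)).p_adjusted == 1.0

    def test_missing_se_rejected(self):
        with pytest.raises(EvaluationError):
            compare_effects(EffectEstimate("cindex", 0.7), self.ee(0.7, 0.01))


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([1, 2, 3, 4], [0, 0, 1, 1]).estimate == 1.0

    def test_eight_point_staircase(self):
        # hand-computed: sorted desc scores 8..1, labels 1,0,1,1,0,0,1,0
        scores = [8, 7, 6, 5, 4, 3, 2, 1]
        labels = [1, 0, 1, 1, 0, 0, 1, 0]
        # AP = sum over hits of precision at that rank / n_pos
        expected = (1 / 1 + 2 / 3 + 3 / 4 + 4 / 7) / 4
        assert auprc(scores, labels).estimate == pytest.approx(expected, abs=1e-12)

    def test_random_score_near_prevalence(self):
        rng = np.random.default_rng(8)
        y = (rng.random(20_000) < 0.1).astype(int)
        est = auprc(rng.normal(size=20_000), y)
        assert abs(est.estimate - y.mean()) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auprc([1, 2], [1, 1])


class TestNagelkerke:
    def test_null_model_is_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 50).estimate == 0.0

    def test_bounded_unit_interval(self):
        for l1 in (-90.0, -50.0, -10.0):
            v = nagelkerke_r2(l1, -100.0, 80).estimate
            assert 0.0 <= v <= 1.0

    def test_20_obs_logistic_fixture_vs_bruteforce(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = (rng.random(20) < 1 / (1 + np.exp(-1.2 * x))).astype(int)
        import statsmodels.api as sm
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        null = sm.Logit(y, np.ones((20, 1))).fit(disp=0)
        # brute-force likelihood sums
        p_hat = fit.predict(sm.add_constant(x))
        ll1 = np.sum(y * np.log(p_hat) + (1 - y) * np.log(1 - p_hat))
        p0 = y.mean()
        ll0 = np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0))
        expected = (1 - np.exp(2 * (ll0 - ll1) / 20)) / (1 - np.exp(2 * ll0 / 20))
        got = nagelkerke_r2(fit.llf, null.llf, 20).estimate
        assert got == pytest.approx(expected, abs=1e-8)


class TestCorrelation:
    def test_identity(self):
        x = pd.Series(np.arange(10.0))
        est = correlation(x, x)
        assert est.estimate == pytest.approx(1.0)

    def test_independent_vectors_small_r(self):
        rng = np.random.default_rng(3)
        est = correlation(pd.Series(rng.normal(size=10_000)),
                          pd.Series(rng.normal(size=10_000)))
        assert abs(est.estimate) < 0.05
        assert est.ci_low <= 0.0 <= est.ci_high

    def test_partial_matches_bruteforce_residualization(self):
        rng = np.random.default_rng(4)
        n = 5000
        z = rng.normal(size=n)
        x = pd.Series(0.8 * z + rng.normal(size=n))
        y = pd.Series(0.8 * z + rng.normal(size=n))
        cov = pd.DataFrame({"z": z})
        est = correlation(x, y, partial_covariates=cov)
        # brute-force: residualize both by OLS, then plain Pearson
        M = np.column_stack([np.ones(n), z])
        rx = x - M @ np.linalg.lstsq(M, x, rcond=None)[0]
        ry = y - M @ np.linalg.lstsq(M, y, rcond=None)[0]
        assert est.estimate == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)
        # the shared-covariate contamination is gone: residual corr near 0
        assert abs(est.estimate) < 0.05 < correlation(x, y).estimate

    def test_zero_variance_rejected(self):
        with pytest.raises(EvaluationError):
            correlation(pd.Series(np.ones(10)), pd.Series(np.arange(10.0)))
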