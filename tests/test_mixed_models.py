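import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tamscreen import simulate
from tamscreen.mixed_models import (
    _profiled_loglik,
    dose_response_fit,
    exosome_vegf_ratio,
    fit_random_intercept,
    fixed_effect_ftest,
    lrt_random_intercept,
    ols_loglik,
    pairwise_contrasts,
    r2_nakagawa,
    treatment_design,
    two_group_compare,
)
from tamscreen.mixed_models import _group_structure


def one_way_data(rng, q=4, n=10, donor_sd=1.0, resid_sd=1.0, mu=2.0):
    donor = np.repeat(np.arange(q), n)
    y = mu + rng.normal(0, donor_sd, q)[donor] + rng.normal(0, resid_sd, q * n)
    return y, np.ones((q * n, 1)), donor


class TestProfileFit:
    def test_no_donor_effect_lands_on_boundary(self, rng):
        donor = np.repeat(np.arange(4), 10)
        y = rng.normal(size=40)  # truly iid: sigma2_d = 0
        # force identical donor means to hit the boundary exactly
        y = y - np.array([y[donor == d].mean() for d in range(4)])[donor]
        fit = fit_random_intercept(y, np.ones((40, 1)), donor)
        assert fit.sigma2_donor <= 1e-6
        assert fit.icc <= 1e-6

    def test_reml_matches_balanced_anova_moments_estimator(self, rng):
        # classical identity: balanced one-way REML variance components equal
        # the ANOVA method-of-moments estimator when it is non-negative
        for _ in range(50):
            q = rng.integers(3, 8)
            n = rng.integers(5, 20)
            y, X, donor = one_way_data(rng, q, n, rng.uniform(0.3, 2), 1.0)
            gm = y.reshape(q, n).mean(axis=1)
            msb = n * np.sum((gm - y.mean()) ** 2) / (q - 1)
            msw = np.sum((y.reshape(q, n) - gm[:, None]) ** 2) / (q * (n - 1))
            mom = max(0.0, (msb - msw) / n)
            fit = fit_random_intercept(y, X, donor, "reml")
            assert fit.sigma2_donor == pytest.approx(mom, rel=1e-4, abs=1e-8)

    def test_ml_never_exceeds_reml_between_variance(self, rng):
        # ML shrinks the between-group variance relative to REML
        for _ in range(10):
            y, X, donor = one_way_data(rng, 5, 8, 1.0, 1.0)
            ml = fit_random_intercept(y, X, donor, "ml")
            reml = fit_random_intercept(y, X, donor, "reml")
            assert ml.sigma2_donor <= reml.sigma2_donor + 1e-10

    def test_profile_fit_matches_dense_grid_search(self, rng):
        # oracle equivalence: 1000 log-spaced theta values never beat the
        # profile optimum by more than 1e-6 loglik units
        thetas = np.logspace(-8, 6, 1000)
        for _ in range(20):
            q = rng.integers(3, 6)
            n = rng.integers(4, 10)
            y, X, donor = one_way_data(rng, q, n, rng.uniform(0, 1.5), 1.0)
            fit = fit_random_intercept(y, X, donor, "ml")
            codes, counts, _ = _group_structure(donor)
            grid_best = max(
                _profiled_loglik(t, y, X, codes, counts, "ml") for t in thetas
            )
            assert fit.loglik >= grid_best - 1e-6

    def test_icc_recovery_at_study_scale(self):
        # 5 donors x 25 units, target ICC 0.6: the estimate is unbiased to
        # within 0.1 over 100 seeds; its per-seed scatter is dominated by
        # the 4 degrees of freedom available for the between-donor variance
        errs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            donor_sd = math.sqrt(0.6 / 0.4)
            y, X, donor = one_way_data(r, 5, 25, donor_sd, 1.0)
            # REML is the variance-reporting method: ML's (q-1)/q shrinkage
            # of the between-donor mean square costs another ~0.05 of bias
            fit = fit_random_intercept(y, X, donor, "reml")
            errs.append(fit.icc - 0.6)
        assert abs(np.mean(errs)) < 0.1
        # scatter sanity: estimates concentrate around the target
        assert np.mean(np.abs(errs)) < 0.2

    def test_icc_invariant_under_affine_transform(self, rng):
        y, X, donor = one_way_data(rng, 5, 10, 1.0, 1.0)
        f1 = fit_random_intercept(y, X, donor)
        f2 = fit_random_intercept(3.7 * y - 11.0, X, donor)
        assert f2.icc == pytest.approx(f1.icc, abs=1e-6)

    def test_matches_statsmodels_loglik(self, rng):
        import statsmodels.api as sm

        for method in ("ml", "reml"):
            y, X, donor = one_way_data(rng, 5, 12, 0.8, 1.2)
            fit = fit_random_intercept(y, X, donor, method)
            ref = sm.MixedLM(y, X, groups=donor).fit(reml=(method == "reml"))
            # the profiled optimum can only match or beat statsmodels'
            # iterative optimizer, which sometimes stops early
            assert fit.loglik >= ref.llf - 1e-5
            assert abs(fit.loglik - ref.llf) < 0.1
            assert fit.beta[0] == pytest.approx(ref.params[0], abs=1e-3)

    def test_single_donor_rejected(self, rng):
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_random_intercept(y, np.ones((10, 1)), np.zeros(10, int))

    def test_singular_design_names_aliased_column(self, rng):
        y, _, donor = one_way_data(rng)
        X = np.column_stack([np.ones(len(y)), np.ones(len(y))])
        with pytest.raises(ValueError, match="aliased"):
            fit_random_intercept(y, X, donor, coef_names=["intercept", "dup"])

    def test_denominator_df_matches_study_shape(self, rng):
        # 63 observations, 3 conditions, 3 donors -> F(2, 58) shape
        frac, _ = simulate.simulate_fractionation(n_donors=3, n_lines=7, seed=0)
        X, levels = treatment_design(frac["condition"])
        fit = fit_random_intercept(frac["vegf_pg_ml"], X, frac["donor"])
        assert fit.n_obs == 63
        assert fit.df_denominator == 63 - 3 - 2  # = 58


class TestLrt:
    def test_null_data_gives_chi2_zero(self, rng):
        donor = np.repeat(np.arange(4), 10)
        y = rng.normal(size=40)
        y = y - np.array([y[donor == d].mean() for d in range(4)])[donor]
        X = np.ones((40, 1))
        fit = fit_random_intercept(y, X, donor, "ml")
        chi2, df, p, pb = lrt_random_intercept(fit, y, X)
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert p > 0.99

    def test_chi2_never_negative(self, rng):
        for _ in range(100):
            y, X, donor = one_way_data(rng, 3, 5, rng.uniform(0, 1), 1.0)
            fit = fit_random_intercept(y, X, donor, "ml")
            chi2, *_ = lrt_random_intercept(fit, y, X)
            assert chi2 >= 0.0

    def test_boundary_mixture_p_never_exceeds_plain_p(self, rng):
        for _ in range(20):
            y, X, donor = one_way_data(rng, 4, 6, rng.uniform(0, 1), 1.0)
            fit = fit_random_intercept(y, X, donor, "ml")
            _, _, p, pb = lrt_random_intercept(fit, y, X)
            assert pb <= p + 1e-12

    def test_reml_fit_rejected(self, rng):
        y, X, donor = one_way_data(rng)
        fit = fit_random_intercept(y, X, donor, "reml")
        with pytest.raises(ValueError, match="ML"):
            lrt_random_intercept(fit, y, X)

    def test_null_p_values_conservative(self):
        # under sigma2_d = 0 the plain df=1 p-values are stochastically
        # larger than uniform
        ps = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            y, X, donor = one_way_data(r, 4, 8, donor_sd=0.0)
            fit = fit_random_intercept(y, X, donor, "ml")
            ps.append(lrt_random_intercept(fit, y, X)[2])
        ps = np.asarray(ps)
        for a in (0.05, 0.1, 0.25):
            assert np.mean(ps < a) <= a + 0.02


class TestContrasts:
    def test_three_levels_give_three_contrasts(self, rng):
        frac, _ = simulate.simulate_fractionation(seed=1)
        X, levels = treatment_design(frac["condition"])
        fit = fit_random_intercept(frac["vegf_pg_ml"], X, frac["donor"])
        assert len(pairwise_contrasts(fit, levels)) == 3

    def test_recovers_planted_1000_effect_within_1pct(self):
        frac, _ = simulate.simulate_fractionation(residual_sd=10.0, seed=5)
        X, levels = treatment_design(frac["condition"])
        fit = fit_random_intercept(frac["vegf_pg_ml"], X, frac["donor"])
        cs = {c.pair: c for c in pairwise_contrasts(fit, levels)}
        est = cs[("exo_only", "exo_depleted")].estimate
        assert est == pytest.approx(1000.0, rel=0.01)

    def test_contrast_antisymmetry_and_adjustment(self, rng):
        frac, _ = simulate.simulate_fractionation(seed=2)
        X, levels = treatment_design(frac["condition"])
        fit = fit_random_intercept(frac["vegf_pg_ml"], X, frac["donor"])
        for c in pairwise_contrasts(fit, levels):
            raw = 2 * stats.t.sf(abs(c.t), c.df)
            assert c.p_adjusted >= raw - 1e-12

    def test_identical_group_means_not_significant(self, rng):
        frac, _ = simulate.simulate_fractionation(
            condition_effects={"a": 0.0, "b": 0.0, "c": 0.0}, donor_sd=0.0, seed=3
        )
        X, levels = treatment_design(frac["condition"])
        fit = fit_random_intercept(frac["vegf_pg_ml"], X, frac["donor"])
        ps = [c.p_adjusted for c in pairwise_contrasts(fit, levels)]
        assert min(ps) > 0.05  # no spurious separation of equal means


class TestNakagawaR2:
    def test_intercept_only_marginal_zero(self, rng):
        y, X, donor = one_way_data(rng)
        fit = fit_random_intercept(y, X, donor)
        assert fit.r2_marginal == pytest.approx(0.0, abs=1e-12)

    def test_no_donor_variance_makes_both_equal(self, rng):
        donor = np.repeat(np.arange(4), 10)
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        y = y - np.array([y[donor == d].mean() for d in range(4)])[donor]
        X = np.column_stack([np.ones(40), x])
        fit = fit_random_intercept(y, X, donor)
        if fit.sigma2_donor < 1e-8:
            assert fit.r2_marginal == pytest.approx(fit.r2_conditional, abs=1e-6)

    def test_recovers_known_variance_shares(self):
        # fixed 0.4, donor 0.3, residual 0.3 => (r2m, r2c) = (0.4, 0.7);
        # averaged over 5 replicates of the n=500 design to damp the
        # between-donor sampling noise
        r2m, r2c = [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            n_donor, n_per = 20, 25
            donor = np.repeat(np.arange(n_donor), n_per)
            x = r.normal(size=n_donor * n_per)
            y = (
                math.sqrt(0.4) * x
                + r.normal(0, math.sqrt(0.3), n_donor)[donor]
                + r.normal(0, math.sqrt(0.3), n_donor * n_per)
            )
            X = np.column_stack([np.ones_like(x), x])
            fit = fit_random_intercept(y, X, donor)
            r2m.append(fit.r2_marginal)
            r2c.append(fit.r2_conditional)
        assert np.mean(r2m) == pytest.approx(0.4, abs=0.05)
        assert np.mean(r2c) == pytest.approx(0.7, abs=0.05)


class TestDoseResponse:
    def test_defaults_recover_printed_predicted_means(self):
        dose, _ = simulate.simulate_dose_response(seed=0)
        fit, pred = dose_response_fit(dose)
        p0 = pred.loc[pred["dose"] == 0.0, "predicted_mean"].iloc[0]
        p5 = pred.loc[pred["dose"] == 5.0, "predicted_mean"].iloc[0]
        assert p0 == pytest.approx(7.42, rel=0.10)
        assert p5 == pytest.approx(23.02, rel=0.10)

    def test_zero_slope_ci_covers_zero(self):
        covered = 0
        n_rep = 60
        for seed in range(n_rep):
            dose, _ = simulate.simulate_dose_response(
                inverse_slope=0.0, seed=seed
            )
            fit, _ = dose_response_fit(dose)
            lo, hi = fit.beta_ci[1]
            covered += lo <= 0.0 <= hi
        assert covered / n_rep >= 0.85  # ~95% nominal, Monte-Carlo slack

    def test_identity_transform_recovers_linear_slope(self):
        r = np.random.default_rng(4)
        rows = []
        for d in range(4):
            u = r.normal(0, 0.1)
            for dose in (0.0, 1.0, 2.5, 5.0):
                rows.append((f"D{d}", dose, 3.0 + 2.0 * dose + u + r.normal(0, 0.05)))
        df = pd.DataFrame(rows, columns=["donor", "dose", "response"])
        fit, _ = dose_response_fit(df, transform="identity")
        assert fit.beta[1] == pytest.approx(2.0, rel=0.05)

    def test_single_dose_level_rejected(self):
        df = pd.DataFrame({"donor": ["D1"] * 4, "dose": [1.0] * 4,
                           "response": [1, 2, 3, 4.0]})
        with pytest.raises(ValueError, match="unidentifiable"):
            dose_response_fit(df)

    def test_nonpositive_response_rejected_under_inverse(self):
        df = pd.DataFrame({"donor": ["D1", "D1", "D2", "D2"],
                           "dose": [0.0, 1.0, 0.0, 1.0],
                           "response": [1.0, -2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="rows"):
            dose_response_fit(df)

    def test_dose_ftest_significant_at_defaults(self):
        dose, _ = simulate.simulate_dose_response(seed=7)
        fit, _ = dose_response_fit(dose)
        F, d1, d2, p = fixed_effect_ftest(fit, [1])
        assert d1 == 1 and p < 0.01


class TestRatioAndGroupTests:
    def test_ratio_arithmetic(self):
        assert exosome_vegf_ratio(140.0, 10.0) == pytest.approx(14.0)
        assert exosome_vegf_ratio(5.0, 5.0) == 1.0
        assert np.isnan(exosome_vegf_ratio(5.0, 0.0))

    def test_rank_sum_extreme_exact_p(self):
        out = two_group_compare([1, 2, 3], [4, 5, 6], test="wilcoxon")
        assert out["p"] == pytest.approx(0.1)  # 2 / C(6,3)

    def test_one_sample_constant_at_reference(self):
        out = two_group_compare([1.0, 1.0, 1.0], reference=1.0, test="one_sample_t")
        assert out["statistic"] == 0.0 and out["p"] == 1.0

    def test_identical_groups_not_significant(self):
        a = [1.0, 2.0, 3.0, 4.0]
        out = two_group_compare(a, a, test="welch_t")
        assert out["p"] > 0.99

    def test_kruskal_multi_group(self, rng):
        g = [rng.normal(size=10), rng.normal(size=10), rng.normal(3, 1, 10)]
        out = two_group_compare(g[0], test="kruskal", groups=g)
        assert out["p"] < 0.05

    def test_normality_routing_is_logged(self, rng, caplog):
        a = rng.exponential(size=20) ** 3  # grossly non-normal
        b = rng.exponential(size=20) ** 3
        with caplog.at_level("INFO", logger="tamscreen"):
            out = two_group_compare(a, b, normality_check=True)
        assert out["test"] == "wilcoxon"
        assert any("routing" in r.message for r in caplog.records)


class TestFractionationCalibration:
    def test_null_ftest_p_uniform(self):
        ps = []
        for seed in range(200):
            df, _ = simulate.simulate_fractionation(
                condition_effects={"whole": 0.0, "exo_depleted": 0.0, "exo_only": 0.0},
                donor_sd=0.0, seed=seed,
            )
            X, levels = treatment_design(df["condition"])
            fit = fit_random_intercept(df["vegf_pg_ml"], X, df["donor"], "reml")
            ps.append(fixed_effect_ftest(fit, [1, 2])[3])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
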