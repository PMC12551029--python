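import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dualrisk.mvn import (
    EstimationError,
    FIMLRegression,
    delta_r2,
    em_mvn,
    fiml_regression,
    fit_indices,
    independence_loglik,
    paired_change_test,
)

SIGMA = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
MU = np.array([0.0, 1.0, -1.0])


def draw(rng, n):
    return pd.DataFrame(rng.multivariate_normal(MU, SIGMA, n), columns=["y", "x1", "x2"])


def mask_mcar(rng, df, frac):
    out = df.copy()
    mask = rng.random(df.shape) < frac
    # never blank an entire row
    mask[mask.all(axis=1), 0] = False
    out[mask] = np.nan
    return out


class TestEmMvn:
    def test_complete_data_is_closed_form_fixed_point(self, rng):
        df = draw(rng, 400)
        fit = em_mvn(df)
        np.testing.assert_allclose(fit.mean, df.mean().to_numpy(), atol=1e-10)
        np.testing.assert_allclose(fit.cov, np.cov(df.to_numpy().T, bias=True), atol=1e-10)
        assert fit.n_iter <= 2  # closed form reached after one M-step

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loglik_monotone(self, seed):
        rng = np.random.default_rng(seed)
        df = mask_mcar(rng, draw(rng, 300), 0.3)
        fit = em_mvn(df)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-7).all()
        assert fit.converged

    def test_mcar_recovery_within_monte_carlo_error(self):
        rng = np.random.default_rng(99)
        n = 5000
        df = mask_mcar(rng, draw(rng, n), 0.25)
        fit = em_mvn(df)
        # 3 MC SEs; SE(sigma_ij) ~ sqrt((s_ii s_jj + s_ij^2) / n_eff)
        n_eff = n * 0.75**2
        for i in range(3):
            assert abs(fit.mean[i] - MU[i]) < 3 * np.sqrt(SIGMA[i, i] / (n * 0.75))
            for j in range(3):
                se = np.sqrt((SIGMA[i, i] * SIGMA[j, j] + SIGMA[i, j] ** 2) / n_eff)
                assert abs(fit.cov[i, j] - SIGMA[i, j]) < 3 * se

    def test_fully_missing_rows_dropped_with_warning(self, rng):
        df = draw(rng, 50)
        df.iloc[3] = np.nan
        with pytest.warns(UserWarning, match="fully missing"):
            fit = em_mvn(df)
        assert fit.n_obs == 49 and fit.n_dropped_rows == 1

    def test_sparse_variable_errors(self, rng):
        df = draw(rng, 30)
        df.loc[df.index[1:], "x2"] = np.nan
        with pytest.raises(EstimationError, match="fewer than twice"):
            em_mvn(df)

    def test_covariance_psd(self, rng):
        df = mask_mcar(rng, draw(rng, 200), 0.4)
        fit = em_mvn(df)
        assert np.linalg.eigvalsh(fit.cov)[0] > -1e-10


class TestFimlRegression:
    def test_complete_data_equals_ols_and_hc0(self, rng):
        df = draw(rng, 300)
        res = FIMLRegression(df, "y", ["x1", "x2"]).fit(small_sample="none")
        ols = sm.OLS(df["y"], sm.add_constant(df[["x1", "x2"]])).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ols.params.to_numpy(), atol=1e-8)
        hc0 = ols.get_robustcov_results("HC0")
        np.testing.assert_allclose(res.bse.to_numpy(), hc0.bse, atol=1e-8)
        # R^2 equals 1 - SSE/SST under the ML fit
        assert res.rsquared == pytest.approx(ols.rsquared, abs=1e-8)

    def test_standardized_relation_to_raw(self, rng):
        df = draw(rng, 300)
        res = FIMLRegression(df, "y", ["x1", "x2"]).fit()
        sd = np.sqrt(np.diag(res.mvn.cov))
        for j, name in enumerate(["x1", "x2"]):
            expect = res.params[name] * sd[j + 1] / sd[0]
            assert res.params_standardized[name] == pytest.approx(expect, abs=1e-12)

    def test_duplication_leaves_coefficients_unchanged(self, rng):
        df = draw(rng, 150)
        df["cl"] = [f"c{i}" for i in range(len(df))]
        doubled = pd.concat([df, df.assign(cl=df["cl"] + "bis")], ignore_index=True)
        r1 = FIMLRegression(df, "y", ["x1", "x2"], cluster="cl").fit()
        r2 = FIMLRegression(doubled, "y", ["x1", "x2"], cluster="cl").fit()
        np.testing.assert_allclose(r1.params, r2.params, atol=1e-8)

    def test_sandwich_invariant_to_cluster_relabeling_and_order(self, rng):
        df = draw(rng, 200)
        df["cl"] = [f"c{i % 40}" for i in range(len(df))]
        r1 = FIMLRegression(df, "y", ["x1", "x2"], cluster="cl").fit()
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        shuffled["cl"] = "z" + shuffled["cl"]
        r2 = FIMLRegression(shuffled, "y", ["x1", "x2"], cluster="cl").fit()
        np.testing.assert_allclose(r1.bse, r2.bse, atol=1e-8)

    def test_missing_outcome_rows_still_inform(self, rng):
        # FIML uses predictor-only rows; estimates stay consistent
        df = draw(rng, 2000)
        df.loc[df.index[:600], "y"] = np.nan
        res = FIMLRegression(df, "y", ["x1", "x2"]).fit()
        truth_b = np.linalg.solve(SIGMA[1:, 1:], SIGMA[1:, 0])
        np.testing.assert_allclose(res.params.to_numpy()[1:], truth_b, atol=0.12)

    def test_too_few_clusters_errors(self, rng):
        df = draw(rng, 30)
        df["cl"] = "c1"
        with pytest.raises(EstimationError, match="clusters"):
            FIMLRegression(df, "y", ["x1", "x2"], cluster="cl").fit()

    def test_collinear_predictors_named(self, rng):
        df = draw(rng, 100)
        df["x3"] = 2.0 * df["x1"]
        with pytest.raises(EstimationError, match="x1.*x3|x3.*x1"):
            FIMLRegression(df, "y", ["x1", "x2", "x3"]).fit()

    def test_from_formula(self, rng):
        df = draw(rng, 100)
        res = FIMLRegression.from_formula("y ~ x1 + x2", df).fit()
        assert list(res.params.index) == ["const", "x1", "x2"]

    def test_functional_wrapper_with_array_clusters(self, rng):
        df = draw(rng, 100)
        res = fiml_regression(df, "y", ["x1", "x2"], cluster_ids=np.arange(100) % 25)
        assert res.n_clusters == 25

    def test_summary_renders(self, rng):
        res = FIMLRegression(draw(rng, 80), "y", ["x1", "x2"]).fit()
        text = res.summary()
        assert "R^2" in text and "x1" in text


class TestDeltaR2:
    def test_plain_numbers(self):
        assert delta_r2(0.312, 0.277) == pytest.approx(0.035, abs=1e-12)

    def test_nested_results_and_identity(self, rng):
        df = draw(rng, 200)
        full = FIMLRegression(df, "y", ["x1", "x2"]).fit()
        reduced = FIMLRegression(df, "y", ["x1"]).fit()
        assert delta_r2(full, reduced) == pytest.approx(full.rsquared - reduced.rsquared)
        assert delta_r2(full, full) == 0.0

    def test_non_nested_errors(self, rng):
        df = draw(rng, 200)
        a = FIMLRegression(df, "y", ["x1"]).fit()
        b = FIMLRegression(df, "y", ["x2"]).fit()
        with pytest.raises(EstimationError, match="nested"):
            delta_r2(a, b)

    def test_noise_predictor_adds_little(self):
        rng = np.random.default_rng(5)
        df = draw(rng, 10000)
        df["noise"] = rng.standard_normal(len(df))
        full = FIMLRegression(df, "y", ["x1", "x2", "noise"]).fit()
        reduced = FIMLRegression(df, "y", ["x1", "x2"]).fit()
        assert 0.0 <= delta_r2(full, reduced) < 0.01


class TestFitIndices:
    def test_saturated_model(self):
        out = fit_indices(-100.0, -100.0, -150.0, df_model=0, df_baseline=3, n=200)
        assert out.chi2 == 0.0 and out.cfi == 1.0 and out.rmsea == 0.0
        assert "df = 0" in out.note

    def test_chi2_below_df_floors_rmsea(self):
        out = fit_indices(-101.0, -100.0, -150.0, df_model=5, df_baseline=10, n=200)
        assert out.chi2 == pytest.approx(2.0)
        assert out.rmsea == 0.0  # chi2 < df

    def test_against_closed_form_baseline_chi2(self, rng):
        # independent hand calculation: for complete data the baseline
        # (independence) chi-square is n * (-log det R) with R the ML
        # correlation matrix
        df = draw(rng, 150)
        fit = em_mvn(df)
        ll_base, df_base = independence_loglik(df)
        out = fit_indices(fit.loglik, fit.loglik, ll_base, 0, df_base, len(df))
        r = fit.corr
        expected = len(df) * (-np.linalg.slogdet(r)[1])
        assert out.chi2_baseline == pytest.approx(expected, rel=1e-8)

    def test_ordering_violation_errors(self):
        with pytest.raises(EstimationError):
            fit_indices(-90.0, -100.0, -150.0, 1, 3, 100)


class TestPairedChangeTest:
    def test_no_change_gives_zero(self, rng):
        x = rng.normal(size=30)
        t, df, p = paired_change_test(x, x)
        assert t == 0.0 and df == 29

    def test_constant_nonzero_differences_error(self):
        with pytest.raises(EstimationError, match="zero-SD"):
            paired_change_test([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])

    def test_too_few_pairs_error(self):
        with pytest.raises(EstimationError, match="2 complete pairs"):
            paired_change_test([1.0], [2.0])

    def test_matches_scipy_and_df(self, rng):
        w5 = rng.normal(size=100)
        w6 = w5 + rng.normal(0.3, 1.0, 100)
        from scipy import stats

        t, df, p = paired_change_test(w5, w6)
        t2, p2 = stats.ttest_rel(w6, w5)
        assert t == pytest.approx(t2) and p == pytest.approx(p2) and df == 99

    def test_alignment_on_ids(self, rng):
        w5 = pd.Series([1.0, 2.0, 3.0])
        t, df, p = paired_change_test(
            [1.0, 2.0, 3.0], [3.3, 1.2, 2.1], pairing_ids=(["a", "b", "c"], ["c", "a", "b"])
        )
        # aligned pairs: a:(1.0,1.2), b:(2.0,2.1), c:(3.0,3.3)
        diffs = np.array([0.2, 0.1, 0.3])
        expect = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(3))
        assert t == pytest.approx(expect)

    def test_power_at_reported_sample_size(self):
        # a 0.5 SD mean shift with 279 completers is detected at alpha = .001
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            w5 = rng.normal(size=279)
            w6 = w5 + rng.normal(0.5, 1.0, 279)
            t, df, p = paired_change_test(w5, w6)
            assert df == 278
            hits += p < 0.001
        assert hits >= 29  # > 95% of seeds
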