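import numpy as np
import pandas as pd
import pytest

from elevgrad import ValidationError
from elevgrad import stats as egs
from oracles import poisson_deviance, r_squared_of_regression

# ---------------------------------------------------------------------------
# Spatially correlated fixture, generated once from a Gaussian process
# (gaussian kernel, range 400 m, sd 0.8) and frozen.  The reference values
# below it were computed with R's nlme::gls (corGaus, method="ML") and
# anova(glm(..., family=quasipoisson), test="F") on exactly these numbers.
# ---------------------------------------------------------------------------
GLS_Y = np.array([
    2.6339260923, 2.80144428, 1.2425289473, -0.6958722598, -1.3641570931,
    -0.3401084266, 1.2052217741, 1.6592187982, 0.5130241208, -1.1794210718,
    -1.8105759032, -0.7088667132, 1.2383099599, 2.3514399065, 1.637368988,
    -0.3041958982, -1.7797551561, -1.5314069797, 0.0712961048, 1.3276141318,
    0.7658965581, -1.4751073109, -3.7343140107, -4.3068773838, -2.9499999538,
])
GLS_I = np.arange(1, 26)
GLS_COORD = 100.0 * GLS_I
GLS_DESIGN = pd.DataFrame({"x1": np.sin(GLS_I), "x2": GLS_I / 10.0})

R_GLS_COEF = np.array([1.1091852606, 1.9878213397, -1.0863682908])
R_GLS_LOGLIK = 66.1200442385
R_GLS_RANGE = 348.4324958038
R_GLS_SIGMA = 0.4263602776
R_GLS_LOGLIK_OLS = -21.9165609865


class TestGLS:
    def test_profile_likelihood_matches_nlme_at_reference_rho(self):
        """Fixing rho at nlme's ML estimate must reproduce its coefficients,
        sigma and log-likelihood almost exactly."""
        f = egs.fit_gls(GLS_Y, GLS_DESIGN, GLS_COORD, structure="gaussian",
                        rho=R_GLS_RANGE)
        np.testing.assert_allclose(f.params.to_numpy(), R_GLS_COEF, atol=1e-6)
        assert f.loglik == pytest.approx(R_GLS_LOGLIK, abs=1e-4)
        assert np.sqrt(f.sigma2) == pytest.approx(R_GLS_SIGMA, abs=1e-6)

    def test_optimized_fit_agrees_with_nlme(self):
        """The profiled optimum must be at least as good as nlme's and land on
        essentially the same parameters."""
        f = egs.fit_gls(GLS_Y, GLS_DESIGN, GLS_COORD, structure="gaussian")
        assert f.loglik >= R_GLS_LOGLIK - 1e-6
        assert f.loglik == pytest.approx(R_GLS_LOGLIK, abs=0.5)
        assert f.rho == pytest.approx(R_GLS_RANGE, rel=0.05)
        np.testing.assert_allclose(f.params.to_numpy(), R_GLS_COEF, atol=0.05)
        assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.k)
        assert f.k == 5  # 3 betas + sigma2 + rho

    def test_structure_none_matches_nlme_ols_loglik(self):
        f = egs.fit_gls(GLS_Y, GLS_DESIGN, GLS_COORD, structure="none")
        assert f.loglik == pytest.approx(R_GLS_LOGLIK_OLS, abs=1e-6)

    def test_noiseless_linear_fixture_exact_coefficients(self):
        x = np.arange(10.0)
        y = 2.0 + 3.0 * x
        f = egs.fit_gls(y, pd.DataFrame({"x": x}), x * 100, structure="none")
        np.testing.assert_allclose(f.params.to_numpy(), [2.0, 3.0], atol=1e-10)

    def test_rho_to_zero_reduces_to_ols(self):
        ols = egs.fit_gls(GLS_Y, GLS_DESIGN, GLS_COORD, structure="none")
        for s in ("gaussian", "exponential", "spherical"):
            tiny = egs.fit_gls(GLS_Y, GLS_DESIGN, GLS_COORD, structure=s, rho=1e-3)
            assert tiny.loglik == pytest.approx(ols.loglik, abs=1e-6)
            np.testing.assert_allclose(tiny.params.to_numpy(), ols.params.to_numpy(),
                                       atol=1e-8)

    def test_singular_design_rejected(self):
        d = pd.DataFrame({"x1": GLS_I * 1.0, "x2": GLS_I * 2.0})
        with pytest.raises(ValidationError, match="singular"):
            egs.fit_gls(GLS_Y, d, GLS_COORD, structure="none")

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValidationError):
            egs.fit_gls(GLS_Y, GLS_DESIGN, GLS_COORD, structure="matern")


class TestStructureComparison:
    def test_aic_table_ranked_with_winner(self):
        out = egs.compare_correlation_structures(GLS_Y, GLS_DESIGN, GLS_COORD)
        assert list(out["aic"]) == sorted(out["aic"])
        assert out["best"].iloc[0]
        assert out.loc[out["best"], "structure"].iloc[0] in (
            "gaussian", "exponential", "spherical"
        )

    def test_single_candidate_is_its_own_winner(self):
        out = egs.compare_correlation_structures(GLS_Y, GLS_DESIGN, GLS_COORD,
                                                 structures=("none",))
        assert len(out) == 1 and out["best"].iloc[0]

    def test_uncorrelated_data_prefers_none_usually(self):
        """With iid noise, 'none' (fewest parameters) should win AIC in most
        replicates against the gaussian structure."""
        rng = np.random.default_rng(99)
        coords = 100.0 * np.arange(1, 31)
        wins = 0
        reps = 40
        for _ in range(reps):
            x = rng.standard_normal(30)
            y = 1.0 + 0.5 * x + rng.standard_normal(30)
            out = egs.compare_correlation_structures(
                y, pd.DataFrame({"x": x}), coords, structures=("none", "gaussian")
            )
            wins += out.loc[out["best"], "structure"].iloc[0] == "none"
        assert wins > reps / 2

    def test_strong_gaussian_correlation_beats_none_usually(self):
        rng = np.random.default_rng(7)
        coords = 100.0 * np.arange(1, 41)
        d = np.abs(coords[:, None] - coords[None, :])
        L = np.linalg.cholesky(np.exp(-((d / 500.0) ** 2)) + 1e-8 * np.eye(40))
        wins = 0
        reps = 40
        for _ in range(reps):
            x = rng.standard_normal(40)
            y = 1.0 + 0.5 * x + L @ rng.standard_normal(40)
            out = egs.compare_correlation_structures(
                y, pd.DataFrame({"x": x}), coords, structures=("none", "gaussian")
            )
            wins += out.loc[out["best"], "structure"].iloc[0] == "gaussian"
        assert wins > reps / 2


class TestLRT:
    def test_adding_terms_never_decreases_loglik(self):
        full = egs.fit_gls(GLS_Y, GLS_DESIGN, GLS_COORD, structure="gaussian")
        for t in egs.lrt_term_tests(full):
            assert t.statistic >= 0
            assert 0 <= t.p_value <= 1
            assert t.df == 1

    def test_full_model_vs_itself_rejected(self):
        full = egs.fit_gls(GLS_Y, GLS_DESIGN, GLS_COORD, structure="none")
        with pytest.raises(ValidationError):
            egs.lrt_term_tests(full, drop_terms=[])

    def test_unknown_term_rejected(self):
        full = egs.fit_gls(GLS_Y, GLS_DESIGN, GLS_COORD, structure="none")
        with pytest.raises(ValidationError):
            egs.lrt_term_tests(full, drop_terms=["nope"])

    def test_dropping_an_irrelevant_duplicate_of_noise(self):
        """A term with no true effect should rarely give an enormous LRT."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40)
        junk = rng.standard_normal(40)
        y = 1 + 2 * x + rng.standard_normal(40)
        full = egs.fit_gls(y, pd.DataFrame({"x": x, "junk": junk}),
                           100.0 * np.arange(40), structure="none")
        (t,) = egs.lrt_term_tests(full, drop_terms=["junk"])
        assert t.statistic < 10


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        i = np.arange(n)
        d = pd.DataFrame({"a": np.sin(2 * np.pi * i / n), "b": np.cos(2 * np.pi * i / n)})
        out = egs.vif(d)
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-10)
        assert not out["severe"].any()

    def test_duplicated_predictor_infinite_and_flagged(self):
        x = np.arange(20.0)
        out = egs.vif(pd.DataFrame({"a": x, "b": x.copy(), "c": np.sin(x)}))
        assert np.isinf(out.set_index("variable").loc["a", "vif"])
        assert out.set_index("variable").loc["a", "severe"]

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        z = rng.standard_normal(200)
        a = z + 0.75 * rng.standard_normal(200)
        b = z + 0.75 * rng.standard_normal(200)
        c = rng.standard_normal(200)
        d = pd.DataFrame({"a": a, "b": b, "c": c})
        out = egs.vif(d).set_index("variable")["vif"]
        X = d.to_numpy()
        for k, name in enumerate(d.columns):
            others = np.column_stack([np.ones(len(X)), np.delete(X, k, axis=1)])
            r2 = r_squared_of_regression(others, X[:, k])
            assert out[name] == pytest.approx(1.0 / (1.0 - r2), rel=1e-8)

    def test_matches_statsmodels(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(4)
        d = pd.DataFrame(rng.standard_normal((100, 3)), columns=["a", "b", "c"])
        d["b"] = d["a"] * 0.8 + 0.6 * d["b"]
        out = egs.vif(d).set_index("variable")["vif"]
        import statsmodels.api as sm

        X = sm.add_constant(d).to_numpy()
        for k, name in enumerate(d.columns):
            assert out[name] == pytest.approx(
                variance_inflation_factor(X, k + 1), rel=1e-8
            )

    def test_constant_column_rejected(self):
        with pytest.raises(ValidationError):
            egs.vif(pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)}))


# quasipoisson ANODEV fixture, frozen R reference (anova(..., test="F"))
ANODEV_Y = np.array([12, 9, 15, 7, 5, 8, 3, 2, 4, 1, 2, 1, 6, 10, 3, 2], float)
ANODEV_X1 = np.array([1.2, 0.8, 1.5, 0.9, 0.4, 0.7, 0.1, -0.2, 0.3, -0.5, -0.1,
                      -0.6, 0.5, 1.1, 0.0, -0.3])
ANODEV_X2 = np.array([0.3, -0.1, 0.2, 0.5, -0.4, 0.1, -0.2, 0.4, -0.3, 0.0, 0.2,
                      -0.5, 0.6, -0.6, 0.1, 0.3])


class TestAnodev:
    def test_matches_r_quasipoisson_table(self):
        out = egs.glm_poisson_anodev(
            ANODEV_Y, pd.DataFrame({"x1": ANODEV_X1, "x2": ANODEV_X2})
        )
        assert out["resid_deviance"].iloc[0] == pytest.approx(46.28200725, abs=1e-6)
        assert out["deviance"].iloc[1] == pytest.approx(44.48279387, abs=1e-6)
        assert out["deviance"].iloc[2] == pytest.approx(0.00387065, abs=1e-6)
        assert out["f_value"].iloc[1] == pytest.approx(321.78579, rel=1e-5)
        assert out["f_value"].iloc[2] == pytest.approx(0.02800, abs=1e-4)
        assert out["p_value"].iloc[1] == pytest.approx(1.4918e-10, rel=1e-3)
        assert out.attrs["dispersion"] == pytest.approx(0.1382372864, rel=1e-8)

    def test_sequential_deviances_sum_to_total_drop(self):
        out = egs.glm_poisson_anodev(
            ANODEV_Y, pd.DataFrame({"x1": ANODEV_X1, "x2": ANODEV_X2})
        )
        total = out["resid_deviance"].iloc[0] - out["resid_deviance"].iloc[-1]
        assert out["deviance"].iloc[1:].sum() == pytest.approx(total, abs=1e-10)

    def test_two_group_deviance_drop_matches_hand_formula(self):
        y = np.array([2.0, 2.0, 8.0, 8.0])
        g = pd.DataFrame({"grp": [0.0, 0.0, 1.0, 1.0]})
        out = egs.glm_poisson_anodev(y, g)
        null_dev = poisson_deviance(y, [5.0] * 4)           # grand mean 5
        full_dev = poisson_deviance(y, [2.0, 2.0, 8.0, 8.0])  # group means
        assert out["deviance"].iloc[1] == pytest.approx(null_dev - full_dev, abs=1e-8)

    def test_all_zero_counts_zero_deviance(self):
        out = egs.glm_poisson_anodev(
            np.zeros(8), pd.DataFrame({"x": np.arange(8.0)})
        )
        assert out["resid_deviance"].iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert out["resid_deviance"].iloc[-1] == pytest.approx(0.0, abs=1e-8)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            egs.glm_poisson_anodev(np.array([-1.0, 2.0]), pd.DataFrame({"x": [0.0, 1.0]}))


class TestResidualElevationFit:
    def test_exact_cubic_recovered(self):
        elev = 100.0 * np.arange(1, 50)
        rng = np.random.default_rng(2)
        area = np.exp(-elev / 2000) * 1000
        null = np.exp(-elev / 3000) * 10
        counts = rng.poisson(5.0, 49)
        fit = egs.residual_elevation_fit(counts, pd.DataFrame({"a": area, "n": null}), elev)
        z = (elev - elev.mean()) / elev.std()
        fake_resid = 0.3 * z**3 - 0.2 * z + 0.1
        import statsmodels.api as sm

        # feed the exact-cubic residuals through the same public path by
        # refitting: a cubic of elevation must give R^2 = 1
        V = np.vander(z, 4, increasing=True)
        Q, _ = np.linalg.qr(V)
        basis = Q[:, 1:] * np.sqrt(len(z))
        ols = sm.OLS(fake_resid, sm.add_constant(basis)).fit()
        assert ols.rsquared == pytest.approx(1.0, abs=1e-12)
        assert 0 <= fit.p_value <= 1 and len(fit.coefficients) == 3

    def test_constant_elevation_rejected(self):
        with pytest.raises(ValidationError):
            egs.residual_elevation_fit(
                np.arange(10.0), pd.DataFrame({"a": np.arange(10.0)}), np.full(10, 5.0)
            )

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError):
            egs.residual_elevation_fit(
                np.arange(4.0), pd.DataFrame({"a": np.arange(4.0)}), np.arange(4.0)
            )


class TestSplineSmooth:
    def test_linear_signal_reproduced(self):
        x = np.linspace(0, 10, 60)
        y = 2.0 + 0.5 * x
        fit = egs.spline_smooth(x, y, df=3)
        np.testing.assert_allclose(fit.fitted, y, atol=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_sine_recovery_on_fine_grid(self):
        x = np.linspace(0, 2 * np.pi, 200)
        y = np.sin(x)
        fit = egs.spline_smooth(x, y, df=6)
        ss_res = np.sum((y - fit.fitted) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.95
        assert fit.p_value < 1e-10

    def test_poisson_family_smooth(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 1, 80)
        y = rng.poisson(np.exp(1.0 + 0.8 * np.sin(2 * np.pi * x)))
        fit = egs.spline_smooth(x, y, df=4, family="poisson")
        assert fit.fitted.shape == y.shape
        assert np.all(fit.fitted > 0)
        assert 0 <= fit.p_value <= 1

    def test_overparameterized_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValidationError):
            egs.spline_smooth(x, x, df=5)

    def test_heavily_duplicated_x_rejected(self):
        x = np.repeat([0.0, 1.0], 10)
        with pytest.raises(ValidationError):
            egs.spline_smooth(x, np.arange(20.0), df=4)
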