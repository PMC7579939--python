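import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from axialgrowth import (
    ALGrowthModel,
    ALGrowthResults,
    RobustConfig,
    SingularDesignError,
    bisquare_weight,
    curved,
    fit_alternative,
    fit_ols,
    fit_robust,
    generate_cohort,
    main_effects,
    reference_linear_model,
)
from axialgrowth.cohort import default_cohort_spec
from axialgrowth.features import FeatureMap, MissingCovariateError


class TestReferenceModel:
    def test_intercept_only_evaluation(self, reference_model):
        assert reference_model.predict({"age": 0, "sex": 0, "ser": 0, "k_mean": 0}) == 40.31

    def test_hand_computed_prediction(self, reference_model):
        # 40.31 + 0.56 - 0.013 - 17.028 + 1.059
        got = reference_model.predict({"age": 10, "sex": 1, "k_mean": 43, "ser": -3})
        assert got == pytest.approx(24.888, abs=1e-12)

    def test_one_diopter_of_myopia_adds_0p353_mm(self, reference_model):
        base = {"age": 12, "sex": 0, "k_mean": 44, "ser": -2.0}
        more_myopic = dict(base, ser=-3.0)
        assert reference_model.predict(more_myopic) - reference_model.predict(base) == \
            pytest.approx(0.353, abs=1e-12)

    def test_prediction_deterministic(self, reference_model, small_cohort):
        a = reference_model.predict(small_cohort)
        b = reference_model.predict(small_cohort)
        np.testing.assert_array_equal(a, b)


class TestOLS:
    def test_exact_line(self):
        df = pd.DataFrame({"age": [1.0, 2.0, 3.0], "al": [2.0, 4.0, 6.0]})
        res = fit_ols(df, FeatureMap.from_names(["1", "age"]))
        np.testing.assert_allclose(res.params_array, [0.0, 2.0], atol=1e-12)
        assert res.sigma == pytest.approx(0.0, abs=1e-12)

    def test_identical_covariates_are_singular(self):
        df = pd.DataFrame({"age": [10.0] * 6, "sex": [1.0] * 6, "ser": [-3.0] * 6,
                           "k_mean": [43.0] * 6, "al": np.arange(6.0)})
        with pytest.raises(SingularDesignError):
            fit_ols(df)

    def test_all_zero_coefficients_predict_zero(self):
        res = ALGrowthResults(None, params=np.zeros(5), feature_map=main_effects())
        assert res.predict({"age": 9, "sex": 1, "ser": -2, "k_mean": 42}) == 0.0

    def test_matches_brute_force_minimizer(self, rng):
        """Normal-equation OLS agrees with direct numerical minimization of the
        squared loss on a small instance."""
        df = pd.DataFrame({
            "age": rng.uniform(6, 18, 40),
            "ser": rng.uniform(-8, 0, 40),
            "k_mean": rng.uniform(39, 47, 40),
        })
        df["al"] = 24 + 0.1 * df.age - 0.3 * df.ser + rng.normal(0, 0.3, 40)
        fm = FeatureMap.from_names(["1", "age", "ser", "k_mean"])
        res = fit_ols(df, fm)
        X = fm.design_matrix(df)
        y = df["al"].to_numpy()
        loss = lambda b: np.sum((y - X @ b) ** 2)
        brute = optimize.minimize(loss, np.zeros(4), method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 40000})
        np.testing.assert_allclose(res.params_array, brute.x, atol=1e-6)


class TestBisquare:
    def test_weight_properties_hold_for_any_residual(self):
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=200)
        @given(st.floats(allow_nan=False, allow_infinity=False, width=32))
        def check(u):
            w = bisquare_weight(u)
            assert 0.0 <= w <= 1.0
            assert w == bisquare_weight(-u)  # even function
            if abs(u) >= 1.0:
                assert w == 0.0

        check()

    @pytest.mark.parametrize("u, w", [(0.0, 1.0), (1.0, 0.0), (-2.5, 0.0),
                                      (0.5, 0.5625), (-0.5, 0.5625)])
    def test_values(self, u, w):
        assert bisquare_weight(u) == pytest.approx(w, abs=1e-15)

    def test_vectorized_range(self, rng):
        w = bisquare_weight(rng.normal(0, 2, 1000))
        assert np.all((w >= 0) & (w <= 1))


class TestRobust:
    def test_zero_noise_equals_ols(self, zero_noise_cohort):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate-scale note is expected
            rob = fit_robust(zero_noise_cohort)
        ols = fit_ols(zero_noise_cohort)
        np.testing.assert_allclose(rob.params_array, ols.params_array, atol=1e-10)

    def test_exactly_zero_residuals_fall_back_to_ols(self):
        """All residuals identical: the MAD scale is 0 and the guarded
        fallback returns the least-squares fit with a warning."""
        df = pd.DataFrame({"age": [1.0, 2.0, 3.0, 4.0]})
        df["al"] = 2.0 * df["age"]  # exact in floating point
        fm = FeatureMap.from_names(["1", "age"])
        with pytest.warns(UserWarning, match="scale is zero"):
            rob = fit_robust(df, fm)
        np.testing.assert_array_equal(rob.params_array, fit_ols(df, fm).params_array)
        assert rob.scale_degenerate

    def test_downweights_gross_outlier(self, rng):
        """On a known line plus one +10 mm outlier the robust fit stays near
        the truth, beats OLS, and gives the outlier essentially zero weight."""
        df = pd.DataFrame({"age": rng.uniform(6, 18, 100)})
        df["al"] = 22.0 + 0.2 * df.age + rng.normal(0, 0.05, 100)
        df.loc[0, "al"] += 10.0
        fm = FeatureMap.from_names(["1", "age"])
        rob, ols = fit_robust(df, fm), fit_ols(df, fm)
        truth = np.array([22.0, 0.2])
        assert np.abs(rob.params_array - truth).max() < np.abs(ols.params_array - truth).max()
        assert np.abs(rob.params_array - truth).max() < 0.05
        assert rob.weights[0] < 0.01
        assert rob.converged

    def test_weights_in_unit_interval_and_one_at_zero_residual(self, small_cohort):
        rob = fit_robust(small_cohort)
        assert np.all((rob.weights >= 0) & (rob.weights <= 1))
        resid = rob.resid()
        assert np.all(rob.weights[np.abs(resid) < 1e-12] == 1.0)

    def test_huge_tuning_constant_recovers_ols(self, small_cohort):
        rob = fit_robust(small_cohort, cfg=RobustConfig(tuning_constant=1e6))
        ols = fit_ols(small_cohort)
        np.testing.assert_allclose(rob.params_array, ols.params_array, atol=1e-10)

    def test_agrees_with_statsmodels_rlm(self):
        """Independent cross-check: statsmodels RLM with the same bisquare norm
        lands on essentially the same coefficients on contaminated data."""
        sm = pytest.importorskip("statsmodels.api")
        df = generate_cohort(default_cohort_spec(n=500, seed=11))
        rng = np.random.default_rng(2)
        df.loc[rng.choice(500, 25, replace=False), "al"] += 10.0
        mine = fit_robust(df)
        X = main_effects().design_matrix(df)
        theirs = sm.RLM(df["al"].to_numpy(), X,
                        M=sm.robust.norms.TukeyBiweight(4.685)).fit()
        np.testing.assert_allclose(mine.params_array, theirs.params, atol=5e-3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RobustConfig(tuning_constant=-1.0)


class TestCoefficientRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_noise_recovery_for_curved_map(self, seed):
        """Any linear-in-coefficients surface is recovered exactly from
        zero-noise data, by both OLS and IRLS."""
        fm = curved()
        rng = np.random.default_rng(seed)
        truth = rng.normal(0, 1, len(fm.terms))
        truth[0] += 24.0
        gen = ALGrowthResults(None, params=truth, feature_map=fm)
        spec = default_cohort_spec(n=200, seed=seed).with_(
            residual_sd=0.0, structural_model=gen)
        df = generate_cohort(spec)
        ols = fit_ols(df, fm)
        np.testing.assert_allclose(ols.params_array, truth, atol=1e-8)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-zero scale note is expected
            rob = fit_robust(df, fm)
        np.testing.assert_allclose(rob.params_array, truth, atol=1e-8)


class TestAlternativeMethods:
    def test_unknown_tag_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            fit_alternative(small_cohort, method_tag="kernel_ridge")

    def test_svr_linear_realizes_zero_noise_surface(self, zero_noise_cohort):
        res = fit_alternative(zero_noise_cohort, method_tag="svr_linear")
        err = np.abs(np.asarray(res.predict(zero_noise_cohort)) - zero_noise_cohort["al"])
        assert err.max() <= res.epsilon + 1e-5

    def test_bagged_single_stump_on_constant_target(self):
        df = pd.DataFrame({"age": np.linspace(6, 18, 30), "sex": 0.0, "ser": -3.0,
                           "k_mean": 43.0, "al": 24.5})
        res = fit_alternative(df, method_tag="bagged_trees", n_estimators=1,
                              min_samples_leaf=30)
        np.testing.assert_allclose(np.asarray(res.predict(df)), 24.5, atol=1e-12)

    def test_svr_quadratic_beats_linear_on_curved_data(self):
        fm = curved()
        coef = {"const": 20.0, "age": 0.4, "age^2": -0.012, "sex": 0.1, "ser": -0.3,
                "k_mean": 0.05, "age*ser": 0.0, "age*k_mean": 0.0, "age*sex": 0.0}
        gen = ALGrowthResults(None, params=np.array([coef[t] for t in fm.term_names]),
                              feature_map=fm)
        spec = default_cohort_spec(n=400, seed=3).with_(residual_sd=0.05,
                                                        structural_model=gen)
        df = generate_cohort(spec)
        train, test = df.iloc[:300], df.iloc[300:]
        mse = {}
        for tag in ("svr_linear", "svr_quadratic"):
            res = fit_alternative(train, method_tag=tag)
            mse[tag] = float(np.mean((np.asarray(res.predict(test)) - test["al"]) ** 2))
        assert mse["svr_quadratic"] < mse["svr_linear"]

    def test_opaque_predictors_refuse_serialization(self, small_cohort):
        res = fit_alternative(small_cohort, method_tag="bagged_trees")
        with pytest.raises(TypeError):
            res.to_json()


class TestResultsInterface:
    def test_missing_covariate_error_names_variable(self, reference_model):
        with pytest.raises(MissingCovariateError, match="ser"):
            reference_model.predict({"age": 10, "sex": 1, "k_mean": 43})

    def test_json_reload_is_bit_exact(self, small_cohort):
        res = fit_robust(small_cohort)
        back = ALGrowthResults.from_json(res.to_json())
        assert back.params_array.tolist() == res.params_array.tolist()
        assert back.sigma == res.sigma
        assert back.feature_map.term_names == res.feature_map.term_names
        assert back.robust_config == res.robust_config

    def test_summary_mentions_method_and_terms(self, small_cohort):
        res = fit_ols(small_cohort)
        text = res.summary()
        assert "ols" in text and "k_mean" in text

    def test_unknown_method_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            ALGrowthModel(small_cohort, method="lasso")
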