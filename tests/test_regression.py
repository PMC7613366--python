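"""Forward-MLR, diagnostics (Durbin-Watson, VIF), SVR tuning and metrics."""

import numpy as np
import pytest

from vitispec.regression import (FAST_SVR_GRID, ForwardSelectionMLR, SVRGrid,
                                 SVRGridSearch, durbin_watson, evaluate,
                                 fit_mlr_forward, tune_and_fit_svr,
                                 validate_mlr, vif)


class TestDurbinWatson:
    def test_constant_residuals_give_zero(self):
        assert durbin_watson([1.0, 1.0, 1.0]) == 0.0

    def test_alternating_residuals(self):
        # numerator 3*(2)^2 = 12, denominator 4
        assert durbin_watson([1, -1, 1, -1]) == pytest.approx(3.0)

    def test_iid_normal_residuals_near_two(self):
        rng = np.random.default_rng(0)
        d = durbin_watson(rng.standard_normal(10_000))
        assert 1.9 <= d <= 2.1

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        e = rng.standard_normal(50)
        for c in (-3.0, 0.01, 7.5):
            assert durbin_watson(c * e) == pytest.approx(durbin_watson(e),
                                                         rel=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.stattools import durbin_watson as sm_dw
        rng = np.random.default_rng(2)
        e = rng.standard_normal(200)
        assert durbin_watson(e) == pytest.approx(float(sm_dw(e)), rel=1e-12)

    def test_zero_residuals_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(durbin_watson([0.0, 0.0, 0.0]))


class TestVIF:
    def test_orthogonal_predictors_give_exactly_one(self):
        X = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        np.testing.assert_array_equal(vif(X), [1.0, 1.0])

    def test_duplicated_predictor_flagged_infinite(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20)
        assert np.isinf(vif(np.column_stack([x, x]))).all()

    def test_near_collinear_pair_exceeds_ten(self):
        rng = np.random.default_rng(4)
        x1 = rng.standard_normal(500)
        x2 = x1 + 0.04 * rng.standard_normal(500)  # rho ~ 0.999
        assert (vif(np.column_stack([x1, x2])) > 10).all()

    def test_single_predictor_rejected(self):
        with pytest.raises(ValueError):
            vif(np.ones((5, 1)))


class TestForwardMLR:
    def test_noiseless_selects_true_variable_with_exact_coefficients(self):
        rng = np.random.default_rng(5)
        x1 = rng.standard_normal(30)
        noise_var = rng.standard_normal(30)
        X = np.column_stack([x1, noise_var])
        y = 1.0 + 2.0 * x1
        res = fit_mlr_forward(X, y, var_names=["x1", "junk"])
        assert res.selected == ("x1",)
        assert res.intercept == pytest.approx(1.0, abs=1e-10)
        assert res.coefs[0] == pytest.approx(2.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_pure_noise_usually_yields_intercept_only(self):
        # best-of-5 candidate screening inflates the entry rate to about
        # 1-(1-alpha)^5, so the per-step alpha is divided by the
        # candidate count to keep the familywise entry rate near 5%
        hits = 0
        import warnings
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 5))
            y = rng.standard_normal(200)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_mlr_forward(X, y, alpha_enter=0.05 / 5)
            hits += len(res.selected) == 0
        assert hits >= 36  # >= 90% of replicates

    def test_duplicate_predictor_selected_once(self):
        rng = np.random.default_rng(6)
        x1 = rng.standard_normal(40)
        X = np.column_stack([x1, x1])
        y = x1 + 0.01 * rng.standard_normal(40)
        res = fit_mlr_forward(X, y, var_names=["a", "a_copy"])
        assert len(res.selected) == 1

    def test_force_all_equals_normal_equations_ols(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((25, 3))
        y = X @ [1.0, -2.0, 0.5] + 0.1 * rng.standard_normal(25)
        res = ForwardSelectionMLR(y, X).fit(force_all=True)
        A = np.column_stack([np.ones(25), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose([res.intercept, *res.coefs], beta,
                                   rtol=1e-9)

    def test_predict_matches_fitted(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 4))
        y = X[:, 0] - X[:, 2] + 0.05 * rng.standard_normal(30)
        res = fit_mlr_forward(X, y)
        np.testing.assert_allclose(res.predict(X), res.fittedvalues)


class TestValidity:
    def _fit(self, seed=9, n=60):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 3))
        y = X @ [1.0, 0.5, -0.8] + 0.1 * rng.standard_normal(n)
        return fit_mlr_forward(X, y)

    def test_well_behaved_model_passes_all_gates(self):
        rep = validate_mlr(self._fit())
        assert rep.dw_ok and rep.vif_ok and rep.significance_ok and rep.valid

    def test_autocorrelated_residuals_fail_dw_gate(self):
        n = 120
        t = np.arange(n)
        x = np.linspace(0, 1, n)
        # strong smooth residual structure -> d well below 1.5
        y = x + 0.5 * np.sin(t / 6)
        res = fit_mlr_forward(x.reshape(-1, 1), y)
        rep = validate_mlr(res)
        assert rep.dw < 1.5 and not rep.dw_ok
        assert not rep.valid

    def test_infinite_vif_fails_gate(self):
        rng = np.random.default_rng(10)
        x1 = rng.standard_normal(40)
        x2 = rng.standard_normal(40)
        X = np.column_stack([x1, x2])
        y = x1 + x2 + 0.05 * rng.standard_normal(40)
        res = ForwardSelectionMLR(y, np.column_stack([x1, x2, x1]),
                                  var_names=["a", "b", "a2"]).fit(
                                      force_all=True)
        rep = validate_mlr(res)
        assert not rep.vif_ok

    def test_dw_band_boundaries(self):
        rep = self._fit().validity(dw_band=(1.5, 2.5))
        assert rep.dw_ok == (1.5 <= rep.dw <= 2.5)


class TestSVR:
    def test_noiseless_linear_recovered_by_linear_kernel(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, (60, 3))
        y = X @ [1.0, -0.5, 0.25]
        grid = SVRGrid(kernels=("linear",), cost=(10.0, 100.0),
                       epsilon=(0.01,))
        res = tune_and_fit_svr(X[:40], y[:40], grid, v_folds=5, seed=0)
        m = evaluate(res, X[:40], y[:40], X[40:], y[40:])
        assert m.r2_test >= 0.99
        assert res.kernel == "linear"

    def test_support_vector_count_bounded(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, (50, 2))
        y = np.sin(3 * X[:, 0]) + 0.1 * rng.standard_normal(50)
        res = tune_and_fit_svr(X, y, FAST_SVR_GRID, v_folds=5, seed=0)
        assert 0 < res.n_support <= 50

    def test_deterministic_given_seed_and_grid(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 1, (40, 2))
        y = X[:, 0] + 0.2 * rng.standard_normal(40)
        a = tune_and_fit_svr(X, y, FAST_SVR_GRID, v_folds=5, seed=3)
        b = tune_and_fit_svr(X, y, FAST_SVR_GRID, v_folds=5, seed=3)
        assert a.config == b.config and a.cv_rmse == b.cv_rmse

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SVRGridSearch(np.zeros(5), np.zeros((5, 1)),
                          SVRGrid(kernels=())).fit(2, 0)

    def test_full_grid_covers_all_kernels(self):
        kernels = {c["kernel"] for c in SVRGrid().configurations()}
        assert kernels == {"linear", "rbf", "poly", "sigmoid"}


class TestEvaluate:
    class _Identity:
        def predict(self, X):
            return np.asarray(X)[:, 0]

    def test_perfect_predictions(self):
        y = np.array([0.0, 1.0, 2.0])
        m = evaluate(self._Identity(), y.reshape(-1, 1), y,
                     y.reshape(-1, 1), y)
        assert m.r2_train == 1.0 and m.rmse_train == 0.0

    def test_mean_prediction_gives_r2_zero(self):
        y = np.array([0.0, 1.0, 2.0])
        preds = np.full(3, 1.0)
        m = evaluate(self._Identity(), preds.reshape(-1, 1), y,
                     preds.reshape(-1, 1), y)
        assert m.r2_train == pytest.approx(0.0)

    def test_direct_rmse_value(self):
        y = np.array([0.0, 1.0, 2.0])
        yhat = np.array([0.0, 1.0, 3.0])
        m = evaluate(self._Identity(), yhat.reshape(-1, 1), y,
                     yhat.reshape(-1, 1), y)
        assert m.rmse_test == pytest.approx(np.sqrt(1 / 3))

    def test_original_unit_rmse_uses_scaler_range(self):
        from vitispec.preprocess import MinMaxScaler
        scaler = MinMaxScaler().fit(np.array([0.0, 20.0]))
        y = np.array([0.1, 0.5, 0.9])
        yhat = np.array([0.2, 0.5, 0.8])
        m = evaluate(self._Identity(), yhat.reshape(-1, 1), y,
                     yhat.reshape(-1, 1), y, y_scaler=scaler)
        assert m.rmse_test_original == pytest.approx(m.rmse_test * 20.0)

    def test_constant_observations_flagged(self):
        y = np.array([1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="R2 undefined"):
            m = evaluate(self._Identity(), y.reshape(-1, 1), y,
                         y.reshape(-1, 1), y)
        assert np.isnan(m.r2_train)
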