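"""PLS1 correctness against independent oracles.

Two independent routes check the NIPALS implementation: (i) brute-force
projection of the centered response onto the Krylov subspace
span{X'y, (X'X)X'y, ...}, which PLS1 fitted values must reproduce, and
(ii) scikit-learn's PLSRegression.  At full rank the fit must collapse
to ordinary least squares.
"""

import numpy as np
import pytest

from vitispec.pls import PLS1, choose_components, fit_pls1, select_variables


def krylov_fitted(X, y, k):
    """Oracle: projection of y onto the order-k Krylov subspace of (X'X, X'y).

    The basis {s, Gs, G^2 s, ...} is orthonormalised incrementally
    (Arnoldi-style) for numerical stability; raw powers of G are far too
    ill-conditioned beyond a few components.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    G = Xc.T @ Xc
    v = Xc.T @ yc
    basis = []
    for _ in range(k):
        for b in basis:  # modified Gram-Schmidt, twice for stability
            v = v - (b @ v) * b
        for b in basis:
            v = v - (b @ v) * b
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            break
        v = v / norm
        basis.append(v)
        v = G @ v
    K = np.column_stack(basis)
    B = Xc @ K
    alpha, *_ = np.linalg.lstsq(B, yc, rcond=None)
    return y.mean() + B @ alpha


def random_instance(rng, n=None, p=None):
    n = n or rng.integers(4, 11)
    p = p or rng.integers(2, 11)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + 0.3 * rng.standard_normal(n)
    return X, y


class TestNIPALSCore:
    def test_single_variable_noiseless_exact(self):
        x = np.linspace(0, 1, 10).reshape(-1, 1)
        y = 2.0 * x.ravel()
        res = fit_pls1(x, y, 1)
        np.testing.assert_allclose(res.fittedvalues, y, atol=1e-12)
        assert res.cumulative_y_variance == pytest.approx(100.0)

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng, n=20, p=8)
        res = fit_pls1(X, y, 5)
        T = res.scores
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.abs(off).max() < 1e-8 * np.abs(T).max() ** 2

    def test_explained_variances_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        X, y = random_instance(rng, n=25, p=6)
        res = fit_pls1(X, y, 5)
        assert (res.explained_x_variance >= -1e-10).all()
        assert res.cumulative_x_variance <= 100 + 1e-8
        assert res.cumulative_y_variance <= 100 + 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_krylov_oracle_any_k(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_instance(rng)
        k_max = min(X.shape[0] - 1, X.shape[1])
        for k in range(1, k_max + 1):
            res = fit_pls1(X, y, k)
            np.testing.assert_allclose(res.fittedvalues,
                                       krylov_fitted(X, y, k),
                                       rtol=1e-6, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_ols(self, seed):
        rng = np.random.default_rng(100 + seed)
        X, y = random_instance(rng, n=20, p=5)
        res = fit_pls1(X, y, 5)
        A = np.column_stack([np.ones(20), X])
        ols_fit = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(res.fittedvalues, ols_fit,
                                   rtol=1e-8, atol=1e-10)
        # explained y variance at full rank equals the OLS R^2
        sst = np.sum((y - y.mean()) ** 2)
        r2_ols = 1 - np.sum((y - ols_fit) ** 2) / sst
        assert res.cumulative_y_variance == pytest.approx(100 * r2_ols,
                                                          abs=1e-6)

    def test_matches_sklearn_predictions(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(7)
        X, y = random_instance(rng, n=30, p=12)
        for k in (1, 2, 4):
            ours = fit_pls1(X, y, k)
            ref = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(ours.predict(X),
                                       ref.predict(X).ravel(),
                                       rtol=1e-6, atol=1e-8)

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            PLS1(np.ones(5), np.random.default_rng(0).random((5, 3)))

    def test_excess_components_rejected(self):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng, n=6, p=3)
        with pytest.raises(ValueError, match="n_components"):
            PLS1(y, X).fit(4)


class TestChooseComponents:
    def test_single_latent_factor_yields_one_component(self):
        rng = np.random.default_rng(11)
        n, p = 100, 15
        t = rng.standard_normal(n)
        loadings = rng.standard_normal(p)
        X = np.outer(t, loadings) + 0.01 * rng.standard_normal((n, p))
        y = 2 * t + 0.01 * rng.standard_normal(n)
        assert choose_components(X, y, k_max=5, v_folds=10, seed=0) == 1

    def test_pure_noise_selects_near_minimal_complexity(self):
        # no spurious complexity: RMSECV of the chosen k stays within one
        # standard error of the k=1 solution
        rng = np.random.default_rng(12)
        n, p = 80, 10
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        k = choose_components(X, y, k_max=6, v_folds=10, seed=0)
        from sklearn.model_selection import KFold
        press = np.zeros(6)
        for tr, te in KFold(10, shuffle=True, random_state=0).split(X):
            model = PLS1(y[tr], X[tr])
            for kk in range(1, 7):
                err = y[te] - model.fit(kk).predict(X[te])
                press[kk - 1] += err @ err
        rmsecv = np.sqrt(press / n)
        se = rmsecv[0] / np.sqrt(2 * n)
        assert rmsecv[k - 1] <= rmsecv[0] + 3 * se

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        X, y = random_instance(rng, n=40, p=8)
        ks = {choose_components(X, y, k_max=5, v_folds=5, seed=9)
              for _ in range(3)}
        assert len(ks) == 1

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng, n=5, p=3)
        with pytest.raises(ValueError):
            choose_components(X, y, v_folds=10, seed=0)


class TestSelectVariables:
    def test_dominant_variable_selected_first(self):
        rng = np.random.default_rng(20)
        n = 50
        x1 = rng.standard_normal(n)
        X = np.column_stack([x1, 0.01 * rng.standard_normal((n, 3))])
        y = 3 * x1 + 0.01 * rng.standard_normal(n)
        sel = select_variables(fit_pls1(X, y, 1, var_names=list("abcd")))
        assert sel.names == ["a"]

    def test_dedupe_yields_runner_up(self):
        res = fit_pls1(np.random.default_rng(0).random((10, 3)),
                       np.random.default_rng(1).random(10), 2,
                       var_names=["u", "v", "w"])
        # force coincident max loadings
        res.x_loadings[:, 0] = [3.0, 2.0, 1.0]
        res.x_loadings[:, 1] = [3.0, 0.5, 1.0]
        sel = select_variables(res)
        assert sel.names == ["u", "w"]  # second component's max is taken

    def test_unique_selection_count_equals_components(self):
        rng = np.random.default_rng(21)
        X, y = random_instance(rng, n=30, p=10)
        sel = select_variables(fit_pls1(X, y, 4))
        assert len(sel.names) == len(set(sel.names)) == 4

    def test_wavelength_names_annotated_with_region(self):
        rng = np.random.default_rng(22)
        X, y = random_instance(rng, n=20, p=3)
        sel = select_variables(fit_pls1(X, y, 2,
                                        var_names=["R690", "R2000", "R550"]))
        regions = {v.name: v.region for v in sel.variables}
        for name, region in regions.items():
            assert region == {"R690": "RDE", "R2000": "MIR",
                              "R550": "VIS"}[name]

    def test_invariant_to_variable_permutation(self):
        rng = np.random.default_rng(23)
        X, y = random_instance(rng, n=30, p=6)
        names = [f"v{j}" for j in range(6)]
        sel = select_variables(fit_pls1(X, y, 3, var_names=names))
        perm = rng.permutation(6)
        sel_p = select_variables(
            fit_pls1(X[:, perm], y, 3, var_names=[names[j] for j in perm]))
        assert sel.names == sel_p.names

    def test_weights_variant_runs(self):
        rng = np.random.default_rng(24)
        X, y = random_instance(rng, n=20, p=5)
        res = fit_pls1(X, y, 2)
        sel_w = select_variables(res, use="weights")
        assert len(sel_w.names) == 2
        with pytest.raises(ValueError):
            select_variables(res, use="scores")
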