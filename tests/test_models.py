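"""PLS/SVR/RF contracts, with independent oracles for each fit."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.cross_decomposition import PLSRegression

import palmspec as ps
from palmspec._pls import cv_rmse_per_component, kfold_indices
from palmspec.models import default_svr_grids, refine_svr_grid


# ---------------------------------------------------------------------- PLS


def test_pls_perfect_linear_target(rng):
    """One latent variable suffices when the single channel carries the target."""
    X = rng.random((30, 1))
    y = 2.5 * X[:, 0] + 1.0
    m = ps.fit_pls(X, y, 1)
    assert ps.rmse(y, m.predict(X)) < 1e-8
    # with multiple channels, full rank recovers the exact linear map
    X6 = rng.random((30, 6))
    y6 = 2.5 * X6[:, 0] + 1.0
    m6 = ps.fit_pls(X6, y6, 6)
    assert ps.rmse(y6, m6.predict(X6)) < 1e-8


def test_pls_full_rank_equals_ols(rng):
    """PLS with as many components as the rank reproduces least squares."""
    X = rng.random((20, 5))
    y = rng.random(20)
    pls = ps.PLSRegressor(n_components=5).fit(X, y)
    # normal-equations oracle with intercept
    A = np.column_stack([np.ones(20), X])
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    ols_pred = A @ beta
    assert np.allclose(pls.predict(X), ols_pred, atol=1e-6)


def test_pls_matches_sklearn_predictions(rng):
    """Cross-check the SIMPLS engine against sklearn's NIPALS PLS."""
    X = rng.random((40, 12))
    y = X[:, 2] - 0.5 * X[:, 7] + 0.05 * rng.standard_normal(40)
    for k in (1, 2, 3, 5):
        ours = ps.PLSRegressor(n_components=k).fit(X, y)
        ref = PLSRegression(n_components=k, scale=False).fit(X, y.reshape(-1, 1))
        assert np.allclose(ours.predict(X), ref.predict(X).ravel(), atol=1e-8)


def test_pls_scores_orthogonal(rng):
    X = rng.random((30, 10))
    y = rng.random(30)
    m = ps.PLSRegressor(n_components=5).fit(X, y)
    G = m.x_scores_.T @ m.x_scores_
    assert np.allclose(G, np.eye(G.shape[0]), atol=1e-10)


def test_pls_constant_target_warns_and_predicts_mean(rng):
    X = rng.random((15, 4))
    y = np.full(15, 3.3)
    with pytest.warns(UserWarning, match="constant"):
        m = ps.PLSRegressor(n_components=2).fit(X, y)
    assert np.allclose(m.predict(X), 3.3, atol=1e-10)


def test_pls_affine_prediction(rng):
    X1, X2 = rng.random((10, 6)), rng.random((10, 6))
    y = rng.random(20)
    m = ps.PLSRegressor(n_components=3).fit(np.vstack([X1, X2]), y)
    a = 0.3
    mix = a * X1 + (1 - a) * X2
    assert np.allclose(m.predict(mix), a * m.predict(X1) + (1 - a) * m.predict(X2), atol=1e-10)


def test_pls_component_bounds(rng):
    X = rng.random((10, 4))
    with pytest.raises(ValueError):
        ps.PLSRegressor(n_components=11).fit(X, rng.random(10))
    m = ps.fit_pls(X, rng.random(10), 4)
    with pytest.raises(ValueError, match="variables"):
        m.predict(rng.random((3, 7)))


# -------------------------------------------------------- component choice


def test_choose_components_rank_two_structure(rng):
    """y built from two orthogonal score directions => CV picks 2."""
    n = 60
    t1, t2 = rng.standard_normal(n), rng.standard_normal(n)
    p1, p2 = rng.standard_normal(12), rng.standard_normal(12)
    X = np.outer(t1, p1) + np.outer(t2, p2) + 0.01 * rng.standard_normal((n, 12))
    y = t1 + 2.0 * t2
    assert ps.choose_pls_components(X, y, max_components=6) == 2


def test_choose_components_forced_single():
    rng = np.random.default_rng(0)
    X, y = rng.random((20, 5)), rng.random(20)
    assert ps.choose_pls_components(X, y, max_components=1) == 1


def test_cv_curve_matches_brute_force_oracle(rng):
    """Recompute the CV RMSE curve fold by fold with sklearn's PLS."""
    X = rng.random((25, 8))
    y = X[:, 1] + 0.3 * rng.standard_normal(25)
    curve = cv_rmse_per_component(X, y, max_components=4, n_folds=5)
    folds = kfold_indices(25, 5)
    for k in range(1, len(curve) + 1):
        sse = 0.0
        for test_idx in folds:
            mask = np.ones(25, dtype=bool)
            mask[test_idx] = False
            ref = PLSRegression(n_components=k, scale=False).fit(X[mask], y[mask].reshape(-1, 1))
            sse += float(np.sum((ref.predict(X[test_idx]).ravel() - y[test_idx]) ** 2))
        assert curve[k - 1] == pytest.approx(np.sqrt(sse / 25), abs=1e-8)


# ---------------------------------------------------------------------- SVR


def _rbf(A, B, gamma):
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
    return np.exp(-gamma * d2)


def _svr_dual_oracle(x_scaled, y_std, C, gamma, epsilon):
    """Solve the epsilon-SVR dual QP directly (beta_i = alpha_i - alpha_i*)."""
    K = _rbf(x_scaled, x_scaled, gamma)
    n = len(y_std)

    def neg_dual(beta):
        return 0.5 * beta @ K @ beta + epsilon * np.abs(beta).sum() - y_std @ beta

    res = minimize(
        neg_dual, np.zeros(n), method="SLSQP",
        bounds=[(-C, C)] * n,
        constraints=[{"type": "eq", "fun": lambda b: b.sum()}],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    beta = res.x
    # intercept from KKT at free (non-bound, non-zero) vectors
    free = (np.abs(beta) > 1e-8) & (np.abs(beta) < C - 1e-8)
    b_vals = y_std[free] - K[free] @ beta - np.sign(beta[free]) * epsilon
    b = b_vals.mean()
    return beta, b, K


def test_svr_pipeline_matches_qp_oracle():
    """Full pipeline (scale -> PCA -> RBF eps-SVR) vs a direct dual solve."""
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]).reshape(-1, 1)
    y = np.array([0.1, 0.9, 1.7, 2.2, 2.1, 1.4, 0.6, 0.0])
    C, gamma, epsilon = 10.0, 0.5, 0.1
    model = ps.RamanSVR(C=C, gamma=gamma, epsilon=epsilon, tol=1e-8).fit(x, y)

    # replicate the frozen transforms
    x_scaled = model.pca_.transform(model.scaler_.transform(x))
    y_std = (y - model.y_mean_) / model.y_std_
    beta, b, K = _svr_dual_oracle(x_scaled, y_std, C, gamma, epsilon)
    oracle_pred = (K @ beta + b) * model.y_std_ + model.y_mean_
    assert np.allclose(model.predict(x), oracle_pred, atol=1e-4)


def test_svr_training_points_within_epsilon_tube():
    """In the interpolable regime every non-support point sits inside the tube."""
    x = np.linspace(0, 7, 8).reshape(-1, 1)
    y = np.array([0.1, 0.9, 1.7, 2.2, 2.1, 1.4, 0.6, 0.0])
    model = ps.RamanSVR(C=1000.0, gamma=0.5, epsilon=0.1, tol=1e-8).fit(x, y)
    resid_std = np.abs(model.predict(x) - y) / model.y_std_
    assert np.all(resid_std <= 0.1 + 1e-6)


def test_svr_constant_target(rng):
    X = rng.random((12, 3))
    with pytest.warns(UserWarning, match="constant"):
        model = ps.RamanSVR().fit(X, np.full(12, 5.0))
    assert np.allclose(model.predict(X), 5.0, atol=0.1 + 1e-9)  # within epsilon


def test_svr_pca_retains_95_percent(rng):
    """PCA keeps the smallest k whose cumulative variance covers the target."""
    n = 80
    Z = rng.standard_normal((n, 3)) * np.array([10.0, 5.0, 2.0])
    mix = rng.standard_normal((3, 20))
    X = Z @ mix + 0.01 * rng.standard_normal((n, 20))
    y = Z[:, 0] + rng.standard_normal(n)
    model = ps.RamanSVR(pca_variance=0.95).fit(X, y)
    ratios = model.pca_.explained_variance_ratio_
    k = model.pca_.n_components_
    cum = np.cumsum(ratios)
    # eigenvalue bookkeeping oracle on the scaled matrix
    Xs = model.scaler_.transform(X)
    ev = np.linalg.svd(Xs - Xs.mean(0), compute_uv=False) ** 2
    full_cum = np.cumsum(ev / ev.sum())
    k_oracle = int(np.searchsorted(full_cum, 0.95) + 1)
    assert k == k_oracle
    assert cum[k - 1] >= 0.95 - 1e-12
    if k > 1:
        assert full_cum[k - 2] < 0.95


def test_svr_zero_variance_column_warns(rng):
    X = rng.random((20, 4))
    X[:, 2] = 3.14
    y = X[:, 0]
    with pytest.warns(UserWarning, match="zero-variance"):
        model = ps.RamanSVR().fit(X, y)
    assert np.all(model.scaler_.transform(X)[:, 2] == 0.0)


def test_svr_column_mismatch_errors(rng):
    X = rng.random((15, 4))
    model = ps.RamanSVR().fit(X, rng.random(15))
    with pytest.raises(ValueError, match="features"):
        model.predict(rng.random((2, 6)))


# -------------------------------------------------------------- grid search


def test_grid_search_single_cell(rng):
    X, y = rng.random((20, 3)), rng.random(20)
    C, g, surface = ps.grid_search_svr(X, y, [2.0], [0.25], cv_folds=4)
    assert (C, g) == (2.0, 0.25) and surface.shape == (1, 1)


def test_default_grids_bracket_reference_optimum():
    """The log2 grids bracket non-power-of-two optima such as
    C = 64.2548, gamma = 0.037062 (typical tuned values for this problem)."""
    C_grid, gamma_grid = default_svr_grids()
    assert np.any(np.abs(np.log2(C_grid) - np.log2(64.2548)) <= 1.0)
    assert np.any(np.abs(np.log2(gamma_grid) - np.log2(0.037062)) <= 1.0)
    assert C_grid[0] == 2.0**-4 and C_grid[-1] == 2.0**10
    assert gamma_grid[0] == 2.0**-10 and gamma_grid[-1] == 2.0**4


def test_grid_search_surface_minimum_recomputed(rng):
    X = rng.random((24, 4))
    y = X[:, 0] + 0.1 * rng.standard_normal(24)
    C_grid, gamma_grid = [1.0, 10.0], [0.1, 1.0]
    C, g, surface = ps.grid_search_svr(X, y, C_grid, gamma_grid, cv_folds=4)
    # independent recomputation at the argmin using the public CV pieces
    folds = kfold_indices(24, 4)
    sse = 0.0
    for test_idx in folds:
        mask = np.ones(24, dtype=bool)
        mask[test_idx] = False
        m = ps.RamanSVR(C=C, gamma=g, epsilon=0.1).fit(X[mask], y[mask])
        sse += float(np.sum((m.predict(X[test_idx]) - y[test_idx]) ** 2))
    assert surface.min() == pytest.approx(np.sqrt(sse / 24), abs=1e-10)


def test_refinement_brackets_by_factor_two(rng):
    X = rng.random((24, 4))
    y = X[:, 0] + 0.1 * rng.standard_normal(24)
    C, g, surface = refine_svr_grid(X, y, 4.0, 0.25, cv_folds=4, n_points=5)
    assert 2.0 - 1e-9 <= C <= 8.0 + 1e-9
    assert 0.125 - 1e-9 <= g <= 0.5 + 1e-9
    assert surface.shape == (5, 5)


# ----------------------------------------------------------------------- RF


def test_rf_single_tree_full_leaf_predicts_mean(rng):
    X = rng.random((12, 3))
    y = rng.random(12)
    spec = ps.ModelSpec(algorithm="RF", n_trees=1, min_leaf=12)
    m = ps.fit_rf(X, y, spec, seed=0)
    # one tree, leaf >= n: every prediction is that tree's bootstrap mean
    preds = m.predict(X)
    assert np.allclose(preds, preds[0])


def test_rf_deterministic_per_seed(rng):
    X = rng.random((60, 10))
    y = X[:, 0] + rng.standard_normal(60) * 0.1
    a = ps.fit_rf(X, y, seed=5).predict(X)
    b = ps.fit_rf(X, y, seed=5).predict(X)
    c = ps.fit_rf(X, y, seed=6).predict(X)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_rf_ensemble_beats_single_tree_on_step_target(rng):
    x = np.sort(rng.uniform(0, 1, 200)).reshape(-1, 1)
    y = (x.ravel() > 0.5).astype(float) + 0.2 * rng.standard_normal(200)
    x_test = rng.uniform(0, 1, 200).reshape(-1, 1)
    y_test = (x_test.ravel() > 0.5).astype(float)
    forest = ps.fit_rf(x, y, ps.ModelSpec(algorithm="RF", n_trees=250, min_leaf=10), seed=1)
    single = ps.fit_rf(x, y, ps.ModelSpec(algorithm="RF", n_trees=1, min_leaf=10), seed=1)
    assert ps.rmse(y_test, forest.predict(x_test)) < ps.rmse(y_test, single.predict(x_test))


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ps.ModelSpec(algorithm="GBM")
    with pytest.raises(ValueError):
        ps.ModelSpec(C=-1.0)
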