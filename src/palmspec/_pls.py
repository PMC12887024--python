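"""Internal SIMPLS engine and cross-validation helpers.

The wavelength selectors (CARS, UVE, GA) need on the order of 10^5 small
PLS fits, so the engine is a non-iterative SIMPLS (de Jong 1993) written in
numpy that returns the regression coefficients for *every* nested component
count 1..k in one pass. Data are mean-centred only; spectra share units, so
autoscaling would inflate noise channels. The public PLS estimator in
:mod:`palmspec.models` wraps this engine; sklearn's PLSRegression serves
only as an independent cross-check in the test suite.
"""

from __future__ import annotations

import numpy as np


def simpls(X: np.ndarray, y: np.ndarray, n_components: int):
    """SIMPLS fit returning nested coefficients for all component counts.

    Returns
    -------
    B : ndarray, shape (k, p)
        Row ``j`` holds the centred-data regression vector using ``j + 1``
        latent variables (k may be < n_components if X is rank deficient).
    x_mean : ndarray, shape (p,)
    y_mean : float
    T : ndarray, shape (n, k)
        X scores (orthonormal columns).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size} entries")
    k_max = min(n_components, n - 1, p)
    if k_max < 1:
        raise ValueError(f"cannot fit {n_components} components to a {n}x{p} matrix")

    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    X0 = X - x_mean
    y0 = y - y_mean

    s = X0.T @ y0  # p
    R = np.zeros((p, k_max))  # weight vectors (coefficients basis)
    V = np.zeros((p, k_max))  # orthonormal loading basis for deflation
    Q = np.zeros(k_max)  # y loadings
    T = np.zeros((n, k_max))

    k = 0
    for j in range(k_max):
        r = s.copy()
        t = X0 @ r
        t -= t.mean()
        norm_t = np.linalg.norm(t)
        if norm_t < 1e-12 * max(1.0, np.linalg.norm(y0)) or not np.isfinite(norm_t):
            break  # rank exhausted
        t /= norm_t
        r /= norm_t
        p_load = X0.T @ t
        q = float(y0 @ t)
        v = p_load.copy()
        if j > 0:
            v -= V[:, :j] @ (V[:, :j].T @ p_load)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            break
        v /= nv
        s = s - v * (v @ s)
        R[:, j] = r
        V[:, j] = v
        Q[j] = q
        T[:, j] = t
        k += 1

    if k == 0:
        # X carries no usable variance: fall back to the mean model
        return np.zeros((1, p)), x_mean, y_mean, np.zeros((n, 1))
    B = np.cumsum(R[:, :k] * Q[:k], axis=1).T  # (k, p)
    return B, x_mean, y_mean, T[:, :k]


def simpls_predict(X_new: np.ndarray, B: np.ndarray, x_mean: np.ndarray, y_mean: float) -> np.ndarray:
    """Predictions for every nested component count; shape (k, n_new)."""
    X_new = np.asarray(X_new, dtype=float)
    return (X_new - x_mean) @ B.T + y_mean  # (n_new, k)


def kfold_indices(n: int, n_folds: int, rng: np.random.Generator | None = None):
    """Deterministic contiguous K-fold assignment (shuffled when rng given)."""
    order = np.arange(n)
    if rng is not None:
        order = rng.permutation(n)
    return [order[i::n_folds] for i in range(n_folds)]


def cv_rmse_per_component(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Cross-validated RMSE for each component count 1..k in one pass per fold.

    SIMPLS yields every nested model from a single fit, so choosing the
    latent-variable count by CV costs no more than one CV run at the
    maximum count. Folds are contiguous and deterministic unless an rng is
    supplied. Returns an array of length k (k <= max_components when rank
    limits bite); index j is the RMSE with j+1 components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"need 2 <= n_folds <= n, got {n_folds} folds for n={n}")
    folds = kfold_indices(n, n_folds, rng)
    k_cap = min(max_components, n - max(len(f) for f in folds) - 1, X.shape[1])
    k_cap = max(k_cap, 1)
    sse = np.zeros(k_cap)
    count = np.zeros(k_cap)
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        B, xm, ym, _ = simpls(X[mask], y[mask], k_cap)
        pred = simpls_predict(X[test_idx], B, xm, ym)  # (n_test, k_fit)
        k_fit = pred.shape[1]
        err = pred - y[test_idx, None]
        sse[:k_fit] += np.sum(err**2, axis=0)
        if k_fit < k_cap:  # rank-deficient fold: reuse the deepest model
            sse[k_fit:] += np.sum(err[:, -1] ** 2)
            count[k_fit:] += test_idx.size
        count[:k_fit] += test_idx.size
    return np.sqrt(sse / count)


def choose_components_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> int:
    """Latent-variable count with minimal CV RMSE; ties go to the smaller count."""
    rmse = cv_rmse_per_component(X, y, max_components, n_folds, rng)
    return int(np.argmin(rmse)) + 1


def min_cv_rmse(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> float:
    """The CV RMSE of the best component count (the selectors' fitness)."""
    return float(np.min(cv_rmse_per_component(X, y, max_components, n_folds, rng)))
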