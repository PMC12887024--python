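"""PLS, epsilon-SVR (RBF) and random-forest regressors behind one contract.

The three algorithms mirror the study's modelling grid:

* PLS — SIMPLS on mean-centred data, latent-variable count chosen by CV;
* SVR — per-variable scaling of the spectra to [-1, 1], PCA keeping 95% of
  the variance, then epsilon-SVR with an RBF kernel, tuned by an exhaustive
  log2 grid over (C, gamma) plus one local refinement pass;
* RF — 250 bootstrap trees, minimum leaf size 10, mtry = floor(p/3).

All fitted state (scaling ranges, PCA loadings, target standardisation) is
frozen at fit time and replayed at prediction, and every fit records the
variable subset it was trained on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from ._pls import (
    choose_components_cv,
    cv_rmse_per_component,
    kfold_indices,
    simpls,
    simpls_predict,
)

__all__ = [
    "ModelSpec",
    "FittedModel",
    "PLSRegressor",
    "RamanSVR",
    "fit_pls",
    "choose_pls_components",
    "fit_svr",
    "grid_search_svr",
    "refine_svr_grid",
    "default_svr_grids",
    "fit_rf",
    "predict",
]


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm identity plus hyperparameters for one model row."""

    algorithm: str = "PLS"  # PLS | SVM | RF
    n_components: int = 10  # PLS: maximum latent variables offered to CV
    C: float = 1.0
    gamma: float = 0.1
    epsilon: float = 0.1  # on the standardised target
    n_trees: int = 250
    min_leaf: int = 10
    svm_scale_range: tuple[float, float] = (-1.0, 1.0)
    svm_pca_variance: float = 0.95

    def __post_init__(self) -> None:
        if self.algorithm not in ("PLS", "SVM", "RF"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if min(self.n_components, self.n_trees, self.min_leaf) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.C, self.gamma, self.epsilon) <= 0:
            raise ValueError("C, gamma and epsilon must be positive")
        if not 0 < self.svm_pca_variance <= 1:
            raise ValueError("svm_pca_variance must lie in (0, 1]")


@dataclass
class FittedModel:
    """Trained estimator + the bookkeeping needed to predict honestly."""

    spec: ModelSpec
    estimator: Any
    variable_subset: np.ndarray | None = None  # indices into the full grid
    n_features: int = 0
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.n_features:
            raise ValueError(
                f"model was trained on {self.n_features} variables but got {X_new.shape[1]}"
            )
        return np.asarray(self.estimator.predict(X_new), dtype=float).ravel()


def predict(model: FittedModel, X_new: np.ndarray) -> np.ndarray:
    """Reference-unit predictions for new spectra (column count must match)."""
    return model.predict(X_new)


# ------------------------------------------------------------------- PLS


class PLSRegressor(RegressorMixin, BaseEstimator):
    """SIMPLS partial least squares with mean centring only.

    Fitted attributes: ``coef_`` (p,), ``intercept_``, ``x_scores_`` with
    orthonormal columns, and ``n_components_`` (may be below the requested
    count when the data rank is exhausted).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if self.n_components < 1:
            raise ValueError(f"n_components must be >= 1, got {self.n_components}")
        if self.n_components > min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(
                f"n_components={self.n_components} too large for {X.shape[0]}x{X.shape[1]} data"
            )
        if np.ptp(y) == 0:
            warnings.warn("target is constant; PLS reduces to the mean model", stacklevel=2)
        B, xm, ym, T = simpls(X, y, self.n_components)
        self.n_components_ = B.shape[0]
        self.coef_ = B[-1]
        self.x_mean_ = xm
        self.y_mean_ = ym
        self.intercept_ = ym - xm @ self.coef_
        self.x_scores_ = T
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return X @ self.coef_ + self.intercept_


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> FittedModel:
    """Fit PLS with a fixed latent-variable count."""
    est = PLSRegressor(n_components=n_components).fit(X, y)
    return FittedModel(
        spec=ModelSpec(algorithm="PLS", n_components=n_components),
        estimator=est,
        n_features=X.shape[1],
        extra={"n_components_used": est.n_components_},
    )


def choose_pls_components(
    X: np.ndarray, y: np.ndarray, max_components: int = 10, cv_folds: int = 5
) -> int:
    """Latent-variable count minimising CV RMSE (ties -> smallest count)."""
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    return choose_components_cv(X, y, max_components, cv_folds)


# ------------------------------------------------------------------- SVR


class _SymmetricMinMax:
    """Per-variable linear map of the training range onto [lo, hi].

    A zero-variance variable maps to 0 (with a warning) instead of an
    arbitrary endpoint, so dead channels cannot steer the RBF kernel.
    """

    def __init__(self, feature_range=(-1.0, 1.0)):
        self.lo, self.hi = feature_range

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        span = self.data_max_ - self.data_min_
        self.degenerate_ = span == 0
        if np.any(self.degenerate_):
            warnings.warn(
                f"{int(self.degenerate_.sum())} zero-variance variable(s) mapped to 0",
                stacklevel=2,
            )
        self.scale_ = np.where(self.degenerate_, 0.0, (self.hi - self.lo) / np.where(span == 0, 1.0, span))
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return self.lo + (X - self.data_min_) * self.scale_ + self.degenerate_ * (0.0 - self.lo)


class RamanSVR(RegressorMixin, BaseEstimator):
    """Scaling -> PCA(variance kept) -> epsilon-SVR(RBF), target standardised.

    ``epsilon`` is interpreted on the standardised target, so its default
    (0.1) means a tenth of a target standard deviation regardless of
    whether the unit is meq O2/kg or g I2/100 g.
    """

    def __init__(self, C: float = 1.0, gamma: float = 0.1, epsilon: float = 0.1,
                 scale_range: tuple[float, float] = (-1.0, 1.0), pca_variance: float = 0.95,
                 tol: float = 1e-3):
        self.C = C
        self.gamma = gamma
        self.epsilon = epsilon
        self.scale_range = scale_range
        self.pca_variance = pca_variance
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.scaler_ = _SymmetricMinMax(self.scale_range).fit(X)
        Xs = self.scaler_.transform(X)
        n_max = min(Xs.shape)
        if self.pca_variance >= 1.0:
            self.pca_ = PCA(n_components=n_max, svd_solver="full")
        else:
            # PCA(float) keeps the smallest k with cumulative variance >= target
            self.pca_ = PCA(n_components=min(self.pca_variance, 1.0 - 1e-12), svd_solver="full")
        Xp = self.pca_.fit_transform(Xs)
        self.y_mean_ = y.mean()
        self.y_std_ = y.std(ddof=0)
        if self.y_std_ == 0:
            self.y_std_ = 1.0
            warnings.warn("constant target; SVR fit on raw residuals", stacklevel=2)
        ys = (y - self.y_mean_) / self.y_std_
        self.svr_ = SVR(kernel="rbf", C=self.C, gamma=self.gamma, epsilon=self.epsilon,
                        tol=self.tol)
        self.svr_.fit(Xp, ys)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "svr_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        Xp = self.pca_.transform(self.scaler_.transform(X))
        return self.svr_.predict(Xp) * self.y_std_ + self.y_mean_


def fit_svr(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> FittedModel:
    est = RamanSVR(
        C=spec.C, gamma=spec.gamma, epsilon=spec.epsilon,
        scale_range=spec.svm_scale_range, pca_variance=spec.svm_pca_variance,
    ).fit(X, y)
    return FittedModel(spec=spec, estimator=est, n_features=X.shape[1],
                       extra={"n_pca_components": int(est.pca_.n_components_)})


def default_svr_grids() -> tuple[np.ndarray, np.ndarray]:
    """Log2-spaced search grids: C in 2^-4..2^10, gamma in 2^-10..2^4."""
    return 2.0 ** np.arange(-4, 11), 2.0 ** np.arange(-10, 5)


def _svr_cv_rmse(X, y, C, gamma, epsilon, folds, spec: ModelSpec) -> float:
    n = X.shape[0]
    sse = 0.0
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        est = RamanSVR(C=C, gamma=gamma, epsilon=epsilon,
                       scale_range=spec.svm_scale_range,
                       pca_variance=spec.svm_pca_variance).fit(X[mask], y[mask])
        sse += float(np.sum((est.predict(X[test_idx]) - y[test_idx]) ** 2))
    return float(np.sqrt(sse / n))


def grid_search_svr(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: np.ndarray | None = None,
    gamma_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    epsilon: float = 0.1,
    spec: ModelSpec | None = None,
):
    """Exhaustive CV over the (C, gamma) grid.

    Returns ``(C, gamma, surface)`` where ``surface[i, j]`` is the CV RMSE
    at ``(C_grid[i], gamma_grid[j])`` — the data behind the study's 3-D
    response plots. Ties break to the smallest C, then the smallest gamma.
    """
    if C_grid is None or gamma_grid is None:
        dC, dG = default_svr_grids()
        C_grid = dC if C_grid is None else np.asarray(C_grid, dtype=float)
        gamma_grid = dG if gamma_grid is None else np.asarray(gamma_grid, dtype=float)
    C_grid = np.asarray(C_grid, dtype=float)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if C_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("search grids must be non-empty")
    spec = spec or ModelSpec(algorithm="SVM")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    folds = kfold_indices(X.shape[0], cv_folds)
    surface = np.empty((C_grid.size, gamma_grid.size))
    for i, C in enumerate(C_grid):
        for j, g in enumerate(gamma_grid):
            surface[i, j] = _svr_cv_rmse(X, y, C, g, epsilon, folds, spec)
    i, j = np.unravel_index(np.argmin(surface), surface.shape)  # first = smallest C then gamma
    return float(C_grid[i]), float(gamma_grid[j]), surface


def refine_svr_grid(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    cv_folds: int = 5,
    epsilon: float = 0.1,
    n_points: int = 5,
    spec: ModelSpec | None = None,
):
    """One local refinement pass: factor-2 bracket around the coarse optimum.

    Log-spaced ``n_points`` per axis between optimum/2 and optimum*2, so
    non-power-of-two optima (e.g. C near 64.25) are expressible.
    """
    C_grid = np.geomspace(C / 2.0, C * 2.0, n_points)
    gamma_grid = np.geomspace(gamma / 2.0, gamma * 2.0, n_points)
    return grid_search_svr(X, y, C_grid, gamma_grid, cv_folds, epsilon, spec)


# -------------------------------------------------------------------- RF


def fit_rf(X: np.ndarray, y: np.ndarray, spec: ModelSpec | None = None, seed: int = 0) -> FittedModel:
    """Bootstrap forest: 250 trees, min leaf 10, mtry = max(1, floor(p/3))."""
    spec = spec or ModelSpec(algorithm="RF")
    X = np.asarray(X, dtype=float)
    mtry = max(1, X.shape[1] // 3)
    est = RandomForestRegressor(
        n_estimators=spec.n_trees,
        min_samples_leaf=spec.min_leaf,
        max_features=mtry,
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    ).fit(X, np.asarray(y, dtype=float).ravel())
    return FittedModel(spec=spec, estimator=est, n_features=X.shape[1], seed=seed)


def pls_cv_rmse_curve(X, y, max_components: int = 10, cv_folds: int = 5) -> np.ndarray:
    """Public alias for the per-component CV RMSE curve (diagnostics export)."""
    return cv_rmse_per_component(X, y, max_components, cv_folds)
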