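"""Spectral conditioning: baseline removal, normalisation, smoothing, derivatives.

All operations are exposed twice: as plain functions on 1-D/2-D intensity
arrays, and as stateless scikit-learn transformers so they drop into
``sklearn.pipeline.Pipeline``. Derivatives are scaled by the grid spacing,
i.e. returned in intensity units per (cm^-1)^order rather than per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectralDataset

PREPROCESS_METHODS = (
    "raw",
    "baseline_norm",
    "sg_smooth",
    "first_derivative",
    "second_derivative",
    "wavelet_denoise",
)


@dataclass(frozen=True)
class PreprocessConfig:
    """One named preprocessing recipe.

    ``baseline_first`` controls whether derivative methods run on
    baseline-corrected rather than raw spectra (derivatives remove smooth
    baselines by themselves, so the default is off).
    """

    method: str = "second_derivative"
    window: int = 15
    polyorder: int = 3
    wavelet_name: str = "sym8"
    decomposition_level: int = 4
    threshold_rule: str = "universal_soft"
    baseline_lambda: float = 1e5
    baseline_p: float = 0.01
    normalization: str = "vector"
    baseline_first: bool = False

    def __post_init__(self) -> None:
        if self.method not in PREPROCESS_METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {PREPROCESS_METHODS}")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError(
                f"window must be odd and > polyorder, got window={self.window}, polyorder={self.polyorder}"
            )
        deriv = {"first_derivative": 1, "second_derivative": 2}.get(self.method, 0)
        if self.polyorder < deriv:
            raise ValueError(f"polyorder {self.polyorder} < derivative order {deriv}")
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        if self.threshold_rule not in ("universal_soft", "universal_hard"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")
        if self.normalization not in ("vector", "area", "minmax"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


# --------------------------------------------------------------- primitives


def als_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01, n_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate (Whittaker smoother).

    Points above the running baseline get weight ``p``, points below get
    ``1 - p``, so the fit hugs the spectrum's lower envelope; ``lam``
    penalises baseline curvature.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if not 0 < p < 1:
        raise ValueError(f"asymmetry p must lie in (0, 1), got {p}")
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        W = sparse.diags(w, format="csc")
        z = spsolve(W + penalty, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def baseline_correct(intensities: np.ndarray, lam: float = 1e5, p: float = 0.01) -> np.ndarray:
    """Subtract the ALS-estimated baseline (rowwise for 2-D input)."""
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim == 1:
        return arr - als_baseline(arr, lam, p)
    return np.vstack([row - als_baseline(row, lam, p) for row in arr])


def normalize(intensities: np.ndarray, mode: str = "vector", grid: np.ndarray | None = None) -> np.ndarray:
    """Normalise each spectrum: unit L2 norm, unit trapezoid area, or [0, 1] range.

    Area mode needs the wavenumber grid for the integral; a degenerate
    spectrum (zero norm / zero area / constant) is an error.
    """
    arr = np.atleast_2d(np.asarray(intensities, dtype=float))
    if mode == "vector":
        scale = np.linalg.norm(arr, axis=1)
        if np.any(scale == 0):
            raise ValueError("cannot vector-normalise an all-zero spectrum")
        out = arr / scale[:, None]
    elif mode == "area":
        if grid is None:
            raise ValueError("area normalisation requires the wavenumber grid")
        area = np.trapezoid(arr, x=np.asarray(grid, dtype=float), axis=1)
        if np.any(area == 0):
            raise ValueError("cannot area-normalise a zero-area spectrum")
        out = arr / area[:, None]
    elif mode == "minmax":
        lo = arr.min(axis=1, keepdims=True)
        hi = arr.max(axis=1, keepdims=True)
        rng = hi - lo
        if np.any(rng == 0):
            raise ValueError("cannot min-max normalise a constant spectrum")
        out = (arr - lo) / rng
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return out[0] if np.asarray(intensities).ndim == 1 else out


def savgol(
    intensities: np.ndarray,
    window: int = 15,
    polyorder: int = 3,
    deriv_order: int = 0,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / differentiation.

    ``delta`` is the grid spacing in cm^-1, so derivative output is in
    intensity units per (cm^-1)^deriv_order. Edges are handled by
    polynomial fits on one-sided windows (``mode='interp'``), keeping the
    channel count unchanged.
    """
    arr = np.asarray(intensities, dtype=float)
    n = arr.shape[-1]
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window >= n:
        raise ValueError(f"window {window} must be smaller than spectrum length {n}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if deriv_order not in (0, 1, 2):
        raise ValueError(f"deriv_order must be 0, 1 or 2, got {deriv_order}")
    if deriv_order > polyorder:
        raise ValueError(f"deriv_order {deriv_order} exceeds polyorder {polyorder}")
    return savgol_filter(
        arr, window_length=window, polyorder=polyorder, deriv=deriv_order,
        delta=delta, axis=-1, mode="interp",
    )


def wavelet_denoise(
    intensities: np.ndarray,
    wavelet_name: str = "sym8",
    level: int = 4,
    rule: str = "universal_soft",
    threshold: float | None = None,
) -> np.ndarray:
    """Multilevel wavelet shrinkage with the universal threshold.

    The noise scale is estimated from the finest detail coefficients as
    MAD/0.6745 and the threshold is sigma * sqrt(2 ln n) (Donoho-Johnstone),
    applied soft or hard to all detail levels. ``threshold`` overrides the
    estimate (0 gives perfect reconstruction, useful as an identity check).
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim == 1:
        return _wavelet_denoise_1d(arr, wavelet_name, level, rule, threshold)
    return np.vstack([_wavelet_denoise_1d(row, wavelet_name, level, rule, threshold) for row in arr])


def _wavelet_denoise_1d(y, wavelet_name, level, rule, threshold):
    n = y.size
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet_name).dec_len)
    if level < 1 or level > max_level:
        raise ValueError(f"level {level} infeasible for length {n} with {wavelet_name} (max {max_level})")
    coeffs = pywt.wavedec(y, wavelet_name, level=level)
    if threshold is None:
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
        threshold = sigma * np.sqrt(2.0 * np.log(n))
    mode = "soft" if rule == "universal_soft" else "hard"
    if threshold > 0:
        coeffs[1:] = [pywt.threshold(c, threshold, mode=mode) for c in coeffs[1:]]
    return pywt.waverec(coeffs, wavelet_name)[:n]


# ------------------------------------------------------ sklearn transformers


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """SG smoothing or differentiation as a stateless sklearn transformer."""

    def __init__(self, window: int = 15, polyorder: int = 3, deriv_order: int = 0, delta: float = 1.0):
        self.window = window
        self.polyorder = polyorder
        self.deriv_order = deriv_order
        self.delta = delta

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return savgol(X, self.window, self.polyorder, self.deriv_order, self.delta)


class WaveletDenoiser(TransformerMixin, BaseEstimator):
    def __init__(self, wavelet_name: str = "sym8", level: int = 4, rule: str = "universal_soft"):
        self.wavelet_name = wavelet_name
        self.level = level
        self.rule = rule

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return wavelet_denoise(X, self.wavelet_name, self.level, self.rule)


class BaselineNormalizer(TransformerMixin, BaseEstimator):
    """ALS baseline removal followed by per-spectrum normalisation."""

    def __init__(self, lam: float = 1e5, p: float = 0.01, mode: str = "vector",
                 grid: np.ndarray | None = None):
        self.lam = lam
        self.p = p
        self.mode = mode
        self.grid = grid

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return normalize(baseline_correct(X, self.lam, self.p), self.mode, self.grid)


# -------------------------------------------------------------- dataset API


def apply_preprocessing(dataset: SpectralDataset, config: PreprocessConfig) -> SpectralDataset:
    """Apply one named recipe to every spectrum; records the config in metadata.

    ``method='raw'`` returns an identical copy (the control arm of the
    preprocessing comparison).
    """
    out = dataset.copy()
    X = out.intensities
    delta = float(np.mean(np.diff(out.wavenumbers)))

    if config.baseline_first and config.method in ("first_derivative", "second_derivative", "sg_smooth"):
        X = baseline_correct(X, config.baseline_lambda, config.baseline_p)

    if config.method == "raw":
        pass
    elif config.method == "baseline_norm":
        X = baseline_correct(X, config.baseline_lambda, config.baseline_p)
        X = normalize(X, config.normalization, out.wavenumbers)
    elif config.method == "sg_smooth":
        X = savgol(X, config.window, config.polyorder, 0, delta)
    elif config.method == "first_derivative":
        X = savgol(X, config.window, config.polyorder, 1, delta)
    elif config.method == "second_derivative":
        X = savgol(X, config.window, config.polyorder, 2, delta)
    elif config.method == "wavelet_denoise":
        X = wavelet_denoise(X, config.wavelet_name, config.decomposition_level, config.threshold_rule)
    else:  # pragma: no cover - guarded by PreprocessConfig
        raise ValueError(f"unknown method {config.method!r}")

    out.intensities = np.asarray(X, dtype=float)
    out.metadata = dict(out.metadata)
    out.metadata["preprocessing"] = {
        k: getattr(config, k) for k in config.__dataclass_fields__
    }
    return out


def make_preprocessor(config: PreprocessConfig, delta: float = 1.0, grid: np.ndarray | None = None):
    """Sklearn transformer equivalent of :func:`apply_preprocessing`'s method arm."""
    if config.method == "raw":
        return FunctionIdentity()
    if config.method == "baseline_norm":
        return BaselineNormalizer(config.baseline_lambda, config.baseline_p, config.normalization, grid)
    if config.method == "sg_smooth":
        return SavitzkyGolay(config.window, config.polyorder, 0, delta)
    if config.method == "first_derivative":
        return SavitzkyGolay(config.window, config.polyorder, 1, delta)
    if config.method == "second_derivative":
        return SavitzkyGolay(config.window, config.polyorder, 2, delta)
    if config.method == "wavelet_denoise":
        return WaveletDenoiser(config.wavelet_name, config.decomposition_level, config.threshold_rule)
    raise ValueError(f"unknown method {config.method!r}")  # pragma: no cover


class FunctionIdentity(TransformerMixin, BaseEstimator):
    """Identity transformer (the 'raw' control arm)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)
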