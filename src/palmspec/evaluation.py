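"""Partitioning and the calibration/prediction metric suite.

The study's protocol: split the samples 2:1 into calibration and
prediction sets (Kennard-Stone on the raw spectra by default), report the
Pearson correlation (Rc/Rp) and RMSE (RMSEC/RMSEP) per set, and summarise
predictive power as the residual predictive deviation

    RPD = sd(prediction-set reference values) / RMSEP

classified as excellent (>= 3), acceptable (2 to 3) or limited (< 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .dataset import SpectralDataset

__all__ = [
    "Partition",
    "EvaluationReport",
    "kennard_stone",
    "partition",
    "pearson_r",
    "rmse",
    "rpd",
    "classify_rpd",
    "evaluate_model",
]


@dataclass(frozen=True)
class Partition:
    """Disjoint calibration/prediction row indices covering all samples."""

    calibration_indices: np.ndarray
    prediction_indices: np.ndarray

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_indices, dtype=int)
        pred = np.asarray(self.prediction_indices, dtype=int)
        object.__setattr__(self, "calibration_indices", cal)
        object.__setattr__(self, "prediction_indices", pred)
        both = np.concatenate([cal, pred])
        if np.intersect1d(cal, pred).size:
            raise ValueError("calibration and prediction sets overlap")
        if not np.array_equal(np.sort(both), np.arange(both.size)):
            raise ValueError("partition must cover all samples exactly once")

    @property
    def n_cal(self) -> int:
        return self.calibration_indices.size

    @property
    def n_pred(self) -> int:
        return self.prediction_indices.size


def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Maximin (Kennard-Stone) selection of ``n_select`` representative rows.

    Starts from the two mutually most distant points, then repeatedly adds
    the point whose minimum Euclidean distance to the chosen set is
    largest. Ties break to the lowest row index, making the algorithm
    deterministic for a fixed row order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= n_select <= n:
        raise ValueError(f"n_select={n_select} outside 1..{n}")
    D = cdist(X, X)
    if n_select == 1:
        return np.array([0])
    i, j = np.unravel_index(np.argmax(D), D.shape)  # argmax => lowest flat index on ties
    chosen = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[chosen[0]], D[chosen[1]])
    min_dist[chosen] = -1.0
    while len(chosen) < n_select:
        nxt = int(np.argmax(min_dist))
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -1.0
    return np.sort(np.array(chosen))


def partition(
    dataset: SpectralDataset,
    ratio_cal: int = 2,
    ratio_pred: int = 1,
    method: str = "kennard_stone",
    seed: int = 0,
) -> Partition:
    """Split the dataset 2:1 (default) into calibration and prediction sets.

    Calibration size is floor(n * ratio_cal / (ratio_cal + ratio_pred)),
    so 200 samples give 133 calibration and 67 prediction samples.
    Kennard-Stone runs on the raw spectra after a canonical sort by sample
    id (so the result is invariant to input row order); ``random`` shuffles
    with the given seed.
    """
    n = dataset.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 samples to partition, got {n}")
    if ratio_cal < 1 or ratio_pred < 1:
        raise ValueError("ratios must be positive integers")
    n_cal = int(np.floor(n * ratio_cal / (ratio_cal + ratio_pred)))
    n_cal = min(max(n_cal, 1), n - 1)

    if method == "kennard_stone":
        order = np.argsort(np.asarray(dataset.sample_ids, dtype=object), kind="stable")
        cal_sorted = kennard_stone(dataset.intensities[order], n_cal)
        cal = np.sort(order[cal_sorted])
    elif method == "random":
        rng = np.random.default_rng(seed)
        cal = np.sort(rng.permutation(n)[:n_cal])
    else:
        raise ValueError(f"unknown partition method {method!r}")
    pred = np.setdiff1d(np.arange(n), cal)
    return Partition(calibration_indices=cal, prediction_indices=pred)


# ------------------------------------------------------------------ metrics


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation between reference and predicted values."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("correlation undefined for constant input")
    yc, pc = y - y.mean(), yhat - yhat.mean()
    return float((yc @ pc) / np.sqrt((yc @ yc) * (pc @ pc)))


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-square error in reference units."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size == 0:
        raise ValueError("need at least one point")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rpd(y_reference_prediction_set: np.ndarray, rmsep: float) -> float:
    """Residual predictive deviation: sd(reference, n-1 denominator) / RMSEP."""
    y = np.asarray(y_reference_prediction_set, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("RPD undefined: prediction-set references are constant")
    if rmsep <= 0:
        raise ValueError(f"RPD undefined for rmsep={rmsep} (perfect or invalid fit)")
    return float(np.std(y, ddof=1) / rmsep)


def classify_rpd(value: float) -> str:
    """excellent (>= 3), acceptable (2 to 3) or limited (< 2)."""
    if value <= 0:
        raise ValueError(f"RPD must be positive, got {value}")
    if value >= 3:
        return "excellent"
    if value >= 2:
        return "acceptable"
    return "limited"


@dataclass
class EvaluationReport:
    """One row of the model-comparison table."""

    parameter: str
    model_name: str
    Rc: float
    RMSEC: float
    Rp: float
    RMSEP: float
    RPD: float
    rpd_class: str
    n_cal: int
    n_pred: int
    n_variables: int
    n_components: int | None = None
    predictions: dict = field(default_factory=dict)  # per-sample, for recomputation

    def to_row(self) -> dict:
        """CSV row in the standard model-comparison column order."""
        return {
            "Parameter": self.parameter,
            "Model": self.model_name,
            "PCs": self.n_components if self.n_components is not None else "",
            "n_variables": self.n_variables,
            "Rc": round(self.Rc, 4),
            "RMSEC": round(self.RMSEC, 4),
            "Rp": round(self.Rp, 4),
            "RMSEP": round(self.RMSEP, 4),
            "RPD": round(self.RPD, 4),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "predictions"}
        payload["predictions"] = {
            key: {sid: float(v) for sid, v in vals.items()}
            for key, vals in self.predictions.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def evaluate_model(
    model,
    part: Partition,
    dataset: SpectralDataset,
    parameter: str,
    selection: np.ndarray | None = None,
    model_name: str = "",
) -> EvaluationReport:
    """Score a fitted model on a partitioned dataset.

    ``selection`` holds the variable indices the model was trained on
    (None = full spectrum); Rc/RMSEC come from calibration predictions,
    Rp/RMSEP/RPD from prediction-set predictions.
    """
    X = dataset.intensities if selection is None else dataset.intensities[:, selection]
    y = dataset.y(parameter)
    cal, pred = part.calibration_indices, part.prediction_indices
    yc_hat = np.asarray(model.predict(X[cal]), dtype=float).ravel()
    yp_hat = np.asarray(model.predict(X[pred]), dtype=float).ravel()

    rmsec = rmse(y[cal], yc_hat)
    rmsep = rmse(y[pred], yp_hat)
    rpd_val = rpd(y[pred], rmsep)
    n_comp = None
    est = getattr(model, "estimator", model)
    if hasattr(est, "n_components_"):
        n_comp = int(est.n_components_)
    return EvaluationReport(
        parameter=parameter,
        model_name=model_name or type(est).__name__,
        Rc=pearson_r(y[cal], yc_hat),
        RMSEC=rmsec,
        Rp=pearson_r(y[pred], yp_hat),
        RMSEP=rmsep,
        RPD=rpd_val,
        rpd_class=classify_rpd(rpd_val),
        n_cal=cal.size,
        n_pred=pred.size,
        n_variables=X.shape[1],
        n_components=n_comp,
        predictions={
            "calibration": {dataset.sample_ids[i]: float(v) for i, v in zip(cal, yc_hat)},
            "prediction": {dataset.sample_ids[i]: float(v) for i, v in zip(pred, yp_hat)},
        },
    )
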