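"""Orchestration of the full 12-model study per quality parameter.

For each parameter (PV, IV) the pipeline partitions the samples 2:1,
applies the configured preprocessing, runs each wavelength selector on the
calibration set only, and fits {PLS, SVM, RF} x {full, CARS, UVE, GA} on
the same partition - twelve models per parameter, compared pairwise on
identical data. Every table cell is recomputable from the emitted
per-sample prediction artifacts.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SpectralDataset
from .evaluation import EvaluationReport, Partition, evaluate_model, partition
from .models import (
    ModelSpec,
    choose_pls_components,
    fit_pls,
    fit_rf,
    fit_svr,
    grid_search_svr,
    refine_svr_grid,
)
from .preprocessing import PreprocessConfig, apply_preprocessing
from .selection import (
    CARSConfig,
    GAConfig,
    SelectionResult,
    UVEConfig,
    cars_select,
    ga_select,
    uve_select,
)

logger = logging.getLogger("palmspec")

SELECTORS = ("full", "CARS", "UVE", "GA")
ALGORITHMS = ("PLS", "SVM", "RF")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one full study run."""

    parameters: tuple[str, ...] = ("PV", "IV")
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    selectors: tuple[str, ...] = SELECTORS
    algorithms: tuple[str, ...] = ALGORITHMS
    partition_method: str = "kennard_stone"
    cars: CARSConfig = field(default_factory=CARSConfig)
    uve: UVEConfig = field(default_factory=UVEConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    max_pls_components: int = 10
    svr_epsilon: float = 0.1
    svr_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.selectors) - set(SELECTORS)
        if unknown:
            raise ValueError(f"unknown selectors {unknown}")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {unknown}")

    @property
    def n_models(self) -> int:
        return len(self.selectors) * len(self.algorithms)


@dataclass
class ExperimentTable:
    """Rows of evaluation reports plus the per-run artifacts."""

    reports: list[EvaluationReport]
    selections: dict[str, SelectionResult] = field(default_factory=dict)
    svr_params: dict[str, dict] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.reports])

    def best(self, parameter: str, by: str = "RPD") -> EvaluationReport:
        rows = [r for r in self.reports if r.parameter == parameter]
        if not rows:
            raise ValueError(f"no rows for parameter {parameter!r}")
        return max(rows, key=lambda r: getattr(r, by))

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out / "model_table.csv", index=False)
        for name, sel in self.selections.items():
            sel.to_json(out / f"selection_{name}.json")
        for name, rep in zip(self._row_names(), self.reports):
            rep.to_json(out / f"report_{name}.json")
        meta = {"seed": self.seed, "svr_params": self.svr_params, "failures": self.failures}
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2, default=float))

    def _row_names(self) -> list[str]:
        return [f"{r.parameter}_{r.model_name.replace('-', '_')}" for r in self.reports]


def dimensionality_report(n_selected: int, p: int) -> tuple[float, float]:
    """Percentage of channels retained and removed, half-up to one decimal.

    (66, 1024) -> (6.4, 93.6): retaining 66 of 1024 channels keeps 6.4% of
    the spectrum and removes 93.6%.
    """
    if not 1 <= n_selected <= p:
        raise ValueError(f"n_selected={n_selected} outside 1..{p}")

    def pct(x: float) -> float:
        return float(Decimal(100.0 * x / p).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))

    return pct(n_selected), pct(p - n_selected)


def _model_name(selector: str, algorithm: str) -> str:
    return algorithm if selector == "full" else f"{selector}-{algorithm}"


def _sub_seed(master: int, *tags: str) -> int:
    """Stable per-stage seed derived from the master seed and stage tags."""
    h = np.random.SeedSequence([master] + [zlib.crc32(t.encode()) for t in tags])
    return int(h.generate_state(1)[0] % (2**31))


def _fit_one(algorithm: str, X_cal, y_cal, config: ExperimentConfig, seed: int):
    """Fit one algorithm on the calibration block; returns (model, svr_info)."""
    if algorithm == "PLS":
        k = choose_pls_components(X_cal, y_cal, config.max_pls_components, config.svr_cv_folds)
        return fit_pls(X_cal, y_cal, k), None
    if algorithm == "SVM":
        C, gamma, _ = grid_search_svr(
            X_cal, y_cal, cv_folds=config.svr_cv_folds, epsilon=config.svr_epsilon)
        C, gamma, surface = refine_svr_grid(
            X_cal, y_cal, C, gamma, cv_folds=config.svr_cv_folds, epsilon=config.svr_epsilon)
        spec = ModelSpec(algorithm="SVM", C=C, gamma=gamma, epsilon=config.svr_epsilon)
        return fit_svr(X_cal, y_cal, spec), {"C": C, "gamma": gamma,
                                             "rmsecv": float(surface.min())}
    if algorithm == "RF":
        return fit_rf(X_cal, y_cal, ModelSpec(algorithm="RF"), seed=seed), None
    raise ValueError(f"unknown algorithm {algorithm!r}")  # pragma: no cover


def run_experiment(
    dataset: SpectralDataset,
    config: ExperimentConfig | None = None,
    out_dir: str | Path | None = None,
) -> ExperimentTable:
    """Run the full selector x algorithm grid for every parameter.

    Selection and hyperparameter tuning see calibration samples only; the
    prediction set is touched exactly once per model, at evaluation time.
    A failing row is recorded in ``failures`` and the rest still run.
    """
    config = config or ExperimentConfig()
    part = partition(dataset, method=config.partition_method, seed=config.seed)
    pre = apply_preprocessing(dataset, config.preprocessing)
    cal = part.calibration_indices

    table = ExperimentTable(reports=[], seed=config.seed)
    for parameter in config.parameters:
        y = pre.y(parameter)
        X = pre.intensities
        selections: dict[str, np.ndarray | None] = {}
        for selector in config.selectors:
            t0 = time.perf_counter()
            if selector == "full":
                selections[selector] = None
                continue
            try:
                if selector == "CARS":
                    res = cars_select(X[cal], y[cal], replace(
                        config.cars, seed=_sub_seed(config.seed, parameter, "CARS")))
                elif selector == "UVE":
                    res = uve_select(X[cal], y[cal], replace(
                        config.uve, seed=_sub_seed(config.seed, parameter, "UVE")))
                else:
                    res = ga_select(X[cal], y[cal], replace(
                        config.ga, seed=_sub_seed(config.seed, parameter, "GA")))
            except Exception as exc:  # noqa: BLE001 - stage isolation
                table.failures[f"{parameter}_{selector}"] = repr(exc)
                logger.error("%s %s selection failed: %r", parameter, selector, exc)
                continue
            table.selections[f"{parameter}_{selector}"] = res
            selections[selector] = res.selected
            logger.info("%s %s: %d variables in %.1fs", parameter, selector,
                        res.selected.size, time.perf_counter() - t0)

        for selector in config.selectors:
            if selector != "full" and selector not in selections:
                continue  # selection itself failed
            sel = selections[selector]
            Xsel = X if sel is None else X[:, sel]
            for algorithm in config.algorithms:
                name = _model_name(selector, algorithm)
                t0 = time.perf_counter()
                try:
                    model, svr_info = _fit_one(
                        algorithm, Xsel[cal], y[cal], config,
                        seed=_sub_seed(config.seed, parameter, name))
                    report = evaluate_model(model, part, pre, parameter,
                                            selection=sel, model_name=name)
                except Exception as exc:  # noqa: BLE001
                    table.failures[f"{parameter}_{name}"] = repr(exc)
                    logger.error("%s %s failed: %r", parameter, name, exc)
                    continue
                if svr_info is not None:
                    table.svr_params[f"{parameter}_{name}"] = svr_info
                table.reports.append(report)
                logger.info("%s %s: Rp=%.4f RPD=%.4f (%.1fs)", parameter, name,
                            report.Rp, report.RPD, time.perf_counter() - t0)

    if out_dir is not None:
        table.write(out_dir)
    return table


def compare_preprocessing(
    dataset: SpectralDataset,
    methods: tuple[str, ...] = ("raw", "first_derivative", "second_derivative",
                                "wavelet_denoise", "sg_smooth"),
    parameter: str = "PV",
    part: Partition | None = None,
    max_components: int = 10,
    cv_folds: int = 5,
) -> tuple[pd.DataFrame, str]:
    """PLS benchmark of preprocessing recipes on one shared partition.

    Returns the comparison table and the name of the winning method
    (highest prediction-set RPD), mirroring the study's control experiment
    that picked the second derivative for all downstream modelling.
    """
    if not methods:
        raise ValueError("need at least one preprocessing method")
    if part is None:
        part = partition(dataset)
    rows = []
    for method in methods:
        pre = apply_preprocessing(dataset, PreprocessConfig(method=method))
        X, y = pre.intensities, pre.y(parameter)
        cal = part.calibration_indices
        k = choose_pls_components(X[cal], y[cal], max_components, cv_folds)
        model = fit_pls(X[cal], y[cal], k)
        report = evaluate_model(model, part, pre, parameter, model_name=f"PLS[{method}]")
        row = report.to_row()
        row["method"] = method
        rows.append(row)
    df = pd.DataFrame(rows)
    winner = str(df.loc[df["RPD"].idxmax(), "method"])
    return df, winner
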