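"""Wavelength selection: CARS, UVE and GA over a cross-validated PLS engine.

All three selectors are scikit-learn feature selectors (``fit`` then
``get_support``/``transform``) and also return a :class:`SelectionResult`
carrying the diagnostics a chemometrician plots: the CARS RMSECV trace and
retained-count trace, the UVE reliability profile and cutoff, and the GA
per-variable selection frequencies. Every selector takes an explicit seed
and is deterministic given it; ties always break to the lowest variable
index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from ._pls import cv_rmse_per_component, kfold_indices, min_cv_rmse, simpls

__all__ = [
    "SelectionResult",
    "CARSConfig",
    "UVEConfig",
    "GAConfig",
    "CARS",
    "UVE",
    "GASelector",
    "edf_retention_ratio",
    "cars_select",
    "uve_select",
    "ga_select",
    "selection_enrichment",
]


@dataclass
class SelectionResult:
    """Selected variable indices plus per-algorithm diagnostics."""

    method: str
    selected: np.ndarray  # sorted unique 0-based indices
    seed: int
    rmsecv_trace: np.ndarray | None = None     # CARS: per iteration
    retained_counts: np.ndarray | None = None  # CARS: per iteration
    reliability: np.ndarray | None = None      # UVE: c_j per real variable
    noise_reliability: np.ndarray | None = None  # UVE: c_j per noise column
    cutoff: float | None = None                # UVE
    frequency: np.ndarray | None = None        # GA: per variable, over runs
    best_fitness_traces: list | None = None    # GA: per run, per generation
    config: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        if self.selected.size == 0:
            raise ValueError("selection must be non-empty")
        if not np.array_equal(self.selected, np.unique(self.selected)):
            raise ValueError("selected indices must be sorted and unique")

    def to_json(self, path: str | Path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, list):
                return [conv(x) for x in v]
            return v

        payload = {k: conv(getattr(self, k)) for k in self.__dataclass_fields__}
        Path(path).write_text(json.dumps(payload, indent=2))


# -------------------------------------------------------------------- CARS


@dataclass(frozen=True)
class CARSConfig:
    n_iterations: int = 50
    mc_fraction: float = 0.8
    cv_folds: int = 5
    max_pls_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mc_fraction < 1:
            raise ValueError(f"mc_fraction must lie in (0, 1), got {self.mc_fraction}")
        if self.n_iterations < 2:
            raise ValueError(f"n_iterations must be >= 2, got {self.n_iterations}")


def edf_retention_ratio(i: int, N: int, p: int) -> float:
    """Exponentially decaying fraction of variables retained at iteration i.

    r_i = a * exp(-k * i) pinned so all p variables survive the first
    iteration (r_1 = 1) and only 2 survive the last (r_N = 2/p):
    k = ln(p/2) / (N - 1), a = e^k.
    """
    if p <= 2:
        raise ValueError(f"need more than 2 variables, got p={p}")
    if not 1 <= i <= N:
        raise ValueError(f"iteration i={i} outside 1..{N}")
    k = np.log(p / 2.0) / (N - 1)
    return float(np.exp(k) * np.exp(-k * i))


def _validate_xy(X, y, cv_folds):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size}")
    if X.shape[0] < cv_folds:
        raise ValueError(f"need at least cv_folds={cv_folds} samples, got {X.shape[0]}")
    if np.ptp(y) == 0:
        raise ValueError("constant target: nothing to select against")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValueError("X has zero variance everywhere")
    return X, y


class CARS(SelectorMixin, BaseEstimator):
    """Competitive adaptive reweighted sampling.

    Each iteration fits PLS on a Monte-Carlo subset of the calibration
    samples, forcibly keeps the top ceil(r_i * p) variables by absolute
    regression coefficient, then resamples among the survivors with
    probability proportional to |coefficient| (adaptive reweighted
    sampling). The surviving set's 5-fold RMSECV is traced, and the set
    with the global minimum wins.
    """

    def __init__(self, n_iterations: int = 50, mc_fraction: float = 0.8,
                 cv_folds: int = 5, max_pls_components: int = 10, seed: int = 0):
        self.n_iterations = n_iterations
        self.mc_fraction = mc_fraction
        self.cv_folds = cv_folds
        self.max_pls_components = max_pls_components
        self.seed = seed

    def fit(self, X, y):
        cfg = CARSConfig(self.n_iterations, self.mc_fraction, self.cv_folds,
                         self.max_pls_components, self.seed)
        X, y = _validate_xy(X, y, cfg.cv_folds)
        n, p = X.shape
        rng = np.random.default_rng(cfg.seed)
        n_mc = max(cfg.cv_folds, int(np.ceil(cfg.mc_fraction * n)))

        survivors = np.arange(p)
        rmsecv = np.empty(cfg.n_iterations)
        retained = np.empty(cfg.n_iterations, dtype=int)
        sets: list[np.ndarray] = []
        for it in range(1, cfg.n_iterations + 1):
            rows = rng.choice(n, size=n_mc, replace=False)
            Xs = X[rows][:, survivors]
            k = int(np.argmin(cv_rmse_per_component(
                Xs, y[rows], cfg.max_pls_components, cfg.cv_folds))) + 1
            B, _, _, _ = simpls(Xs, y[rows], k)
            w = np.abs(B[-1])
            # forced retention by exponential decay of the pool size
            n_keep = min(survivors.size, max(2, int(np.ceil(edf_retention_ratio(it, cfg.n_iterations, p) * p))))
            top = np.argsort(-w, kind="stable")[:n_keep]  # stable => lowest index on ties
            kept = survivors[np.sort(top)]
            w_kept = w[np.sort(top)]
            # adaptive reweighted sampling among the survivors
            if w_kept.sum() > 0:
                draws = rng.choice(kept, size=n_keep, replace=True, p=w_kept / w_kept.sum())
                new = np.unique(draws)
            else:
                new = kept
            if new.size < 2:  # keep the PLS fit feasible
                order = np.argsort(-w_kept, kind="stable")
                new = np.unique(np.concatenate([new, kept[order[:2]]]))
            survivors = new
            sets.append(survivors.copy())
            retained[it - 1] = survivors.size
            rmsecv[it - 1] = min_cv_rmse(X[:, survivors], y, cfg.max_pls_components, cfg.cv_folds)

        best = int(np.argmin(rmsecv))
        self.result_ = SelectionResult(
            method="CARS", selected=sets[best], seed=cfg.seed,
            rmsecv_trace=rmsecv, retained_counts=retained,
            config={k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        )
        self.n_features_in_ = p
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.result_.selected] = True
        return self

    def _get_support_mask(self):
        return self.support_


# --------------------------------------------------------------------- UVE


@dataclass(frozen=True)
class UVEConfig:
    noise_amplitude: float = 1e-10
    cutoff_factor: float = 1.0
    cv_folds: int | None = None  # None => leave-one-out when n <= 150 else 10-fold
    max_pls_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_amplitude <= 0:
            raise ValueError("noise_amplitude must be positive")
        if self.cutoff_factor < 0:
            raise ValueError("cutoff_factor must be >= 0")


class UVE(SelectorMixin, BaseEstimator):
    """Uninformative variable elimination by coefficient stability.

    The spectrum matrix is augmented with p pure-noise columns scaled to
    ``noise_amplitude``; jackknifed PLS coefficient vectors give each
    variable a reliability c_j = mean(b_j) / sd(b_j). Real variables whose
    |c_j| does not exceed ``cutoff_factor`` times the largest noise-column
    |c_j| are uninformative and dropped. Noise columns are never returned.
    """

    def __init__(self, noise_amplitude: float = 1e-10, cutoff_factor: float = 1.0,
                 cv_folds: int | None = None, max_pls_components: int = 10, seed: int = 0):
        self.noise_amplitude = noise_amplitude
        self.cutoff_factor = cutoff_factor
        self.cv_folds = cv_folds
        self.max_pls_components = max_pls_components
        self.seed = seed

    def fit(self, X, y):
        cfg = UVEConfig(self.noise_amplitude, self.cutoff_factor, self.cv_folds,
                        self.max_pls_components, self.seed)
        X, y = _validate_xy(X, y, 2)
        n, p = X.shape
        rng = np.random.default_rng(cfg.seed)
        Xaug = np.hstack([X, cfg.noise_amplitude * rng.standard_normal((n, p))])

        # latent-variable count fixed once by CV on the augmented matrix,
        # then held across the jackknife refits (classical UVE)
        k = int(np.argmin(cv_rmse_per_component(Xaug, y, cfg.max_pls_components, min(5, n)))) + 1
        n_folds = n if (cfg.cv_folds is None and n <= 150) else (cfg.cv_folds or 10)
        folds = kfold_indices(n, n_folds)
        coefs = np.empty((len(folds), 2 * p))
        for f, test_idx in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            B, _, _, _ = simpls(Xaug[mask], y[mask], k)
            coefs[f] = B[-1]

        mean = coefs.mean(axis=0)
        sd = coefs.std(axis=0, ddof=1)
        warns = []
        with np.errstate(divide="ignore", invalid="ignore"):
            c = mean / sd
        zero_sd_real = (sd[:p] == 0)
        if np.any(zero_sd_real):
            c[:p][zero_sd_real] = np.inf
            msg = f"{int(zero_sd_real.sum())} real variable(s) had zero coefficient spread; retained with +inf reliability"
            warnings.warn(msg, stacklevel=2)
            warns.append(msg)
        c_real, c_noise = c[:p], c[p:]
        c_noise = np.where(np.isfinite(c_noise), c_noise, 0.0)
        cutoff = cfg.cutoff_factor * float(np.max(np.abs(c_noise)))
        selected = np.flatnonzero(np.abs(c_real) > cutoff)
        if selected.size == 0:  # degenerate data: keep the single most reliable variable
            selected = np.array([int(np.argmax(np.abs(np.nan_to_num(c_real))))])
            msg = "no variable exceeded the noise cutoff; keeping the most reliable one"
            warnings.warn(msg, stacklevel=2)
            warns.append(msg)

        self.result_ = SelectionResult(
            method="UVE", selected=selected, seed=cfg.seed,
            reliability=np.nan_to_num(c_real, posinf=np.inf),
            noise_reliability=c_noise, cutoff=cutoff,
            config={kk: getattr(cfg, kk) for kk in cfg.__dataclass_fields__},
            warnings=warns,
        )
        self.n_features_in_ = p
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        return self

    def _get_support_mask(self):
        return self.support_


# ---------------------------------------------------------------------- GA


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 64
    n_generations: int = 100
    crossover_rate: float = 0.5
    mutation_rate: float = 0.01
    n_runs: int = 5
    frequency_threshold: float = 3 / 5
    fitness_cv_folds: int = 5
    max_pls_components: int = 10
    elitism: int = 1
    init_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for r in (self.crossover_rate, self.mutation_rate, self.frequency_threshold):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


class GASelector(SelectorMixin, BaseEstimator):
    """Binary-chromosome genetic algorithm over wavelength subsets.

    One gene per channel; fitness is minus the cross-validated PLS RMSE of
    the active genes (empty chromosomes get worst fitness). Tournament
    selection, uniform crossover, bit-flip mutation and elitism; the whole
    search repeats ``n_runs`` times with derived sub-seeds and a variable
    is finally selected when it appears in at least
    ``frequency_threshold * n_runs`` of the per-run best chromosomes.
    Chromosomes start sparse (``init_fraction`` of genes on) so the search
    explores small subsets, as wavelength-selection GAs conventionally do.

    Each run's best chromosome is finished with one backward-elimination
    pass (genes whose removal does not worsen the CV RMSE are dropped, in
    ascending index order). Bit-flip mutation constantly injects near-
    neutral genes that hitchhike on fit chromosomes; pruning them is the
    standard refinement in GA wavelength selection and leaves the
    frequency vote to genes that actually earn their place.
    """

    def __init__(self, population_size: int = 64, n_generations: int = 100,
                 crossover_rate: float = 0.5, mutation_rate: float = 0.01,
                 n_runs: int = 5, frequency_threshold: float = 3 / 5,
                 fitness_cv_folds: int = 5, max_pls_components: int = 10,
                 elitism: int = 1, init_fraction: float = 0.1, seed: int = 0):
        self.population_size = population_size
        self.n_generations = n_generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.n_runs = n_runs
        self.frequency_threshold = frequency_threshold
        self.fitness_cv_folds = fitness_cv_folds
        self.max_pls_components = max_pls_components
        self.elitism = elitism
        self.init_fraction = init_fraction
        self.seed = seed

    def fit(self, X, y):
        cfg = GAConfig(self.population_size, self.n_generations, self.crossover_rate,
                       self.mutation_rate, self.n_runs, self.frequency_threshold,
                       self.fitness_cv_folds, self.max_pls_components, self.elitism,
                       self.init_fraction, self.seed)
        X, y = _validate_xy(X, y, cfg.fitness_cv_folds)
        n, p = X.shape
        cache: dict[bytes, float] = {}

        def fitness(chrom: np.ndarray) -> float:
            key = np.packbits(chrom).tobytes()
            val = cache.get(key)
            if val is None:
                idx = np.flatnonzero(chrom)
                if idx.size == 0:
                    val = -np.inf
                else:
                    val = -min_cv_rmse(X[:, idx], y, cfg.max_pls_components, cfg.fitness_cv_folds)
                cache[key] = val
            return val

        sub_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_runs) % (2**31)
        best_chroms = np.zeros((cfg.n_runs, p), dtype=bool)
        traces: list[list[float]] = []
        for run in range(cfg.n_runs):
            rng = np.random.default_rng(int(sub_seeds[run]))
            pop = rng.random((cfg.population_size, p)) < cfg.init_fraction
            for row in pop:  # guarantee non-empty start
                if not row.any():
                    row[rng.integers(p)] = True
            fits = np.array([fitness(c) for c in pop])
            trace = [float(fits.max())]
            for _ in range(cfg.n_generations):
                order = np.argsort(-fits, kind="stable")
                elite = pop[order[: cfg.elitism]].copy()
                children = [e for e in elite]
                while len(children) < cfg.population_size:
                    a, b = _tournament(rng, fits), _tournament(rng, fits)
                    c1, c2 = pop[a].copy(), pop[b].copy()
                    if rng.random() < cfg.crossover_rate:
                        swap = rng.random(p) < 0.5
                        c1[swap], c2[swap] = pop[b][swap], pop[a][swap]
                    for c in (c1, c2):
                        flip = rng.random(p) < cfg.mutation_rate
                        c[flip] = ~c[flip]
                        if len(children) < cfg.population_size:
                            children.append(c)
                pop = np.array(children)
                fits = np.array([fitness(c) for c in pop])
                trace.append(float(fits.max()))
            best = pop[int(np.argmax(fits))].copy()
            best_chroms[run] = _backward_eliminate(best, fitness)
            traces.append(trace)

        freq = best_chroms.sum(axis=0)
        need = cfg.frequency_threshold * cfg.n_runs - 1e-9
        selected = np.flatnonzero(freq >= need)
        warns = []
        if selected.size == 0:
            run_best = int(np.argmax([t[-1] for t in traces]))
            selected = np.flatnonzero(best_chroms[run_best])
            msg = "no variable met the cross-run frequency threshold; falling back to the best single run"
            warnings.warn(msg, stacklevel=2)
            warns.append(msg)

        self.result_ = SelectionResult(
            method="GA", selected=selected, seed=cfg.seed,
            frequency=freq, best_fitness_traces=traces,
            config={k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
            warnings=warns,
        )
        self.n_features_in_ = p
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        return self

    def _get_support_mask(self):
        return self.support_


def _backward_eliminate(chrom: np.ndarray, fitness, tol: float = 1e-9) -> np.ndarray:
    """One pruning pass: drop genes whose removal keeps fitness within tol."""
    best = fitness(chrom)
    for j in np.flatnonzero(chrom):
        if chrom.sum() <= 2:
            break
        chrom[j] = False
        f = fitness(chrom)
        if f >= best - tol:
            best = max(best, f)
        else:
            chrom[j] = True
    return chrom


def _tournament(rng: np.random.Generator, fits: np.ndarray, size: int = 2) -> int:
    idx = rng.integers(fits.size, size=size)
    return int(idx[np.argmax(fits[idx])])


# ------------------------------------------------------------- functional


def cars_select(X, y, config: CARSConfig | None = None) -> SelectionResult:
    cfg = config or CARSConfig()
    return CARS(**{k: getattr(cfg, k) for k in cfg.__dataclass_fields__}).fit(X, y).result_


def uve_select(X, y, config: UVEConfig | None = None) -> SelectionResult:
    cfg = config or UVEConfig()
    return UVE(**{k: getattr(cfg, k) for k in cfg.__dataclass_fields__}).fit(X, y).result_


def ga_select(X, y, config: GAConfig | None = None) -> SelectionResult:
    cfg = config or GAConfig()
    return GASelector(**{k: getattr(cfg, k) for k in cfg.__dataclass_fields__}).fit(X, y).result_


# -------------------------------------------------------------- enrichment


def selection_enrichment(
    selected: SelectionResult | np.ndarray,
    target_band: tuple[float, float],
    grid: np.ndarray,
) -> float:
    """Hypergeometric tail p-value for band concentration of a selection.

    Probability of drawing at least the observed number of in-band
    variables when ``len(selected)`` variables are drawn without
    replacement from the grid. Small p => the selection concentrates in
    the band (e.g. the carbonyl region for PV models).
    """
    idx = selected.selected if isinstance(selected, SelectionResult) else np.asarray(selected, dtype=int)
    if idx.size == 0:
        raise ValueError("selection must be non-empty")
    grid = np.asarray(grid, dtype=float)
    lo, hi = float(target_band[0]), float(target_band[1])
    if lo > hi:
        raise ValueError(f"band ({lo}, {hi}) is reversed")
    if hi < grid[0] or lo > grid[-1]:
        raise ValueError(f"band ({lo}, {hi}) lies outside the grid [{grid[0]}, {grid[-1]}]")
    in_band = (grid >= lo) & (grid <= hi)
    m = int(in_band.sum())  # band size in channels
    if m == 0:
        return 1.0
    k_obs = int(np.sum(in_band[idx]))
    return float(hypergeom.sf(k_obs - 1, grid.size, m, idx.size))
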