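"""Experiment orchestration.

* mixed-space hyperparameter decoding: optimizers search the unit cube
  ``[0,1]^m``; each axis is decoded to its hyperparameter by log-uniform or
  linear interpolation, or by uniform binning for categorical choices;
* the multi-run feature-selection protocol: each binary optimizer is run
  ``n_runs`` times with consecutive seeds on the same table and fixed
  evaluation split, and the per-run outcomes are aggregated into run
  statistics (average error, average selected fraction, average/best/worst
  fitness and its population standard deviation);
* the hyperparameter-tuning driver: a continuous optimizer minimizes
  ``1 − evaluator(decode(u))`` over the unit cube.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .baselines import BaselineParams, optimize_baseline, optimize_baseline_binary
from .binary import TransferParams, optimize_binary
from .core import OcoaParams, OptimizationResult, optimize
from .errors import InvalidParameterError, InvalidSpecError
from .objectives import CachedSubsetFitness, LabelledTable, SubsetFitnessParams
from .space import SearchSpace
from .splitting import stratified_split as _stratified_split_labels
from .stats import RunStats, fs_run_stats

logger = logging.getLogger(__name__)

HP_KINDS = ("continuous_log", "continuous_linear", "categorical")

BINARY_ALGORITHMS = ("bocoa", "bpso", "bgwo", "bfa", "bga", "bwoa")
CONTINUOUS_ALGORITHMS = ("ocoa", "pso", "gwo", "fa", "ga", "woa")


@dataclass(frozen=True)
class HyperparamSpec:
    """One axis of a mixed hyperparameter space."""

    name: str
    kind: str
    low: Optional[float] = None
    high: Optional[float] = None
    choices: Optional[tuple] = None
    default: object = None

    def __post_init__(self) -> None:
        if self.kind not in HP_KINDS:
            raise InvalidSpecError(f"kind must be one of {HP_KINDS}")
        if self.kind == "categorical":
            if not self.choices:
                raise InvalidSpecError(f"{self.name}: categorical axis needs a non-empty choice list")
        else:
            if self.low is None or self.high is None or not self.low < self.high:
                raise InvalidSpecError(f"{self.name}: continuous axis needs low < high")
            if self.kind == "continuous_log" and self.low <= 0:
                raise InvalidSpecError(f"{self.name}: log axis needs positive bounds")


def cnn_search_space() -> List[HyperparamSpec]:
    """The convolutional-network tuning space used throughout the package."""
    return [
        HyperparamSpec("learning_rate", "continuous_log", 1e-4, 0.1, default=1e-3),
        HyperparamSpec("dropout", "continuous_linear", 0.2, 0.5, default=0.3),
        HyperparamSpec("batch_size", "categorical", choices=(32, 64, 128), default=64),
        HyperparamSpec("filters", "categorical", choices=(32, 64, 128), default=64),
        HyperparamSpec("layers", "categorical", choices=(2, 3, 4), default=3),
        HyperparamSpec("optimizer", "categorical", choices=("adam", "sgd"), default="adam"),
        HyperparamSpec("activation", "categorical", choices=("relu", "leaky_relu"), default="relu"),
    ]


def decode_hyperparams(u: np.ndarray, specs: Sequence[HyperparamSpec]) -> Dict:
    """Decode a unit-cube position into a hyperparameter configuration.

    Log axes interpolate in log10 space, linear axes linearly; categorical
    axes use uniform binning with ``u = 1`` mapping into the last bin.
    Coordinates outside [0, 1] are clipped with a warning.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (len(specs),):
        raise InvalidParameterError(f"expected {len(specs)} coordinates, got shape {u.shape}")
    if np.min(u) < 0.0 or np.max(u) > 1.0:
        logger.warning("decode_hyperparams: coordinates outside [0, 1] clipped")
        u = np.clip(u, 0.0, 1.0)
    config: Dict = {}
    for uj, spec in zip(u, specs):
        if spec.kind == "continuous_log":
            lo, hi = np.log10(spec.low), np.log10(spec.high)
            config[spec.name] = float(10.0 ** (lo + uj * (hi - lo)))
        elif spec.kind == "continuous_linear":
            config[spec.name] = float(spec.low + uj * (spec.high - spec.low))
        else:
            idx = min(int(uj * len(spec.choices)), len(spec.choices) - 1)
            config[spec.name] = spec.choices[idx]
    return config


def stratified_split(table: LabelledTable, fractions: Sequence[float], seed: int = 0) -> List[np.ndarray]:
    """Stratified partition of a table's row indices (largest-remainder rounding)."""
    return _stratified_split_labels(table.labels, fractions, seed)


# ---------------------------------------------------------------------------
# Feature-selection experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Multi-run protocol settings.

    The study protocol is 30 runs of population 30 for 500 iterations per
    algorithm; desk-scale work uses fewer runs/iterations via these fields.
    """

    n_runs: int = 30
    population_size: int = 30
    max_iter: int = 500
    algorithms: tuple = BINARY_ALGORITHMS
    seed_base: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.population_size < 1 or self.max_iter < 1:
            raise InvalidParameterError("n_runs, population_size and max_iter must be positive")

    @classmethod
    def desk_scale(cls, **overrides) -> "ExperimentConfig":
        """Reduced defaults (10 runs, 100 iterations) for interactive work."""
        base = dict(n_runs=10, max_iter=100)
        base.update(overrides)
        return cls(**base)


def run_binary_algorithm(
    name: str,
    fitness: Callable[[np.ndarray], float],
    d: int,
    population_size: int,
    max_iter: int,
    seed: int,
) -> OptimizationResult:
    """Dispatch one seeded run of a named binary optimizer."""
    name = name.lower()
    if name == "bocoa":
        params = OcoaParams(population_size=population_size, max_iter=max_iter, seed=seed)
        return optimize_binary(fitness, d, params, TransferParams(seed=seed))
    if name in BINARY_ALGORITHMS:
        algo = name[1:].upper()
        params = BaselineParams(algorithm=algo, population_size=population_size, max_iter=max_iter, seed=seed)
        return optimize_baseline_binary(algo, fitness, d, params, TransferParams(seed=seed))
    raise InvalidParameterError(f"unknown binary algorithm {name!r}; expected one of {BINARY_ALGORITHMS}")


@dataclass
class FsExperimentResult:
    """Per-algorithm aggregation plus the raw per-run records."""

    stats: Dict[str, RunStats]
    records: pd.DataFrame

    def stats_frame(self) -> pd.DataFrame:
        rows = []
        for name, st in self.stats.items():
            rows.append(
                {
                    "algorithm": name,
                    "average_error": st.average_error,
                    "average_select_size": st.average_select_size,
                    "average_fitness": st.average_fitness,
                    "best_fitness": st.best_fitness,
                    "worst_fitness": st.worst_fitness,
                    "std_fitness": st.std_fitness,
                }
            )
        return pd.DataFrame(rows)


def run_fs_experiment(
    table: LabelledTable,
    config: Optional[ExperimentConfig] = None,
    fitness_params: Optional[SubsetFitnessParams] = None,
) -> FsExperimentResult:
    """Run the repeated feature-selection protocol on a labelled table.

    For each algorithm and run ``r`` (seed ``seed_base + r``), the binary
    optimizer minimizes the cached wrapper fitness on a fixed evaluation
    split; the final best mask's fitness, classification error and selected
    fraction are recorded and aggregated.
    """
    config = config or ExperimentConfig()
    fitness_params = fitness_params or SubsetFitnessParams()
    d = table.n_features
    rows = []
    stats: Dict[str, RunStats] = {}
    for name in config.algorithms:
        errors, sizes, fitnesses = [], [], []
        for r in range(1, config.n_runs + 1):
            seed = config.seed_base + r
            cache = CachedSubsetFitness(table, fitness_params)
            result = run_binary_algorithm(name, cache, d, config.population_size, config.max_iter, seed)
            mask = result.best.position
            err = cache.error_of(mask)
            size_frac = float(np.sum(mask)) / d
            errors.append(err)
            sizes.append(size_frac)
            fitnesses.append(result.best.fitness)
            rows.append(
                {
                    "algorithm": name,
                    "run": r,
                    "seed": seed,
                    "best_fitness": result.best.fitness,
                    "error": err,
                    "select_size": size_frac,
                    "n_selected": int(np.sum(mask)),
                    "mask": "".join(str(int(b)) for b in mask),
                    "evaluations": result.evaluations_used,
                }
            )
        stats[name] = fs_run_stats(errors, sizes, fitnesses)
    return FsExperimentResult(stats, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Hyperparameter-tuning experiment
# ---------------------------------------------------------------------------

def run_continuous_algorithm(
    name: str,
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    population_size: int,
    max_iter: int,
    seed: int,
) -> OptimizationResult:
    """Dispatch one seeded run of a named continuous optimizer."""
    name = name.lower()
    if name == "ocoa":
        params = OcoaParams(population_size=population_size, max_iter=max_iter, seed=seed)
        return optimize(objective, space, params)
    if name in CONTINUOUS_ALGORITHMS:
        algo = name.upper()
        params = BaselineParams(algorithm=algo, population_size=population_size, max_iter=max_iter, seed=seed)
        return optimize_baseline(algo, objective, space, params)
    raise InvalidParameterError(f"unknown algorithm {name!r}; expected one of {CONTINUOUS_ALGORITHMS}")


@dataclass
class HpoResult:
    """Best decoded configuration with its score and the raw run."""

    best_config: Dict
    best_score: float
    result: OptimizationResult


def run_hpo_experiment(
    evaluator: Callable[[Dict], float],
    specs: Sequence[HyperparamSpec],
    algorithm: str = "ocoa",
    population_size: int = 30,
    max_iter: int = 100,
    seed: int = 0,
) -> HpoResult:
    """Tune a mixed hyperparameter space against an evaluator.

    The optimizer minimizes ``1 − evaluator(decode(u))`` over ``[0,1]^m``;
    the returned score is the evaluator value of the best position.
    Reproducible per seed.
    """
    specs = list(specs)
    space = SearchSpace.unit(len(specs))

    def objective(u: np.ndarray) -> float:
        score = float(evaluator(decode_hyperparams(u, specs)))
        if not np.isfinite(score):
            raise InvalidParameterError("evaluator returned a non-finite score")
        return 1.0 - score

    result = run_continuous_algorithm(algorithm, objective, space, population_size, max_iter, seed)
    best_config = decode_hyperparams(result.best.position, specs)
    return HpoResult(best_config, 1.0 - result.best.fitness, result)
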