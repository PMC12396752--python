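"""Continuous Ocotillo optimization.

The ocotillo search alternates two phases each iteration over a population of
``N`` real-valued positions:

* **Exploration** perturbs every position with trigonometric factors —
  a distance factor ``D = 2 cos(Θ) / Train²``, an amplitude ``A = sin(ab·Θ)``
  and a learning factor ``L = 1 − 2 sin(Θ)(1 + 8 cos(Θ))²`` — via the update
  ``Θ' = Θ + A·D + r1·L``.
* **Exploitation** builds two candidate refinements per position: a Gaussian
  mutation ``Θ' = g + L1·r1·A_i/Train + F·A_o`` with ``g ~ N(µ, σ)`` drawn
  around the population mean, and an alternative mutation
  ``Θ'' = (r2·i²)·(K·A_i/(i·Train)²)²`` driven by the convergence factor
  ``K = 1 − (g/(A + D))²``; the fitter candidate (after bounds repair)
  replaces the position.

``Train`` is by default the 1-based iteration index, so the ``1/Train²``
factors damp the perturbations over time: broad exploration early, local
refinement late.  The best-so-far solution is tracked elitistically and is
never lost; population replacement itself is unconditional.

Fitness is minimized throughout.  Every run is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Tuple

import numpy as np

from .errors import InvalidParameterError
from .space import SearchSpace, apply_bounds, BOUNDS_MODES

logger = logging.getLogger(__name__)

TRAIN_CONVENTIONS = ("iteration_index", "fixed_scalar")
MUTATION_TRAIN_MODES = ("divide", "multiply")

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class OcoaParams:
    """Constants and conventions of the ocotillo search.

    Parameters
    ----------
    population_size : int
        Number of concurrent candidate solutions ``N``.
    max_iter : int
        Number of full exploration+exploitation iterations.
    ab : float
        Frequency constant in the amplitude ``A = sin(ab·Θ)``; must be nonzero.
    train_convention : {"iteration_index", "fixed_scalar"}
        Whether ``Train`` is the current 1-based iteration index (default) or
        the fixed value ``train_scalar``.
    train_scalar : float
        Value of ``Train`` under the ``fixed_scalar`` convention.
    bounds_mode : {"clip", "reflect"}
        Bounds repair applied after every position update.
    seed : int
        Seed of the run's random stream.
    gaussian_sigma : float
        Standard deviation of the Gaussian mutation draw.
    mutation_train_mode : {"divide", "multiply"}
        Whether the Gaussian-mutation middle term divides or multiplies by
        ``Train`` (division is the default, consistent with the ``1/Train²``
        damping of the other factors).
    draw_unused_r3 : bool
        Draw (and discard) the declared-but-unused ``r3`` each iteration so
        random streams match a fully literal reading of the update loop.
    division_eps : float
        Magnitude floor substituted (sign-preserving) for near-zero
        denominators.
    """

    population_size: int = 30
    max_iter: int = 500
    ab: float = 1.0
    train_convention: str = "iteration_index"
    train_scalar: float = 1.0
    bounds_mode: str = "clip"
    seed: int = 0
    gaussian_sigma: float = 1.0
    mutation_train_mode: str = "divide"
    draw_unused_r3: bool = True
    division_eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise InvalidParameterError("population_size must be >= 1")
        if self.max_iter < 0:
            raise InvalidParameterError("max_iter must be >= 0 (0 = initialization only)")
        if self.ab == 0:
            raise InvalidParameterError("ab must be nonzero")
        if self.train_convention not in TRAIN_CONVENTIONS:
            raise InvalidParameterError(f"train_convention must be one of {TRAIN_CONVENTIONS}")
        if self.train_convention == "fixed_scalar" and self.train_scalar <= 0:
            raise InvalidParameterError("train_scalar must be positive")
        if self.bounds_mode not in BOUNDS_MODES:
            raise InvalidParameterError(f"bounds_mode must be one of {BOUNDS_MODES}")
        if self.mutation_train_mode not in MUTATION_TRAIN_MODES:
            raise InvalidParameterError(f"mutation_train_mode must be one of {MUTATION_TRAIN_MODES}")
        if self.gaussian_sigma <= 0:
            raise InvalidParameterError("gaussian_sigma must be positive")

    def with_seed(self, seed: int) -> "OcoaParams":
        return replace(self, seed=int(seed))


@dataclass
class CandidateSolution:
    """A position together with its (lower-is-better) fitness."""

    position: np.ndarray
    fitness: float


@dataclass
class OptimizationResult:
    """Outcome of a population run.

    ``history`` holds ``(iteration, best_fitness)`` pairs — iteration 0 is the
    state after initialization — and is non-increasing in fitness by elitism.
    ``mean_history`` tracks the population-mean fitness per iteration and
    ``evaluations_history`` the cumulative objective evaluations.
    """

    best: CandidateSolution
    history: List[Tuple[int, float]]
    evaluations_used: int
    mean_history: List[float] = field(default_factory=list)
    evaluations_history: List[int] = field(default_factory=list)

    @property
    def best_fitness(self) -> float:
        return self.best.fitness

    @property
    def best_position(self) -> np.ndarray:
        return self.best.position


# ---------------------------------------------------------------------------
# Closed-form factors
# ---------------------------------------------------------------------------

def _check_train(train: float) -> float:
    if train <= 0:
        raise InvalidParameterError(f"train must be positive, got {train}")
    return float(train)


def guard_denominator(x: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Sign-preserving magnitude floor: values with ``|x| < eps`` become ``±eps``."""
    x = np.asarray(x, dtype=float)
    sign = np.where(x < 0, -1.0, 1.0)
    return np.where(np.abs(x) < eps, sign * eps, x)


def distance_factor(theta: np.ndarray, train: float) -> np.ndarray:
    """``D = 2·cos(Θ) / Train²``, element-wise; ``|D| <= 2/Train²``."""
    train = _check_train(train)
    return 2.0 * np.cos(np.asarray(theta, dtype=float)) / train**2


def amplitude(theta: np.ndarray, ab: float = 1.0) -> np.ndarray:
    """``A = sin(ab·Θ)``, element-wise, in [-1, 1]."""
    return np.sin(ab * np.asarray(theta, dtype=float))


def learning_factor(theta: np.ndarray) -> np.ndarray:
    """``L = 1 − 2·sin(Θ)·(1 + 8·cos(Θ))²``, element-wise."""
    theta = np.asarray(theta, dtype=float)
    return 1.0 - 2.0 * np.sin(theta) * (1.0 + 8.0 * np.cos(theta)) ** 2


def oscillation_sum(theta: np.ndarray, train: float) -> np.ndarray:
    """``F = Σ_{n=0}^{10} sin(n·Θ) / Train²``, element-wise."""
    train = _check_train(train)
    theta = np.asarray(theta, dtype=float)
    n = np.arange(11, dtype=float)
    return np.sin(theta[..., None] * n).sum(axis=-1) / train**2


def convergence_factor(
    gauss_sample: np.ndarray,
    a: np.ndarray,
    d: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """``K = 1 − (g/(A + D))²``, element-wise; ``K <= 1``.

    Near-zero denominators ``A + D`` are replaced by a sign-preserving ``eps``
    (logged at warning level) so the factor stays finite.
    """
    g = np.asarray(gauss_sample, dtype=float)
    denom = np.asarray(a, dtype=float) + np.asarray(d, dtype=float)
    if np.any(np.abs(denom) < eps):
        logger.warning("convergence_factor: near-zero denominator A + D guarded with eps=%g", eps)
    return 1.0 - (g / guard_denominator(denom, eps)) ** 2


# ---------------------------------------------------------------------------
# Update steps
# ---------------------------------------------------------------------------

def explore_step(
    theta: np.ndarray,
    r1: float,
    train: float,
    ab: float = 1.0,
    space: Optional[SearchSpace] = None,
    bounds_mode: str = "clip",
) -> np.ndarray:
    """Exploration update ``Θ' = Θ + A·D + r1·L`` with optional bounds repair."""
    if np.min(r1) < 0.0 or np.max(r1) > 1.0:
        raise InvalidParameterError("r1 must lie in [0, 1]")
    theta = np.asarray(theta, dtype=float)
    new = theta + amplitude(theta, ab) * distance_factor(theta, train) + np.asarray(r1) * learning_factor(theta)
    if space is not None:
        new = apply_bounds(new, space, bounds_mode)
    return new


def exploit_candidates(
    theta: np.ndarray,
    best: np.ndarray,
    i: np.ndarray,
    train: float,
    params: OcoaParams,
    r1: np.ndarray,
    r2: np.ndarray,
    gauss: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Raw (unbounded) exploitation candidates for one position or a stack.

    ``theta``/``gauss`` may be shape ``(d,)`` or ``(N, d)``; ``i`` is the
    1-based solution index (scalar or shape ``(N, 1)``); ``r1``/``r2`` are
    uniform draws broadcastable against ``theta``.

    Candidate (a), Gaussian mutation: ``g + L1·r1·A_i/Train + F·A_o`` with
    ``L1``/``A_i``/``F`` evaluated on the current position and ``A_o`` on the
    global best.  Candidate (b), alternative mutation:
    ``(r2·i²)·(K·A_i/(i·Train)²)²`` with ``K = 1 − (g/(A_i + D))²``.
    """
    train = _check_train(train)
    theta = np.asarray(theta, dtype=float)
    i = np.asarray(i, dtype=float)
    if np.any(i < 1):
        raise InvalidParameterError("solution index i must be >= 1")
    a_i = amplitude(theta, params.ab)
    l1 = learning_factor(theta)
    d = distance_factor(theta, train)
    f = oscillation_sum(theta, train)
    a_o = amplitude(np.asarray(best, dtype=float), params.ab)
    if params.mutation_train_mode == "divide":
        middle = l1 * r1 * a_i / train
    else:
        middle = l1 * r1 * a_i * train
    cand_a = gauss + middle + f * a_o
    k = convergence_factor(gauss, a_i, d, params.division_eps)
    denom = guard_denominator((i * train) ** 2, params.division_eps)
    cand_b = (r2 * i**2) * (k * a_i / denom) ** 2
    return cand_a, cand_b


def exploit_step(
    theta: np.ndarray,
    best: np.ndarray,
    pop_mean: np.ndarray,
    i: int,
    train: float,
    params: OcoaParams,
    rng: np.random.Generator,
    objective: Objective,
    space: SearchSpace,
    r1: Optional[float] = None,
    r2: Optional[float] = None,
    gauss: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, float]:
    """Single-solution exploitation: evaluate both candidates, keep the fitter.

    ``r1``, ``r2`` and the Gaussian sample ``gauss`` may be forced for
    reproducible unit checks; otherwise they are drawn from ``rng`` (``gauss``
    per-coordinate from ``N(pop_mean, σ)``).  Ties go to candidate (a).
    """
    theta = np.asarray(theta, dtype=float)
    if r1 is None:
        r1 = float(rng.uniform())
    if r2 is None:
        r2 = float(rng.uniform())
    if gauss is None:
        gauss = rng.normal(np.asarray(pop_mean, dtype=float), params.gaussian_sigma, size=theta.shape)
    cand_a, cand_b = exploit_candidates(theta, best, i, train, params, r1, r2, np.asarray(gauss, dtype=float))
    cand_a = apply_bounds(cand_a, space, params.bounds_mode)
    cand_b = apply_bounds(cand_b, space, params.bounds_mode)
    fa = _safe_fitness(objective, cand_a)
    fb = _safe_fitness(objective, cand_b)
    if fb < fa:
        return cand_b, fb
    return cand_a, fa


def _safe_fitness(objective: Objective, theta: np.ndarray) -> float:
    value = float(objective(theta))
    if not np.isfinite(value):
        logger.warning("objective returned non-finite value %r; assigning +inf", value)
        return float("inf")
    return value


def _evaluate_population(objective: Objective, positions: np.ndarray) -> np.ndarray:
    return np.array([_safe_fitness(objective, p) for p in positions])


def _train_value(params: OcoaParams, t: int) -> float:
    if params.train_convention == "iteration_index":
        return float(t)
    return float(params.train_scalar)


def optimize(
    objective: Objective,
    space: SearchSpace,
    params: Optional[OcoaParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> OptimizationResult:
    """Run the continuous ocotillo search; minimizes ``objective`` over ``space``.

    Per iteration: exploration update + evaluation for all ``N`` positions,
    elitist best update, then exploitation (two candidates each, both
    evaluated — ``3N`` evaluations per iteration), unconditional population
    replacement, and a second best update.  Total budget is exactly
    ``N·(1 + 3·max_iter)`` evaluations.
    """
    params = params or OcoaParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, d = params.population_size, space.dim

    positions = space.sample(rng, n)
    fitness = _evaluate_population(objective, positions)
    evals = n
    best_idx = int(np.argmin(fitness))  # ties: first index wins
    best = CandidateSolution(positions[best_idx].copy(), float(fitness[best_idx]))

    history: List[Tuple[int, float]] = [(0, best.fitness)]
    mean_history: List[float] = [float(np.mean(fitness))]
    evals_history: List[int] = [evals]
    index = np.arange(1, n + 1, dtype=float)[:, None]

    for t in range(1, params.max_iter + 1):
        train = _train_value(params, t)

        # exploration
        r1 = rng.uniform(size=(n, 1))
        positions = explore_step(positions, r1, train, params.ab, space, params.bounds_mode)
        fitness = _evaluate_population(objective, positions)
        evals += n
        _update_best(best, positions, fitness)

        # exploitation: both candidates evaluated, fitter survives (tie -> a)
        r1x = rng.uniform(size=(n, 1))
        r2 = rng.uniform(size=(n, 1))
        if params.draw_unused_r3:
            rng.uniform()  # declared r3, unused by any update rule
        pop_mean = positions.mean(axis=0)
        gauss = rng.normal(pop_mean, params.gaussian_sigma, size=(n, d))
        cand_a, cand_b = exploit_candidates(positions, best.position, index, train, params, r1x, r2, gauss)
        cand_a = apply_bounds(cand_a, space, params.bounds_mode)
        cand_b = apply_bounds(cand_b, space, params.bounds_mode)
        fit_a = _evaluate_population(objective, cand_a)
        fit_b = _evaluate_population(objective, cand_b)
        evals += 2 * n
        take_b = fit_b < fit_a
        positions = np.where(take_b[:, None], cand_b, cand_a)
        fitness = np.where(take_b, fit_b, fit_a)
        _update_best(best, positions, fitness)

        history.append((t, best.fitness))
        mean_history.append(float(np.mean(fitness)))
        evals_history.append(evals)

    return OptimizationResult(best, history, evals, mean_history, evals_history)


def _update_best(best: CandidateSolution, positions: np.ndarray, fitness: np.ndarray) -> None:
    idx = int(np.argmin(fitness))
    if fitness[idx] < best.fitness:  # strict: first-encountered wins ties
        best.position = positions[idx].copy()
        best.fitness = float(fitness[idx])


def history_records(result: OptimizationResult) -> List[dict]:
    """Flatten a result into ``iteration, best_fitness, mean_fitness, evaluations`` rows."""
    rows = []
    for k, (it, bf) in enumerate(result.history):
        rows.append(
            {
                "iteration": it,
                "best_fitness": bf,
                "mean_fitness": result.mean_history[k] if k < len(result.mean_history) else float("nan"),
                "evaluations": result.evaluations_history[k] if k < len(result.evaluations_history) else result.evaluations_used,
            }
        )
    return rows
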