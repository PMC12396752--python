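"""Baseline metaheuristics: PSO, GWO, FA, GA and WOA, continuous and binary.

All five follow their canonical textbook update rules and share the result,
elitism and determinism contracts of :func:`ocotillo.core.optimize`.  Binary
variants map each continuous position update through the shared sigmoid
transfer + stochastic binarization layer of :mod:`ocotillo.binary`, except
the genetic algorithm, which operates natively on bit strings (single-point
crossover + bit-flip mutation).

A uniform random-search oracle (continuous and binary) is provided for
budget-matched dominance checks: given the same number of objective
evaluations, every population algorithm here is expected to reach a better
median best fitness than blind sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Tuple

import numpy as np

from .binary import TransferParams, _repair_empty, sigmoid_transfer
from .core import CandidateSolution, Objective, OptimizationResult, _evaluate_population, _safe_fitness
from .errors import InvalidParameterError
from .space import SearchSpace, apply_bounds

ALGORITHMS = ("PSO", "GWO", "FA", "GA", "WOA")


@dataclass(frozen=True)
class BaselineParams:
    """Shared and per-algorithm settings for the comparison metaheuristics.

    Defaults follow the study protocol: population 30, 500 iterations;
    PSO c1 = c2 = 2 with inertia 0.3; GWO's ``a`` decreased linearly 2 -> 0;
    GA mutation probability 0.05 and crossover rate 0.02 (as printed, however
    low); FA step size 0.94 (attractiveness beta0 and absorption gamma are
    conventional defaults); WOA spiral constant decreased linearly 2 -> 0.
    """

    algorithm: str = "PSO"
    population_size: int = 30
    max_iter: int = 500
    pso_c1: float = 2.0
    pso_c2: float = 2.0
    pso_w: float = 0.3
    gwo_a_start: float = 2.0
    gwo_a_end: float = 0.0
    ga_mutation_prob: float = 0.05
    ga_crossover_rate: float = 0.02
    ga_mutation_sigma_frac: float = 0.1
    fa_step_size: float = 0.94
    fa_beta0: float = 1.0
    fa_gamma: float = 1.0
    woa_b_start: float = 2.0
    woa_b_end: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise InvalidParameterError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")
        if self.population_size < 1 or self.max_iter < 0:
            raise InvalidParameterError("population_size must be >= 1 and max_iter >= 0")
        for p in (self.ga_mutation_prob, self.ga_crossover_rate):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError("GA probabilities must lie in [0, 1]")

    def with_algorithm(self, algorithm: str) -> "BaselineParams":
        return replace(self, algorithm=algorithm)

    def with_seed(self, seed: int) -> "BaselineParams":
        return replace(self, seed=int(seed))


class _Tracker:
    """Elitist best tracking plus per-iteration history bookkeeping."""

    def __init__(self, positions: np.ndarray, fitness: np.ndarray) -> None:
        idx = int(np.argmin(fitness))
        self.best = CandidateSolution(positions[idx].copy(), float(fitness[idx]))
        self.evals = len(fitness)
        self.history: List[Tuple[int, float]] = [(0, self.best.fitness)]
        self.mean_history = [float(np.mean(fitness))]
        self.evals_history = [self.evals]

    def update(self, positions: np.ndarray, fitness: np.ndarray) -> None:
        idx = int(np.argmin(fitness))
        if fitness[idx] < self.best.fitness:
            self.best.position = positions[idx].copy()
            self.best.fitness = float(fitness[idx])

    def record(self, t: int, fitness: np.ndarray) -> None:
        self.history.append((t, self.best.fitness))
        self.mean_history.append(float(np.mean(fitness)))
        self.evals_history.append(self.evals)

    def result(self) -> OptimizationResult:
        return OptimizationResult(self.best, self.history, self.evals, self.mean_history, self.evals_history)


def _schedule(start: float, end: float, t: int, max_iter: int) -> float:
    if max_iter <= 1:
        return end
    return start + (end - start) * (t - 1) / (max_iter - 1)


# ---------------------------------------------------------------------------
# Continuous variants
# ---------------------------------------------------------------------------

def optimize_baseline(
    algorithm: str,
    objective: Objective,
    space: SearchSpace,
    params: Optional[BaselineParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> OptimizationResult:
    """Run one of the five baseline metaheuristics on a continuous space."""
    params = (params or BaselineParams()).with_algorithm(algorithm)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    runner = {
        "PSO": _pso,
        "GWO": _gwo,
        "FA": _fa,
        "GA": _ga_real,
        "WOA": _woa,
    }[params.algorithm]
    return runner(objective, space, params, rng)


def _pso(objective, space, params, rng):
    n, d = params.population_size, space.dim
    x = space.sample(rng, n)
    v = np.zeros((n, d))
    fit = _evaluate_population(objective, x)
    tr = _Tracker(x, fit)
    pbest, pbest_fit = x.copy(), fit.copy()
    for t in range(1, params.max_iter + 1):
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        v = params.pso_w * v + params.pso_c1 * r1 * (pbest - x) + params.pso_c2 * r2 * (tr.best.position - x)
        x = apply_bounds(x + v, space, "clip")
        fit = _evaluate_population(objective, x)
        tr.evals += n
        improved = fit < pbest_fit
        pbest[improved] = x[improved]
        pbest_fit[improved] = fit[improved]
        tr.update(x, fit)
        tr.record(t, fit)
    return tr.result()


def _gwo(objective, space, params, rng):
    n, d = params.population_size, space.dim
    x = space.sample(rng, n)
    fit = _evaluate_population(objective, x)
    tr = _Tracker(x, fit)
    for t in range(1, params.max_iter + 1):
        a = _schedule(params.gwo_a_start, params.gwo_a_end, t, params.max_iter)
        order = np.argsort(fit, kind="stable")
        leaders = x[order[: min(3, n)]]
        while leaders.shape[0] < 3:
            leaders = np.vstack([leaders, leaders[-1]])
        new_x = np.zeros_like(x)
        for k in range(3):
            r1 = rng.uniform(size=(n, d))
            r2 = rng.uniform(size=(n, d))
            A = 2.0 * a * r1 - a
            C = 2.0 * r2
            D = np.abs(C * leaders[k] - x)
            new_x += leaders[k] - A * D
        x = apply_bounds(new_x / 3.0, space, "clip")
        fit = _evaluate_population(objective, x)
        tr.evals += n
        tr.update(x, fit)
        tr.record(t, fit)
    return tr.result()


def _fa(objective, space, params, rng):
    n, d = params.population_size, space.dim
    scale = space.upper - space.lower
    x = space.sample(rng, n)
    fit = _evaluate_population(objective, x)
    tr = _Tracker(x, fit)
    for t in range(1, params.max_iter + 1):
        order = np.argsort(fit, kind="stable")
        for i in order[::-1]:  # dimmer fireflies move first
            for j in order:
                if fit[j] < fit[i]:
                    r2 = np.sum((x[i] - x[j]) ** 2)
                    beta = params.fa_beta0 * np.exp(-params.fa_gamma * r2)
                    x[i] = x[i] + beta * (x[j] - x[i]) + params.fa_step_size * (rng.uniform(size=d) - 0.5) * scale * 0.1
        x = apply_bounds(x, space, "clip")
        fit = _evaluate_population(objective, x)
        tr.evals += n
        tr.update(x, fit)
        tr.record(t, fit)
    return tr.result()


def _tournament(rng: np.random.Generator, fit: np.ndarray) -> int:
    a, b = rng.integers(len(fit)), rng.integers(len(fit))
    return int(a if fit[a] <= fit[b] else b)


def _ga_real(objective, space, params, rng):
    n, d = params.population_size, space.dim
    sigma = params.ga_mutation_sigma_frac * (space.upper - space.lower)
    x = space.sample(rng, n)
    fit = _evaluate_population(objective, x)
    tr = _Tracker(x, fit)
    for t in range(1, params.max_iter + 1):
        children = np.empty_like(x)
        for i in range(n):
            p1 = x[_tournament(rng, fit)]
            p2 = x[_tournament(rng, fit)]
            if rng.uniform() < params.ga_crossover_rate:
                take = rng.uniform(size=d) < 0.5  # uniform crossover
                child = np.where(take, p1, p2)
            else:
                child = p1.copy()
            mutate = rng.uniform(size=d) < params.ga_mutation_prob
            child = child + mutate * rng.normal(0.0, sigma, size=d)
            children[i] = child
        # elitism: the best individual survives unchanged
        children[0] = tr.best.position
        x = apply_bounds(children, space, "clip")
        fit = _evaluate_population(objective, x)
        tr.evals += n
        tr.update(x, fit)
        tr.record(t, fit)
    return tr.result()


def _woa(objective, space, params, rng):
    n, d = params.population_size, space.dim
    x = space.sample(rng, n)
    fit = _evaluate_population(objective, x)
    tr = _Tracker(x, fit)
    for t in range(1, params.max_iter + 1):
        a = _schedule(2.0, 0.0, t, params.max_iter)
        b = _schedule(params.woa_b_start, params.woa_b_end, t, params.max_iter)
        new_x = np.empty_like(x)
        for i in range(n):
            r = rng.uniform(size=d)
            A = 2.0 * a * r - a
            C = 2.0 * rng.uniform(size=d)
            if rng.uniform() < 0.5:  # encircling / search branch
                if np.abs(A).max() < 1.0:
                    D = np.abs(C * tr.best.position - x[i])
                    new_x[i] = tr.best.position - A * D
                else:
                    rand = x[int(rng.integers(n))]
                    D = np.abs(C * rand - x[i])
                    new_x[i] = rand - A * D
            else:  # spiral update
                l = rng.uniform(-1.0, 1.0)
                D = np.abs(tr.best.position - x[i])
                new_x[i] = D * np.exp(b * l) * np.cos(2.0 * np.pi * l) + tr.best.position
        x = apply_bounds(new_x, space, "clip")
        fit = _evaluate_population(objective, x)
        tr.evals += n
        tr.update(x, fit)
        tr.record(t, fit)
    return tr.result()


# ---------------------------------------------------------------------------
# Binary variants
# ---------------------------------------------------------------------------

def optimize_baseline_binary(
    algorithm: str,
    fitness: Callable[[np.ndarray], float],
    d: int,
    params: Optional[BaselineParams] = None,
    tparams: Optional[TransferParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> OptimizationResult:
    """Binary variant of a baseline metaheuristic over ``{0,1}^d``."""
    if d < 2:
        raise InvalidParameterError("dimension d must be >= 2")
    params = (params or BaselineParams()).with_algorithm(algorithm)
    tparams = tparams or TransferParams(seed=params.seed)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.algorithm == "GA":
        return _ga_binary(fitness, d, params, tparams, rng)
    return _transfer_binary(fitness, d, params, tparams, rng)


def _init_bits(rng, n, d, policy):
    bits = (rng.uniform(size=(n, d)) < 0.5).astype(np.int8)
    for row in range(n):
        bits[row] = _repair_empty(bits[row], np.full(d, 0.5), rng, policy)
    return bits


def _binarize_rows(cont: np.ndarray, rng, policy) -> np.ndarray:
    s = sigmoid_transfer(cont)
    bits = (s > rng.uniform(size=s.shape)).astype(np.int8)
    for row in range(bits.shape[0]):
        bits[row] = _repair_empty(bits[row], s[row], rng, policy)
    return bits


def _transfer_binary(fitness, d, params, tparams, rng):
    """PSO/GWO/FA/WOA on bits via the sigmoid + stochastic-binarization layer."""
    n = params.population_size
    policy = tparams.empty_mask_policy
    algo = params.algorithm
    bits = _init_bits(rng, n, d, policy)
    fit = np.array([_safe_fitness(fitness, b) for b in bits])
    tr = _Tracker(bits, fit)
    v = np.zeros((n, d))  # PSO velocity state
    pbest, pbest_fit = bits.copy(), fit.copy()
    for t in range(1, params.max_iter + 1):
        x = bits.astype(float)
        if algo == "PSO":
            r1 = rng.uniform(size=(n, d))
            r2 = rng.uniform(size=(n, d))
            v = params.pso_w * v + params.pso_c1 * r1 * (pbest - x) + params.pso_c2 * r2 * (tr.best.position - x)
            cont = v  # transfer applied to the velocity, standard binary PSO
        elif algo == "GWO":
            a = _schedule(params.gwo_a_start, params.gwo_a_end, t, params.max_iter)
            order = np.argsort(fit, kind="stable")
            leaders = x[order[: min(3, n)]]
            while leaders.shape[0] < 3:
                leaders = np.vstack([leaders, leaders[-1]])
            cont = np.zeros_like(x)
            for k in range(3):
                r1 = rng.uniform(size=(n, d))
                r2 = rng.uniform(size=(n, d))
                A = 2.0 * a * r1 - a
                C = 2.0 * r2
                cont += leaders[k] - A * np.abs(C * leaders[k] - x)
            cont = cont / 3.0 - 0.5  # center so that S(0.5-ish) is not biased to 1
        elif algo == "FA":
            cont = x.copy()
            order = np.argsort(fit, kind="stable")
            for i in order[::-1]:
                for j in order:
                    if fit[j] < fit[i]:
                        r2 = np.sum((cont[i] - x[j]) ** 2)
                        beta = params.fa_beta0 * np.exp(-params.fa_gamma * r2)
                        cont[i] = cont[i] + beta * (x[j] - cont[i]) + params.fa_step_size * (rng.uniform(size=d) - 0.5)
            cont = cont - 0.5
        else:  # WOA
            a = _schedule(2.0, 0.0, t, params.max_iter)
            b = _schedule(params.woa_b_start, params.woa_b_end, t, params.max_iter)
            cont = np.empty_like(x)
            gbest = tr.best.position.astype(float)
            for i in range(n):
                r = rng.uniform(size=d)
                A = 2.0 * a * r - a
                C = 2.0 * rng.uniform(size=d)
                if rng.uniform() < 0.5:
                    if np.abs(A).max() < 1.0:
                        cont[i] = gbest - A * np.abs(C * gbest - x[i])
                    else:
                        rand = x[int(rng.integers(n))]
                        cont[i] = rand - A * np.abs(C * rand - x[i])
                else:
                    l = rng.uniform(-1.0, 1.0)
                    cont[i] = np.abs(gbest - x[i]) * np.exp(b * l) * np.cos(2.0 * np.pi * l) + gbest
            cont = cont - 0.5
        bits = _binarize_rows(cont, rng, policy)
        fit = np.array([_safe_fitness(fitness, b) for b in bits])
        tr.evals += n
        if algo == "PSO":
            improved = fit < pbest_fit
            pbest[improved] = bits[improved]
            pbest_fit[improved] = fit[improved]
        tr.update(bits, fit)
        tr.record(t, fit)
    return tr.result()


def _ga_binary(fitness, d, params, tparams, rng):
    """Native bit-string GA: tournament, single-point crossover, bit flips."""
    n = params.population_size
    policy = tparams.empty_mask_policy
    bits = _init_bits(rng, n, d, policy)
    fit = np.array([_safe_fitness(fitness, b) for b in bits])
    tr = _Tracker(bits, fit)
    for t in range(1, params.max_iter + 1):
        children = np.empty_like(bits)
        for i in range(n):
            p1 = bits[_tournament(rng, fit)]
            p2 = bits[_tournament(rng, fit)]
            if rng.uniform() < params.ga_crossover_rate and d > 1:
                point = int(rng.integers(1, d))
                child = np.concatenate([p1[:point], p2[point:]])
            else:
                child = p1.copy()
            flip = rng.uniform(size=d) < params.ga_mutation_prob
            child = np.where(flip, 1 - child, child).astype(np.int8)
            children[i] = _repair_empty(child, np.full(d, 0.5), rng, policy)
        children[0] = tr.best.position
        bits = children
        fit = np.array([_safe_fitness(fitness, b) for b in bits])
        tr.evals += n
        tr.update(bits, fit)
        tr.record(t, fit)
    return tr.result()


# ---------------------------------------------------------------------------
# Random-search oracles
# ---------------------------------------------------------------------------

def random_search(
    objective: Objective,
    space: SearchSpace,
    n_evals: int,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> OptimizationResult:
    """Uniform sampling oracle at a fixed evaluation budget (continuous)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    x = space.sample(rng, n_evals)
    fit = _evaluate_population(objective, x)
    tr = _Tracker(x, fit)
    return tr.result()


def random_search_binary(
    fitness: Callable[[np.ndarray], float],
    d: int,
    n_evals: int,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    policy: str = "force_random_bit",
) -> OptimizationResult:
    """Uniform non-empty-mask sampling oracle at a fixed evaluation budget."""
    if rng is None:
        rng = np.random.default_rng(seed)
    bits = _init_bits(rng, n_evals, d, policy)
    fit = np.array([_safe_fitness(fitness, b) for b in bits])
    tr = _Tracker(bits, fit)
    return tr.result()
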