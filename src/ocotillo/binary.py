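"""Binary ocotillo search for feature-subset selection.

Candidate solutions are bit masks in ``{0,1}^d`` (bit j = feature j
included).  The continuous update rules of :mod:`ocotillo.core` are applied
literally to the 0/1 coordinates; the resulting real-valued positions are
mapped back to bits through a sigmoid transfer ``S(x) = 1/(1+e^{-x})``
followed by stochastic binarization (``bit_j = 1`` iff ``S_j > u_j`` with
``u_j ~ U(0,1)``).  There is no velocity or continuous shadow state — the
bit mask is the only state carried between iterations.

Masks submitted for fitness evaluation are always non-empty: an all-zero
outcome is repaired by the configured empty-mask policy (set one uniformly
random bit, or re-binarize up to 10 times first).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.special import expit

from .core import (
    CandidateSolution,
    OcoaParams,
    OptimizationResult,
    _safe_fitness,
    _train_value,
    amplitude,
    distance_factor,
    exploit_candidates,
    learning_factor,
)
from .errors import InvalidMaskError, InvalidParameterError

EMPTY_MASK_POLICIES = ("resample", "force_random_bit")

BitFitness = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class TransferParams:
    """Binarization-layer settings (empty-mask repair policy and seed)."""

    empty_mask_policy: str = "force_random_bit"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.empty_mask_policy not in EMPTY_MASK_POLICIES:
            raise InvalidParameterError(f"empty_mask_policy must be one of {EMPTY_MASK_POLICIES}")


def sigmoid_transfer(x: np.ndarray) -> np.ndarray:
    """Overflow-safe logistic transfer ``1/(1+exp(-x))`` in (0, 1)."""
    return expit(np.asarray(x, dtype=float))


def stochastic_binarize(s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw ``bit_j = 1`` iff ``s_j > u_j`` with independent ``u_j ~ U(0,1)``.

    The expected value of each bit equals its input probability.
    """
    s = np.asarray(s, dtype=float)
    if np.min(s) < 0.0 or np.max(s) > 1.0:
        raise InvalidParameterError("transfer probabilities must lie in [0, 1]")
    return (s > rng.uniform(size=s.shape)).astype(np.int8)


def validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.all((mask == 0) | (mask == 1)):
        raise InvalidMaskError("mask elements must be exactly 0 or 1")
    if mask.sum() == 0:
        raise InvalidMaskError("mask must select at least one feature")
    return mask.astype(np.int8)


def _repair_empty(
    bits: np.ndarray,
    s: np.ndarray,
    rng: np.random.Generator,
    policy: str,
) -> np.ndarray:
    """Enforce the non-empty invariant on a single mask."""
    if bits.sum() > 0:
        return bits
    if policy == "resample":
        for _ in range(10):
            bits = stochastic_binarize(s, rng)
            if bits.sum() > 0:
                return bits
    bits = bits.copy()
    bits[int(rng.integers(bits.shape[-1]))] = 1
    return bits


def binary_explore(
    mask: np.ndarray,
    r1: float,
    train: float,
    ab: float,
    rng: np.random.Generator,
    policy: str = "force_random_bit",
) -> np.ndarray:
    """Exploration on bits: continuous update, sigmoid, binarize, repair."""
    theta = validate_mask(mask).astype(float)
    cont = theta + amplitude(theta, ab) * distance_factor(theta, train) + r1 * learning_factor(theta)
    s = sigmoid_transfer(cont)
    bits = stochastic_binarize(s, rng)
    return _repair_empty(bits, s, rng, policy)


def binary_exploit(
    mask: np.ndarray,
    best: np.ndarray,
    pop_mean: np.ndarray,
    i: int,
    train: float,
    params: OcoaParams,
    rng: np.random.Generator,
    fitness: BitFitness,
    policy: str = "force_random_bit",
) -> Tuple[np.ndarray, float]:
    """Exploitation on bits: both continuous candidates are binarized and the
    fitter mask survives (ties keep the Gaussian-mutation candidate)."""
    theta = validate_mask(mask).astype(float)
    r1 = float(rng.uniform())
    r2 = float(rng.uniform())
    gauss = rng.normal(np.asarray(pop_mean, dtype=float), params.gaussian_sigma, size=theta.shape)
    cand_a, cand_b = exploit_candidates(theta, np.asarray(best, dtype=float), i, train, params, r1, r2, gauss)
    sa, sb = sigmoid_transfer(cand_a), sigmoid_transfer(cand_b)
    bits_a = _repair_empty(stochastic_binarize(sa, rng), sa, rng, policy)
    bits_b = _repair_empty(stochastic_binarize(sb, rng), sb, rng, policy)
    fa = _safe_fitness(fitness, bits_a)
    fb = _safe_fitness(fitness, bits_b)
    if fb < fa:
        return bits_b, fb
    return bits_a, fa


def optimize_binary(
    fitness: BitFitness,
    d: int,
    params: Optional[OcoaParams] = None,
    tparams: Optional[TransferParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> OptimizationResult:
    """Binary ocotillo run over ``{0,1}^d`` minimizing ``fitness``.

    Same loop structure, elitism, determinism and ``N·(1 + 3·max_iter)``
    budget contract as the continuous :func:`ocotillo.core.optimize`.
    """
    if d < 2:
        raise InvalidParameterError("dimension d must be >= 2")
    params = params or OcoaParams()
    tparams = tparams or TransferParams(seed=params.seed)
    if rng is None:
        rng = np.random.default_rng(tparams.seed)
    n = params.population_size
    policy = tparams.empty_mask_policy

    bits = (rng.uniform(size=(n, d)) < 0.5).astype(np.int8)
    for row in range(n):
        bits[row] = _repair_empty(bits[row], np.full(d, 0.5), rng, policy)
    fit = np.array([_safe_fitness(fitness, b) for b in bits])
    evals = n
    best_idx = int(np.argmin(fit))
    best = CandidateSolution(bits[best_idx].copy(), float(fit[best_idx]))

    history: List[Tuple[int, float]] = [(0, best.fitness)]
    mean_history = [float(np.mean(fit))]
    evals_history = [evals]
    index = np.arange(1, n + 1, dtype=float)[:, None]

    for t in range(1, params.max_iter + 1):
        train = _train_value(params, t)

        # exploration (vectorized continuous update, per-row repair)
        r1 = rng.uniform(size=(n, 1))
        theta = bits.astype(float)
        cont = theta + amplitude(theta, params.ab) * distance_factor(theta, train) + r1 * learning_factor(theta)
        s = sigmoid_transfer(cont)
        new_bits = (s > rng.uniform(size=s.shape)).astype(np.int8)
        for row in range(n):
            new_bits[row] = _repair_empty(new_bits[row], s[row], rng, policy)
        bits = new_bits
        fit = np.array([_safe_fitness(fitness, b) for b in bits])
        evals += n
        _update_best_bits(best, bits, fit)

        # exploitation
        r1x = rng.uniform(size=(n, 1))
        r2 = rng.uniform(size=(n, 1))
        if params.draw_unused_r3:
            rng.uniform()
        theta = bits.astype(float)
        pop_mean = theta.mean(axis=0)
        gauss = rng.normal(pop_mean, params.gaussian_sigma, size=(n, d))
        cand_a, cand_b = exploit_candidates(theta, best.position.astype(float), index, train, params, r1x, r2, gauss)
        sa, sb = sigmoid_transfer(cand_a), sigmoid_transfer(cand_b)
        bits_a = (sa > rng.uniform(size=sa.shape)).astype(np.int8)
        bits_b = (sb > rng.uniform(size=sb.shape)).astype(np.int8)
        for row in range(n):
            bits_a[row] = _repair_empty(bits_a[row], sa[row], rng, policy)
            bits_b[row] = _repair_empty(bits_b[row], sb[row], rng, policy)
        fit_a = np.array([_safe_fitness(fitness, b) for b in bits_a])
        fit_b = np.array([_safe_fitness(fitness, b) for b in bits_b])
        evals += 2 * n
        take_b = fit_b < fit_a
        bits = np.where(take_b[:, None], bits_b, bits_a).astype(np.int8)
        fit = np.where(take_b, fit_b, fit_a)
        _update_best_bits(best, bits, fit)

        history.append((t, best.fitness))
        mean_history.append(float(np.mean(fit)))
        evals_history.append(evals)

    return OptimizationResult(best, history, evals, mean_history, evals_history)


def _update_best_bits(best: CandidateSolution, bits: np.ndarray, fit: np.ndarray) -> None:
    idx = int(np.argmin(fit))
    if fit[idx] < best.fitness:
        best.position = bits[idx].copy()
        best.fitness = float(fit[idx])


# ---------------------------------------------------------------------------
# Mask export helpers
# ---------------------------------------------------------------------------

def mask_to_string(mask: np.ndarray) -> str:
    """Plain-text 0/1 representation, e.g. ``'01101'``."""
    return "".join(str(int(b)) for b in np.asarray(mask).ravel())


def selected_indices(mask: np.ndarray) -> np.ndarray:
    """0-based indices of the selected features."""
    return np.flatnonzero(np.asarray(mask))


def selected_features_frame(mask: np.ndarray, feature_names: Optional[List[str]] = None):
    """DataFrame of selected feature indices (and names when provided)."""
    import pandas as pd

    idx = selected_indices(mask)
    data = {"feature_index": idx}
    if feature_names is not None:
        data["feature_name"] = [feature_names[j] for j in idx]
    return pd.DataFrame(data)
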