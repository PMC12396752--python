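"""Synthetic inputs with the statistical structure the experiments assume.

Two generators:

* :func:`make_feature_table` builds a labelled feature table emulating deep
  image embeddings: a small set of *informative* columns whose class-
  conditional Gaussian means encode the class identity, *redundant* columns
  that are noisy copies of informative parents, and pure-noise columns.
  Class means are placed on a binary (or small-base) code across the
  informative axes, so each informative feature separates a different
  bipartition of the classes and no informative feature is substitutable by
  the others — the geometry a wrapper selector must recover.

* :func:`make_hpo_surface` returns a deterministic, smooth, unimodal
  "validation accuracy" surface over a convolutional-network hyperparameter
  configuration, standing in for real classifier validation during
  hyperparameter tuning.  Its maximizer (value exactly 1.0) is the reference
  configuration lr=0.001, dropout=0.3, batch 64, 64 filters, 3 conv layers,
  Adam, ReLU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Dict, Tuple

import numpy as np

from .errors import InvalidSpecError
from .objectives import LabelledTable

# Redundant columns copy their parent informative column plus Gaussian noise
# of this many noise_sd units; 0.7 keeps the parent correlation near 0.95
# while making a redundant copy measurably worse than its parent for
# classification.
REDUNDANT_NOISE_FRAC = 0.7


@dataclass(frozen=True)
class GeneratorSpec:
    """Shape and signal-strength parameters of the synthetic feature table."""

    n_samples: int = 400
    n_features: int = 12
    n_informative: int = 3
    n_redundant: int = 3
    n_classes: int = 8
    class_separation: float = 4.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise InvalidSpecError("n_informative + n_redundant must not exceed n_features")
        if self.n_informative < 1:
            raise InvalidSpecError("need at least one informative feature")
        if self.n_classes < 2:
            raise InvalidSpecError("n_classes must be >= 2")
        if self.n_samples < 10 * self.n_classes:
            raise InvalidSpecError("n_samples must be at least 10 per class times n_classes")
        if self.class_separation <= 0:
            raise InvalidSpecError("class_separation must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")

    def with_seed(self, seed: int) -> "GeneratorSpec":
        return replace(self, seed=int(seed))


def _class_codes(c: int, k: int) -> np.ndarray:
    """Distinct per-class codes over k informative axes.

    Uses base-b digits with the smallest base that fits all classes, cycling
    the digit index over the axes; for ``c <= 2**k`` this is the binary code
    of the class index, so every axis separates a different bipartition and
    all axes are needed to tell all classes apart.
    """
    n_digits = max(1, math.ceil(math.log2(c))) if c <= 2**k else k
    base = 2 if c <= 2**k else math.ceil(c ** (1.0 / k))
    codes = np.zeros((c, k), dtype=float)
    for cls in range(c):
        rem = cls
        digits = []
        for _ in range(max(n_digits, k)):
            digits.append(rem % base)
            rem //= base
        for j in range(k):
            codes[cls, j] = digits[j % max(n_digits, 1)]
    return codes


def make_feature_table(spec: GeneratorSpec) -> Tuple[LabelledTable, Dict]:
    """Generate the labelled table plus ground-truth structure.

    Returns ``(table, truth)`` where ``truth`` records the informative,
    redundant and noise column indices, each redundant column's parent, and
    the class-code matrix.  Classes are balanced (remainders assigned to the
    lowest class labels) and rows are shuffled; identical spec + seed give a
    bit-identical table.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    k, r, c = spec.n_informative, spec.n_redundant, spec.n_classes

    counts = np.full(c, n // c)
    counts[: n % c] += 1
    labels = np.repeat(np.arange(c), counts)
    labels = labels[rng.permutation(n)]

    codes = _class_codes(c, k)
    sep = spec.class_separation * spec.noise_sd

    informative = sep * codes[labels] + spec.noise_sd * rng.normal(size=(n, k))
    parents = np.arange(r) % k
    redundant = informative[:, parents] + REDUNDANT_NOISE_FRAC * spec.noise_sd * rng.normal(size=(n, r))
    noise = rng.normal(size=(n, d - k - r))

    features = np.concatenate([informative, redundant, noise], axis=1)
    names = (
        [f"inf_{j}" for j in range(k)]
        + [f"red_{j}" for j in range(r)]
        + [f"noise_{j}" for j in range(d - k - r)]
    )
    table = LabelledTable(features, labels, names)
    truth = {
        "informative_idx": list(range(k)),
        "redundant_idx": list(range(k, k + r)),
        "noise_idx": list(range(k + r, d)),
        "redundant_parents": parents.tolist(),
        "class_codes": codes.tolist(),
    }
    return table, truth


# ---------------------------------------------------------------------------
# Surrogate hyperparameter surface
# ---------------------------------------------------------------------------

SURFACE_OPTIMUM: Dict = {
    "learning_rate": 0.001,
    "dropout": 0.3,
    "batch_size": 64,
    "filters": 64,
    "layers": 3,
    "optimizer": "adam",
    "activation": "relu",
}

# Quadratic penalty weights of the surrogate surface; score = 1/(1+penalty).
_LR_WEIGHT = 2.0        # per squared decade of learning-rate error
_DROPOUT_WEIGHT = 8.0   # per squared unit of dropout error
_CATEGORICAL_PENALTY = 0.25  # flat cost of each wrong categorical choice


def surrogate_accuracy(config: Dict) -> float:
    """Deterministic analytic validation-accuracy surface in (0, 1].

    Smooth and unimodal: ``1/(1 + penalty)`` with a quadratic penalty on the
    log10 learning-rate and dropout distances from the optimum and a flat
    penalty per mismatched categorical choice.  Equals 1.0 exactly at
    :data:`SURFACE_OPTIMUM`.
    """
    penalty = _LR_WEIGHT * (math.log10(float(config["learning_rate"])) - math.log10(SURFACE_OPTIMUM["learning_rate"])) ** 2
    penalty += _DROPOUT_WEIGHT * (float(config["dropout"]) - SURFACE_OPTIMUM["dropout"]) ** 2
    for key in ("batch_size", "filters", "layers", "optimizer", "activation"):
        if config[key] != SURFACE_OPTIMUM[key]:
            penalty += _CATEGORICAL_PENALTY
    return 1.0 / (1.0 + penalty)


def make_hpo_surface(seed: int = 0) -> Tuple[Callable[[Dict], float], Dict]:
    """Return ``(evaluator, optimum_config)`` for the surrogate surface.

    The surface is analytic and identical for every seed; the argument is
    accepted for interface uniformity with stochastic evaluators.
    """
    del seed
    return surrogate_accuracy, dict(SURFACE_OPTIMUM)
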