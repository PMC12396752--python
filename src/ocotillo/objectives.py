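"""Fitness definitions.

Three families of objective live here:

* benchmark test functions (sphere, Rastrigin, Ackley) for validating the
  continuous optimizers — all with global minimum 0 at the origin;
* the wrapper feature-selection fitness: a k-nearest-neighbour
  misclassification estimate on the masked feature columns combined with a
  subset-compactness penalty, ``f = ω·error + (1 − ω)·|mask|/d`` with
  ω = 0.99 (lower is better);
* the hyperparameter-evaluator contract: any callable mapping a decoded
  hyperparameter configuration to a validation accuracy in [0, 1].  A
  deterministic analytic surrogate lives in :mod:`ocotillo.synthetic`;
  :func:`tiny_classifier_evaluator` trains a small neural network on a
  synthetic table instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .errors import InvalidMaskError, InvalidParameterError, InvalidSpecError
from .splitting import stratified_split

EVAL_SCHEMES = ("holdout_70_30", "kfold")


# ---------------------------------------------------------------------------
# Labelled feature tables
# ---------------------------------------------------------------------------

@dataclass
class LabelledTable:
    """A feature matrix with one class label per row.

    Invariants: no missing values, at least two classes, every class with at
    least two samples.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise InvalidSpecError("features must be a 2-D matrix")
        if len(self.labels) != self.features.shape[0]:
            raise InvalidSpecError("labels length must match the number of rows")
        if not np.all(np.isfinite(self.features)):
            raise InvalidSpecError("features must be finite (no missing values)")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) < 2:
            raise InvalidSpecError("at least 2 classes are required")
        if counts.min() < 2:
            raise InvalidSpecError("every class needs at least 2 samples")
        if self.feature_names is not None and len(self.feature_names) != self.features.shape[1]:
            raise InvalidSpecError("feature_names length must match the number of columns")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        names = self.feature_names or [f"f{j}" for j in range(self.n_features)]
        df = pd.DataFrame(self.features, columns=names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label") -> "LabelledTable":
        if label_column not in df.columns:
            raise InvalidSpecError(f"label column {label_column!r} not found")
        labels = df[label_column].to_numpy()
        feats = df.drop(columns=[label_column])
        return cls(feats.to_numpy(dtype=float), labels, list(feats.columns))

    @classmethod
    def from_csv(cls, path, label_column: str = "label") -> "LabelledTable":
        return cls.from_dataframe(pd.read_csv(path), label_column)


@dataclass(frozen=True)
class SubsetFitnessParams:
    """Settings of the wrapper feature-selection fitness.

    ``omega`` weights the classification error against the selected-fraction
    penalty; ``knn_k`` is the neighbour count of the embedded evaluator;
    ``eval_scheme`` is a stratified 70:30 holdout by default (a stratified
    k-fold alternative is available); ``seed`` fixes the split.
    """

    omega: float = 0.99
    knn_k: int = 5
    eval_scheme: str = "holdout_70_30"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise InvalidParameterError("omega must lie in [0, 1]")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise InvalidParameterError("knn_k must be a positive odd integer")
        if self.eval_scheme not in EVAL_SCHEMES:
            raise InvalidParameterError(f"eval_scheme must be one of {EVAL_SCHEMES}")
        if self.n_folds < 2:
            raise InvalidParameterError("n_folds must be >= 2")

    def with_seed(self, seed: int) -> "SubsetFitnessParams":
        return replace(self, seed=int(seed))


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def knn_error(table: LabelledTable, mask: np.ndarray, params: Optional[SubsetFitnessParams] = None) -> float:
    """Misclassification rate of a KNN classifier on the masked columns.

    Features are standardized with the training fold's mean and variance
    before Euclidean distances are computed.  Deterministic given the params
    seed.
    """
    params = params or SubsetFitnessParams()
    mask = np.asarray(mask)
    if mask.sum() == 0:
        raise InvalidMaskError("cannot evaluate an empty feature mask")
    cols = table.features[:, mask.astype(bool)]
    y = table.labels

    if params.eval_scheme == "holdout_70_30":
        train_idx, test_idx = stratified_split(y, (0.7, 0.3), params.seed)
        folds = [(train_idx, test_idx)]
    else:
        skf = StratifiedKFold(n_splits=params.n_folds, shuffle=True, random_state=params.seed)
        folds = list(skf.split(cols, y))

    wrong = 0
    total = 0
    for train_idx, test_idx in folds:
        if params.knn_k >= len(train_idx):
            raise InvalidParameterError("knn_k must be smaller than the training-fold size")
        x_tr, x_te = _standardize(cols[train_idx], cols[test_idx])
        clf = KNeighborsClassifier(n_neighbors=params.knn_k, algorithm="brute")
        clf.fit(x_tr, y[train_idx])
        pred = clf.predict(x_te)
        wrong += int(np.sum(pred != y[test_idx]))
        total += len(test_idx)
    return wrong / total


def subset_fitness(table: LabelledTable, mask: np.ndarray, params: Optional[SubsetFitnessParams] = None) -> float:
    """Wrapper fitness ``ω·error + (1 − ω)·|mask|/d``; lower is better."""
    params = params or SubsetFitnessParams()
    mask = np.asarray(mask)
    err = knn_error(table, mask, params)
    return params.omega * err + (1.0 - params.omega) * (mask.sum() / table.n_features)


class CachedSubsetFitness:
    """Memoized mask -> fitness callable for a fixed table and params.

    Wrapper feature selection re-visits masks constantly; with a fixed
    evaluation split the fitness of a mask never changes within a run, so the
    KNN evaluation is computed once per distinct mask.
    """

    def __init__(self, table: LabelledTable, params: Optional[SubsetFitnessParams] = None) -> None:
        self.table = table
        self.params = params or SubsetFitnessParams()
        self._fitness: Dict[bytes, float] = {}
        self._error: Dict[bytes, float] = {}

    def __call__(self, mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=np.int8).tobytes()
        if key not in self._fitness:
            err = knn_error(self.table, mask, self.params)
            size_frac = np.asarray(mask).sum() / self.table.n_features
            self._error[key] = err
            self._fitness[key] = self.params.omega * err + (1.0 - self.params.omega) * size_frac
        return self._fitness[key]

    def error_of(self, mask: np.ndarray) -> float:
        """Classification error of a (possibly cached) mask."""
        key = np.asarray(mask, dtype=np.int8).tobytes()
        if key not in self._error:
            self(mask)
        return self._error[key]

    @property
    def n_distinct_masks(self) -> int:
        return len(self._fitness)


# ---------------------------------------------------------------------------
# Benchmark objectives
# ---------------------------------------------------------------------------

def sphere(theta: np.ndarray) -> float:
    theta = np.asarray(theta, dtype=float)
    return float(np.sum(theta**2))


def rastrigin(theta: np.ndarray) -> float:
    theta = np.asarray(theta, dtype=float)
    return float(10.0 * theta.size + np.sum(theta**2 - 10.0 * np.cos(2.0 * np.pi * theta)))


def ackley(theta: np.ndarray) -> float:
    theta = np.asarray(theta, dtype=float)
    d = theta.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(theta**2) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * theta)) / d)
        + 20.0
        + np.e
    )


BENCHMARKS: Dict[str, Callable[[np.ndarray], float]] = {
    "sphere": sphere,
    "rastrigin": rastrigin,
    "ackley": ackley,
}


def benchmark_objective(name: str) -> Callable[[np.ndarray], float]:
    """Look up a registered benchmark function by name."""
    try:
        return BENCHMARKS[name]
    except KeyError:
        raise InvalidParameterError(f"unknown benchmark {name!r}; registered: {sorted(BENCHMARKS)}") from None


def register_benchmark(name: str, fn: Callable[[np.ndarray], float]) -> None:
    BENCHMARKS[name] = fn


# ---------------------------------------------------------------------------
# Hyperparameter-evaluator contract
# ---------------------------------------------------------------------------

def tiny_classifier_evaluator(seed: int = 0, spec=None) -> Callable[[dict], float]:
    """Evaluator that trains a small MLP on a synthetic table per config.

    Returns held-out accuracy on a stratified 30% split of a cleanly
    separable planted-signal table (a harder table may be supplied via
    ``spec``).  The decoded hyperparameters map onto the closest
    scikit-learn MLP equivalents: ``filters``/``layers`` set the
    hidden-layer widths and depth, ``dropout`` is translated into an L2
    penalty of comparable strength (scikit-learn has no dropout), and both
    ReLU variants use the ``relu`` activation.
    """
    from sklearn.neural_network import MLPClassifier

    from .synthetic import GeneratorSpec, make_feature_table

    if spec is None:
        spec = GeneratorSpec(n_samples=400, n_features=12, n_informative=3, n_redundant=3,
                             n_classes=4, class_separation=6.0, seed=seed)
    else:
        spec = spec.with_seed(seed)
    table, _ = make_feature_table(spec)
    train_idx, test_idx = stratified_split(table.labels, (0.7, 0.3), seed)
    x_tr, x_te = _standardize(table.features[train_idx], table.features[test_idx])
    y_tr, y_te = table.labels[train_idx], table.labels[test_idx]

    def evaluate(config: dict) -> float:
        clf = MLPClassifier(
            hidden_layer_sizes=(int(config.get("filters", 64)),) * int(config.get("layers", 3)),
            learning_rate_init=float(config.get("learning_rate", 1e-3)),
            alpha=float(config.get("dropout", 0.3)) * 0.01,
            batch_size=min(int(config.get("batch_size", 64)), len(y_tr)),
            solver={"adam": "adam", "sgd": "sgd"}[str(config.get("optimizer", "adam"))],
            activation="relu",
            max_iter=400,
            random_state=seed,
        )
        clf.fit(x_tr, y_tr)
        acc = float(np.mean(clf.predict(x_te) == y_te))
        if not np.isfinite(acc):
            raise InvalidParameterError("evaluator produced a non-finite score")
        return acc

    return evaluate
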