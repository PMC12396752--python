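"""Evaluation metrics and statistical comparison tests.

Covers the confusion-matrix diagnostics of binary (or one-vs-rest)
classification — accuracy, sensitivity, specificity, PPV, NPV and F-score —
the per-run aggregation statistics of repeated feature-selection runs, a
one-way ANOVA decomposition, and an exact Wilcoxon signed-rank test whose
null distribution is enumerated over all 2^n sign assignments.

A brute-force confusion-matrix reconstruction is included as a test oracle:
given printed sensitivity/specificity/PPV values it searches integer count
tables that reproduce them, which lets published metric rows be checked for
internal consistency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InvalidParameterError, NotFoundError, UndefinedTestError


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts (true/false positives/negatives)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.total < 1:
            raise InvalidParameterError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The six standard diagnostics derived from a confusion matrix.

    A metric whose denominator is zero is reported as NaN.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f_score: float


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN", RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricSet:
    """Exact closed-form metrics: accuracy (TP+TN)/total, TPR TP/(TP+FN),
    TNR TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN), F 2TP/(2TP+FP+FN)."""
    return MetricSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.total, "accuracy"),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=_ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        ppv=_ratio(cm.tp, cm.tp + cm.fp, "ppv"),
        npv=_ratio(cm.tn, cm.tn + cm.fn, "npv"),
        f_score=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f_score"),
    )


def f_from_precision_recall(ppv: float, tpr: float) -> float:
    """Harmonic mean 2·PPV·TPR/(PPV+TPR); equals 2TP/(2TP+FP+FN) algebraically."""
    if ppv + tpr == 0:
        warnings.warn("F-score undefined for ppv = tpr = 0; reported as NaN", RuntimeWarning, stacklevel=2)
        return float("nan")
    return 2.0 * ppv * tpr / (ppv + tpr)


def reconstruct_confusion(
    sensitivity: float,
    specificity: float,
    ppv: float,
    max_total: int = 2000,
    tol: float = 1e-8,
) -> ConfusionMatrix:
    """Smallest integer confusion matrix matching printed rates within ``tol``.

    Searches positives ``P = tp + fn`` and negatives ``N = tn + fp`` up to
    ``max_total`` each; for every pair the nearest-integer ``tp``/``tn`` are
    checked against the target sensitivity/specificity and the implied PPV
    against its target.  Raises :class:`NotFoundError` when nothing matches.
    """
    if max_total < 4:
        raise InvalidParameterError("max_total must be >= 4")
    P = np.arange(1, max_total + 1)
    tp = np.rint(sensitivity * P)
    ok_p = np.abs(tp / P - sensitivity) <= tol
    N = np.arange(1, max_total + 1)
    tn = np.rint(specificity * N)
    ok_n = np.abs(tn / N - specificity) <= tol
    P, tp = P[ok_p], tp[ok_p].astype(int)
    N, tn = N[ok_n], tn[ok_n].astype(int)
    if len(P) == 0 or len(N) == 0:
        raise NotFoundError("no integer counts reproduce the printed rates at this tolerance")

    fp = (N[None, :] - tn[None, :]).astype(float)
    denom = tp[:, None] + fp
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv_grid = np.where(denom > 0, tp[:, None] / denom, np.nan)
    match = np.abs(ppv_grid - ppv) <= tol
    if not match.any():
        raise NotFoundError("no integer counts reproduce the printed rates at this tolerance")
    totals = P[:, None] + N[None, :] + np.zeros_like(ppv_grid)
    totals = np.where(match, totals, np.inf)
    i, j = np.unravel_index(int(np.argmin(totals)), totals.shape)
    return ConfusionMatrix(tp=int(tp[i]), fp=int(N[j] - tn[j]), tn=int(tn[j]), fn=int(P[i] - tp[i]))


def one_vs_rest_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Per-class one-vs-rest metric sets plus macro and micro averages.

    Macro averages the per-class metrics with equal class weight; micro pools
    the per-class confusion counts before computing the metrics.  Which
    averaging a published table used must be stated by its authors — both are
    reported here, clearly labelled.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    per_class = {}
    pooled = dict(tp=0, fp=0, tn=0, fn=0)
    for cls in classes:
        tp = int(np.sum((y_pred == cls) & (y_true == cls)))
        fp = int(np.sum((y_pred == cls) & (y_true != cls)))
        fn = int(np.sum((y_pred != cls) & (y_true == cls)))
        tn = int(np.sum((y_pred != cls) & (y_true != cls)))
        per_class[cls] = metrics_from_confusion(ConfusionMatrix(tp, fp, tn, fn))
        for key, val in zip(("tp", "fp", "tn", "fn"), (tp, fp, tn, fn)):
            pooled[key] += val
    fields = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f_score")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        macro = MetricSet(**{f: float(np.nanmean([getattr(m, f) for m in per_class.values()])) for f in fields})
    micro = metrics_from_confusion(ConfusionMatrix(**pooled))
    return {"per_class": per_class, "macro": macro, "micro": micro}


# ---------------------------------------------------------------------------
# Run statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunStats:
    """Aggregation of repeated feature-selection runs.

    ``std_fitness`` uses the population (1/n) divisor.
    """

    average_error: float
    average_select_size: float
    average_fitness: float
    best_fitness: float
    worst_fitness: float
    std_fitness: float


def fs_run_stats(errors: Sequence[float], sizes: Sequence[float], fitnesses: Sequence[float]) -> RunStats:
    """Arithmetic means, min/max fitness and population-divisor fitness SD."""
    errors = np.asarray(errors, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    fitnesses = np.asarray(fitnesses, dtype=float)
    if not (len(errors) == len(sizes) == len(fitnesses)) or len(errors) == 0:
        raise InvalidParameterError("errors, sizes and fitnesses must be equal-length and non-empty")
    return RunStats(
        average_error=float(errors.mean()),
        average_select_size=float(sizes.mean()),
        average_fitness=float(fitnesses.mean()),
        best_fitness=float(fitnesses.min()),
        worst_fitness=float(fitnesses.max()),
        std_fitness=float(fitnesses.std(ddof=0)),
    )


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTable:
    """Between/within sum-of-squares decomposition with the F test."""

    ss_between: float
    df_between: int
    ms_between: float
    ss_within: float
    df_within: int
    ms_within: float
    f_stat: float
    p_value: float
    degenerate: bool = False

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def anova_from_sums(ss_between: float, df_between: int, ss_within: float, df_within: int) -> AnovaTable:
    """Build the ANOVA table (F and p) from sum-of-squares cells."""
    if df_between < 1 or df_within < 1:
        raise InvalidParameterError("degrees of freedom must be positive")
    ms_b = ss_between / df_between
    ms_w = ss_within / df_within
    if ms_w == 0:
        return AnovaTable(ss_between, df_between, ms_b, ss_within, df_within, ms_w,
                          float("inf"), 0.0, degenerate=True)
    f_stat = ms_b / ms_w
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaTable(ss_between, df_between, ms_b, ss_within, df_within, ms_w, f_stat, p)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """Standard one-way decomposition: F = MS_between/MS_within with
    (k−1, N−k) degrees of freedom.

    Identical groups of constants yield a degenerate table (F = +inf, p = 0,
    flagged) rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InvalidParameterError("need >= 2 groups with >= 2 values each")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_b = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_w = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    return anova_from_sums(ss_b, df_b, ss_w, df_w)


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank sums and the two-tailed p of a paired comparison.

    ``w_statistic`` is the sum of signed ranks ``W+ − W−`` (the quantity
    reported as W in standard software output); the p-value is computed from
    ``min(W+, W−)``.
    """

    n_effective: int
    w_positive: float
    w_negative: float
    w_statistic: float
    p_two_tailed: float
    exact_flag: bool


def _signed_rank_null_counts(ranks: Sequence[int]) -> np.ndarray:
    """Distribution of W+ over all 2^n sign assignments, by dynamic
    programming over the (integer) ranks; counts[w] = #assignments with
    W+ = w."""
    total = int(sum(ranks))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(differences: Sequence[float], max_exact_n: int = 25) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test of paired differences.

    Zeros are discarded; absolute differences are ranked with mid-ranks for
    ties.  With no ties and ``n <= max_exact_n`` the p-value is exact —
    ``2·P(W <= min(W+, W−))`` under full enumeration of the 2^n sign
    assignments — otherwise a normal approximation with continuity and tie
    correction is used and ``exact_flag`` is False.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedTestError("all differences are zero; the test is undefined")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w_min = min(w_pos, w_neg)
    w_signed = w_pos - w_neg
    has_ties = len(np.unique(np.abs(d))) < n

    if not has_ties and n <= max_exact_n:
        counts = _signed_rank_null_counts(ranks.astype(int))
        total = counts.sum()  # 2^n
        p = 2.0 * counts[: int(w_min) + 1].sum() / total
        return WilcoxonResult(n, w_pos, w_neg, w_signed, min(1.0, float(p)), True)

    # normal approximation with continuity and tie correction
    mean = n * (n + 1) / 4.0
    tie_term = 0.0
    for _, cnt in zip(*np.unique(ranks, return_counts=True)):
        if cnt > 1:
            tie_term += cnt**3 - cnt
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        raise UndefinedTestError("zero variance; the test is undefined")
    z = (w_min - mean + 0.5) / math.sqrt(var)
    p = 2.0 * float(sps.norm.cdf(z))
    return WilcoxonResult(n, w_pos, w_neg, w_signed, min(1.0, p), False)


def pairwise_wilcoxon(
    reference: Sequence[float],
    others: dict,
) -> dict:
    """Wilcoxon of ``reference − other`` for each named competitor."""
    reference = np.asarray(reference, dtype=float)
    out = {}
    for name, values in others.items():
        out[name] = wilcoxon_signed_rank_exact(reference - np.asarray(values, dtype=float))
    return out
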