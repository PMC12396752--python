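"""Metrics, run statistics, ANOVA and the exact Wilcoxon test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ocotillo.errors import InvalidParameterError, NotFoundError, UndefinedTestError
from ocotillo.stats import (
    ConfusionMatrix,
    anova_from_sums,
    f_from_precision_recall,
    fs_run_stats,
    metrics_from_confusion,
    one_vs_rest_metrics,
    one_way_anova,
    pairwise_wilcoxon,
    reconstruct_confusion,
    wilcoxon_signed_rank_exact,
)

# Published metric rows used as integer-consistency references: the baseline
# convolutional classifier and the ocotillo-tuned one.
CNN_BASELINE_ROW = dict(accuracy=0.862944162, sensitivity=0.860215054, specificity=0.865384615,
                        ppv=0.851063830, npv=0.873786408, f_score=0.855614973)
TUNED_CNN_ROW = dict(accuracy=0.982395878, sensitivity=0.983391608, specificity=0.981434599,
                     ppv=0.980819529, npv=0.983925550, f_score=0.982103885)


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

def test_metrics_reproduce_published_baseline_row():
    m = metrics_from_confusion(ConfusionMatrix(tp=80, fp=14, tn=90, fn=13))
    for name, value in CNN_BASELINE_ROW.items():
        assert getattr(m, name) == pytest.approx(value, abs=5e-10)


def test_metrics_degenerate_cases():
    perfect = metrics_from_confusion(ConfusionMatrix(1, 0, 1, 0))
    assert all(getattr(perfect, f) == 1.0 for f in
               ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f_score"))
    wrong = metrics_from_confusion(ConfusionMatrix(0, 1, 0, 1))
    assert wrong.accuracy == 0.0


def test_zero_denominator_reported_as_nan():
    with pytest.warns(RuntimeWarning):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
    assert math.isnan(m.ppv) and m.specificity == 1.0


def test_metric_identities_on_random_matrices(rng):
    for _ in range(200):
        tp, fp, tn, fn = rng.integers(1, 500, size=4)
        cm = ConfusionMatrix(int(tp), int(fp), int(tn), int(fn))
        m = metrics_from_confusion(cm)
        assert m.accuracy == pytest.approx((tp + tn) / cm.total, abs=1e-12)
        assert m.f_score == pytest.approx(f_from_precision_recall(m.ppv, m.sensitivity), abs=1e-12)
        assert min(m.ppv, m.sensitivity) - 1e-12 <= m.f_score <= max(m.ppv, m.sensitivity) + 1e-12


def test_harmonic_mean_of_equals_is_identity():
    assert f_from_precision_recall(0.7, 0.7) == pytest.approx(0.7, abs=1e-15)


def test_reconstruct_confusion_published_rows():
    cm = reconstruct_confusion(CNN_BASELINE_ROW["sensitivity"], CNN_BASELINE_ROW["specificity"],
                               CNN_BASELINE_ROW["ppv"], max_total=2000, tol=1e-8)
    assert (cm.tp, cm.fp, cm.tn, cm.fn) == (80, 14, 90, 13)
    cm2 = reconstruct_confusion(TUNED_CNN_ROW["sensitivity"], TUNED_CNN_ROW["specificity"],
                                TUNED_CNN_ROW["ppv"], max_total=2000, tol=1e-8)
    assert (cm2.tp, cm2.fp, cm2.tn, cm2.fn) == (1125, 22, 1163, 19)


def test_reconstruct_roundtrip_identity(rng):
    for _ in range(20):
        tp, fp, tn, fn = (int(v) for v in rng.integers(1, 60, size=4))
        m = metrics_from_confusion(ConfusionMatrix(tp, fp, tn, fn))
        cm = reconstruct_confusion(m.sensitivity, m.specificity, m.ppv, max_total=200, tol=1e-9)
        back = metrics_from_confusion(cm)
        assert back.sensitivity == pytest.approx(m.sensitivity, abs=1e-9)
        assert back.specificity == pytest.approx(m.specificity, abs=1e-9)
        assert back.ppv == pytest.approx(m.ppv, abs=1e-9)


def test_reconstruct_trivial_roundtrip():
    cm = reconstruct_confusion(1.0, 1.0, 1.0, max_total=10, tol=1e-12)
    assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 0, 1, 0)


def test_reconstruct_failure_raises():
    with pytest.raises(NotFoundError):
        reconstruct_confusion(1 / math.pi, 1 / math.e, 0.123456789, max_total=50, tol=1e-12)


def test_one_vs_rest_micro_equals_accuracy_structure():
    y_true = np.array([0, 0, 1, 1, 2, 2, 2])
    y_pred = np.array([0, 1, 1, 1, 2, 0, 2])
    out = one_vs_rest_metrics(y_true, y_pred)
    # micro-averaged sensitivity equals overall accuracy for single-label data
    acc = np.mean(y_true == y_pred)
    assert out["micro"].sensitivity == pytest.approx(acc)
    assert set(out["per_class"]) == {0, 1, 2}


# ---------------------------------------------------------------------------
# Run statistics
# ---------------------------------------------------------------------------

def test_fs_run_stats_population_divisor():
    st = fs_run_stats([0.1, 0.2, 0.3], [0.5, 0.5, 0.5], [0.4, 0.5, 0.6])
    assert st.average_fitness == pytest.approx(0.5)
    assert st.best_fitness == 0.4 and st.worst_fitness == 0.6
    assert st.std_fitness == pytest.approx(math.sqrt(0.02 / 3))


def test_fs_run_stats_degenerate():
    st = fs_run_stats([0.1], [0.2], [0.7])
    assert st.average_fitness == st.best_fitness == st.worst_fitness == 0.7
    assert st.std_fitness == 0.0
    same = fs_run_stats([0.1] * 5, [0.2] * 5, [0.7] * 5)
    assert same.std_fitness == 0.0
    with pytest.raises(InvalidParameterError):
        fs_run_stats([], [], [])


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_anova_hand_example():
    table = one_way_anova([[0.0, 1.0], [2.0, 3.0]])
    assert table.ss_between == pytest.approx(4.0)
    assert table.ms_within == pytest.approx(0.5)
    assert table.f_stat == pytest.approx(8.0)


def test_anova_published_cells():
    table = anova_from_sums(0.01415, 5, 0.0009636, 54)
    assert round(table.f_stat, 1) == 158.6
    assert table.ms_within == pytest.approx(0.00001784, abs=5e-9)
    assert table.p_value < 0.0001


def test_anova_degenerate_groups():
    table = one_way_anova([[1.0, 1.0], [1.0, 1.0]])
    assert table.degenerate and math.isinf(table.f_stat) and table.p_value == 0.0


def test_anova_matches_scipy_and_additivity(rng):
    for _ in range(50):
        groups = [rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(3, 12)) for _ in range(4)]
        table = one_way_anova(groups)
        f_ref, p_ref = sps.f_oneway(*groups)
        assert table.f_stat == pytest.approx(f_ref, rel=1e-10)
        assert table.p_value == pytest.approx(p_ref, rel=1e-8)
        allv = np.concatenate(groups)
        ss_total = float(((allv - allv.mean()) ** 2).sum())
        assert table.ss_total == pytest.approx(ss_total, rel=1e-9)


def test_anova_input_validation():
    with pytest.raises(InvalidParameterError):
        one_way_anova([[1.0, 2.0]])
    with pytest.raises(InvalidParameterError):
        one_way_anova([[1.0], [2.0, 3.0]])


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------

def test_wilcoxon_ten_positive_differences():
    res = wilcoxon_signed_rank_exact(np.arange(1.0, 11.0))
    assert res.w_positive == 55 and res.w_negative == 0
    assert res.w_statistic == 55
    assert res.exact_flag
    assert res.p_two_tailed == pytest.approx(2 / 1024)
    assert round(res.p_two_tailed, 3) == 0.002


def test_wilcoxon_five_positive_differences():
    res = wilcoxon_signed_rank_exact([1.0, 2.0, 3.0, 4.0, 5.0])
    assert res.p_two_tailed == pytest.approx(2 / 32)


def test_wilcoxon_antisymmetry():
    d = np.array([0.3, -1.2, 2.5, 0.7, -0.1, 1.9])
    a = wilcoxon_signed_rank_exact(d)
    b = wilcoxon_signed_rank_exact(-d)
    assert a.w_positive == b.w_negative and a.w_negative == b.w_positive
    assert a.p_two_tailed == pytest.approx(b.p_two_tailed)
    assert a.w_positive + a.w_negative == a.n_effective * (a.n_effective + 1) / 2


def test_wilcoxon_discards_zeros_and_rejects_all_zero():
    res = wilcoxon_signed_rank_exact([0.0, 1.0, -2.0, 0.0, 3.0])
    assert res.n_effective == 3
    with pytest.raises(UndefinedTestError):
        wilcoxon_signed_rank_exact([0.0, 0.0])


def _brute_force_exact_p(d):
    ranks = sps.rankdata(np.abs(d))
    w_obs = min(ranks[np.asarray(d) > 0].sum(), ranks[np.asarray(d) < 0].sum())
    count = 0
    n = len(d)
    for signs in itertools.product((1, -1), repeat=n):
        w_pos = sum(r for r, s in zip(ranks, signs) if s > 0)
        if min(w_pos, ranks.sum() - w_pos) <= w_obs:
            count += 1
    # two-sided: 2 * P(W <= w_obs) with W = min tail
    low = sum(
        1
        for signs in itertools.product((1, -1), repeat=n)
        if sum(r for r, s in zip(ranks, signs) if s > 0) <= w_obs
    )
    return min(1.0, 2.0 * low / 2**n)


@pytest.mark.parametrize("n", [4, 7, 10, 12])
def test_wilcoxon_exact_equals_enumeration(n, rng):
    d = rng.normal(size=n)
    while len(np.unique(np.abs(d))) < n or np.any(d == 0):
        d = rng.normal(size=n)
    res = wilcoxon_signed_rank_exact(d)
    assert res.exact_flag
    assert res.p_two_tailed == pytest.approx(_brute_force_exact_p(d), abs=1e-12)


def test_wilcoxon_matches_scipy_exact(rng):
    for _ in range(10):
        d = rng.normal(size=9)
        if len(np.unique(np.abs(d))) < 9:
            continue
        ours = wilcoxon_signed_rank_exact(d)
        ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert ours.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_approximation_path_with_ties():
    d = np.array([1.0, 1.0, -1.0, 2.0, 3.0, 3.0, -2.0, 4.0] * 4)
    res = wilcoxon_signed_rank_exact(d)
    assert not res.exact_flag and 0.0 < res.p_two_tailed <= 1.0


def test_pairwise_wilcoxon_structure():
    ref = np.linspace(0.9, 0.99, 10)
    others = {"a": ref - 0.05, "b": ref - 0.01}
    out = pairwise_wilcoxon(ref, others)
    assert set(out) == {"a", "b"}
    assert out["a"].w_positive == 55.0
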