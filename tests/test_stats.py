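"""Validation statistics against independent oracles.

Every nontrivial quantity is cross-checked against a route independent of
the implementation: exhaustive pair counting and sklearn's trapezoidal ROC
area for the AUC, full permutation enumeration for the exact Wilcoxon test,
exact-binomial-test inversion and statsmodels for Clopper–Pearson, and a
stratified bootstrap for the DeLong interval.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.optimize import brentq
from sklearn.metrics import roc_auc_score

from rheumascore import (
    ConfusionTable2x2,
    LabelledParticipant,
    ScoredCohort,
    auc_roc,
    clopper_pearson,
    confusion_at_threshold,
    diagnostic_accuracy,
    evaluate_cohort,
    summarize_scores,
    wilcoxon_rank_sum,
)
from rheumascore.exceptions import EvaluationError
from rheumascore.stats import percent


def make_cohort(scores, outcomes, t1=None, t2=None) -> ScoredCohort:
    t1 = t1 if t1 is not None else [False] * len(scores)
    t2 = t2 if t2 is not None else [False] * len(scores)
    return ScoredCohort(
        "toy",
        [
            LabelledParticipant(f"p{i}", int(s), bool(a), bool(b), int(o))
            for i, (s, o, a, b) in enumerate(zip(scores, outcomes, t1, t2))
        ],
    )


# ---------------------------------------------------------------------------
# summaries


def test_group_summaries_split_by_outcome():
    cohort = make_cohort([7, 163, 444, 101, 245, 445], [0, 0, 0, 1, 1, 1])
    by_group = {s.group: s for s in summarize_scores(cohort)}
    assert by_group["outcome=0"].min == 7
    assert by_group["outcome=1"].min == 101
    assert by_group["outcome=0"].median == 163
    assert by_group["outcome=1"].median == 245
    assert by_group["all"].n == 6


def test_single_participant_summary():
    cohort = make_cohort([5], [1])
    s = {x.group: x for x in summarize_scores(cohort)}
    assert s["outcome=1"].mean == s["outcome=1"].median == 5
    assert "outcome=0" not in s  # empty group omitted


def test_summaries_are_order_invariant(rng):
    scores = rng.integers(0, 500, size=30)
    outcomes = rng.integers(0, 2, size=30)
    a = summarize_scores(make_cohort(scores, outcomes))
    perm = rng.permutation(30)
    b = summarize_scores(make_cohort(scores[perm], outcomes[perm]))
    assert a == b


def test_even_group_median_is_midpoint():
    s = {x.group: x for x in summarize_scores(make_cohort([10, 20], [1, 1]))}
    assert s["outcome=1"].median == 15


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def permutation_pvalue(x, y) -> float:
    """Oracle: exact two-sided p by enumerating every group assignment."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    lo = min(u_obs, n1 * len(y) - u_obs)
    hi = max(u_obs, n1 * len(y) - u_obs)
    cnt = tot = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        tot += 1
        cnt += u <= lo or u >= hi
    return min(cnt / tot, 1.0)


def test_tiny_exact_case_enumerates_to_one_third():
    res = wilcoxon_rank_sum([1, 2], [3, 4])
    assert res.u == 0
    assert res.method == "exact"
    assert res.pvalue == pytest.approx(2 / 6)


def test_identical_samples_give_p_one():
    res = wilcoxon_rank_sum([3, 3, 3], [3, 3, 3])
    assert res.degenerate and res.pvalue == 1.0


def test_equal_multisets_not_significant():
    x = list(range(30))
    res = wilcoxon_rank_sum(x, x)
    assert res.method == "normal_approx"
    assert res.pvalue >= 0.99


def test_exact_p_matches_permutation_enumeration(rng):
    for _ in range(25):
        n1 = int(rng.integers(1, 8))
        n2 = int(rng.integers(1, 8))
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(permutation_pvalue(x, y), abs=1e-12)
        assert 0 <= res.u <= n1 * n2


def test_ties_fall_back_to_corrected_normal_approximation(rng):
    x = rng.integers(0, 4, size=8).astype(float)
    y = rng.integers(0, 4, size=7).astype(float)
    res = wilcoxon_rank_sum(x, y)
    assert res.method == "normal_approx"
    assert 0 < res.pvalue <= 1


# ---------------------------------------------------------------------------
# AUC-ROC


def pair_count_auc(scores, labels) -> float:
    """Oracle: exhaustive concordant/tied pair counting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_perfect_separation_gives_auc_one():
    res = auc_roc([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0])
    assert res.auc == 1.0
    assert res.ci_high == 1.0


def test_all_tied_scores_give_half():
    res = auc_roc([5, 5, 5, 5], [1, 0, 1, 0])
    assert res.auc == 0.5


def test_single_class_is_an_error():
    with pytest.raises(EvaluationError):
        auc_roc([1, 2, 3], [1, 1, 1])


def test_auc_matches_pair_counting_and_trapezoidal_roc(rng):
    for _ in range(40):
        n = int(rng.integers(4, 40))
        scores = rng.integers(0, 12, size=n).astype(float)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = auc_roc(scores, labels)
        assert res.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)
        # sklearn's roc_auc_score is the trapezoidal area under the ROC curve
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        assert 0 <= res.ci_low <= res.auc <= res.ci_high <= 1


def test_auc_complement_symmetry(rng):
    """AUC(s) + AUC(-s) = 1 when no positive ties a negative."""
    for _ in range(20):
        pos = rng.normal(1, 1, size=int(rng.integers(2, 15)))
        neg = rng.normal(0, 1, size=int(rng.integers(2, 15)))
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * len(pos) + [0] * len(neg))
        a = auc_roc(scores, labels).auc
        b = auc_roc(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


def test_delong_ci_close_to_stratified_bootstrap(rng):
    """DeLong endpoints within 0.02 of a 2000-replicate bootstrap CI."""
    n = 100
    pos = rng.normal(1.0, 1.0, size=n)
    neg = rng.normal(0.0, 1.0, size=n)
    scores = np.concatenate([pos, neg])
    labels = np.array([1] * n + [0] * n)
    res = auc_roc(scores, labels)
    boots = np.empty(2000)
    for b in range(2000):
        bp = pos[rng.integers(0, n, n)]
        bn = neg[rng.integers(0, n, n)]
        ranks = sps.rankdata(np.concatenate([bp, bn]))
        boots[b] = (ranks[:n].sum() - n * (n + 1) / 2) / (n * n)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    assert res.ci_low == pytest.approx(lo, abs=0.02)
    assert res.ci_high == pytest.approx(hi, abs=0.02)


# ---------------------------------------------------------------------------
# Clopper–Pearson


def inversion_interval(x, n, level=0.95):
    """Oracle: invert the exact binomial test by root search over p."""
    alpha = 1 - level
    lo = 0.0 if x == 0 else brentq(
        lambda p: sps.binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-13
    )
    hi = 1.0 if x == n else brentq(
        lambda p: sps.binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-13
    )
    return lo, hi


def test_known_interval_17_of_28():
    # endpoints cross-checked against R's binom.test(17, 28)$conf.int
    lo, hi = clopper_pearson(17, 28)
    assert lo == pytest.approx(0.405768, abs=5e-6)
    assert hi == pytest.approx(0.784957, abs=5e-6)
    assert (percent(lo), percent(hi)) == (41, 78)


def test_known_interval_20_of_23():
    lo, hi = clopper_pearson(20, 23)
    assert (percent(20 / 23), percent(lo), percent(hi)) == (87, 66, 97)


def test_boundary_conventions():
    assert clopper_pearson(0, 10)[0] == 0.0
    assert clopper_pearson(10, 10)[1] == 1.0


def test_endpoints_match_binomial_test_inversion(rng):
    for _ in range(100):
        n = int(rng.integers(1, 51))
        x = int(rng.integers(0, n + 1))
        got = clopper_pearson(x, n)
        want = inversion_interval(x, n)
        assert got[0] == pytest.approx(want[0], abs=1e-9)
        assert got[1] == pytest.approx(want[1], abs=1e-9)


def test_matches_statsmodels_beta_interval(rng):
    from statsmodels.stats.proportion import proportion_confint

    for _ in range(50):
        n = int(rng.integers(1, 80))
        x = int(rng.integers(0, n + 1))
        want = proportion_confint(x, n, alpha=0.05, method="beta")
        got = clopper_pearson(x, n)
        assert got[0] == pytest.approx(np.nan_to_num(want[0]), abs=1e-10)
        assert got[1] == pytest.approx(np.nan_to_num(want[1], nan=1.0), abs=1e-10)


@settings(derandomize=True, max_examples=80, deadline=None)
@given(n=st.integers(1, 200), frac=st.floats(0, 1), level=st.sampled_from([0.9, 0.95, 0.99]))
def test_interval_properties(n, frac, level):
    x = min(int(frac * (n + 1)), n)
    lo, hi = clopper_pearson(x, n, level)
    assert 0.0 <= lo <= x / n <= hi <= 1.0


def test_exact_intervals_are_conservative(rng):
    """Empirical coverage >= nominal over 2000 simulated binomials, n=30."""
    n = 30
    intervals = [clopper_pearson(x, n) for x in range(n + 1)]
    for p in (0.1, 0.5, 0.9):
        xs = rng.binomial(n, p, size=2000)
        covered = np.array([intervals[x][0] <= p <= intervals[x][1] for x in xs])
        assert covered.mean() >= 0.95


# ---------------------------------------------------------------------------
# confusion tables and accuracy


def test_confusion_counts_partition_cohort(rng):
    n = 40
    outcomes = rng.integers(0, 2, size=n)
    t1 = rng.integers(0, 2, size=n).astype(bool)
    cohort = make_cohort(rng.integers(0, 100, n), outcomes, t1, [False] * n)
    table = confusion_at_threshold(cohort, 1)
    assert table.n == n
    assert table.tp + table.fn == outcomes.sum()
    assert table.fp + table.tn == n - outcomes.sum()
    t_nobody = confusion_at_threshold(cohort, 2)
    assert t_nobody.tp == t_nobody.fp == 0


def test_accuracy_from_validation_counts():
    acc = diagnostic_accuracy(ConfusionTable2x2(tp=14, fn=7, fp=8, tn=21))
    assert (acc.sens_pct, acc.spec_pct) == (67, 72)
    acc2 = diagnostic_accuracy(ConfusionTable2x2(tp=1, fn=20, fp=0, tn=29))
    assert (acc2.sens_pct, acc2.spec_pct) == (5, 100)


def test_perfect_table():
    acc = diagnostic_accuracy(ConfusionTable2x2(tp=10, fn=0, fp=0, tn=12))
    assert acc.sensitivity == 1.0 and acc.specificity == 1.0


def test_empty_margin_is_an_error():
    with pytest.raises(EvaluationError) as exc:
        diagnostic_accuracy(ConfusionTable2x2(tp=0, fn=0, fp=3, tn=4))
    assert "sensitivity" in str(exc.value)


def test_percent_rounds_half_away_from_zero():
    assert percent(14 / 21) == 67
    assert percent(1 / 21) == 5
    assert percent(22 / 23) == 96
    assert percent(20 / 22) == 91
    assert percent(0.125) == 13  # 12.5 -> 13


# ---------------------------------------------------------------------------
# full evaluation


def test_two_participant_cohort_completes():
    cohort = make_cohort([10, 5], [1, 0], [True, False], [False, False])
    rep = evaluate_cohort(cohort)
    assert rep.auc.auc == 1.0
    assert rep.wilcoxon.pvalue == 1.0  # n too small for significance
    assert set(rep.thresholds) == {1, 2}


def test_single_class_cohort_partial_report(caplog):
    cohort = make_cohort([10, 5, 7], [1, 1, 1])
    rep = evaluate_cohort(cohort)
    assert rep.wilcoxon is None and rep.auc is None and rep.thresholds == {}


def test_null_cohorts_give_chance_auc_and_uniform_p(rng):
    """No group difference: AUC near 1/2 and Wilcoxon p-values uniform."""
    aucs, pvals = [], []
    for _ in range(400):
        scores = rng.normal(size=60)
        labels = np.array([1] * 30 + [0] * 30)
        aucs.append(auc_roc(scores, labels).auc)
        pvals.append(wilcoxon_rank_sum(scores[:30], scores[30:]).pvalue)
    assert abs(np.mean(aucs) - 0.5) < 0.02
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_report_render_and_frames():
    cohort = make_cohort(
        [50, 40, 30, 20, 10, 5],
        [1, 1, 1, 0, 0, 0],
        [True, True, False, True, False, False],
        [True, False, False, False, False, False],
    )
    rep = evaluate_cohort(cohort)
    text = rep.render_text()
    assert "sensitivity" in text and "AUC-ROC" in text
    assert len(rep.summary_frame()) == 3
    assert list(rep.accuracy_frame()["threshold"]) == [1, 2]
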