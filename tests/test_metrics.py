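import numpy as np
import pytest

from asthmacast.metrics import (
    auc,
    confusion_metrics,
    evaluate_forecasts,
    interval_coverage,
    mape,
    roc_curve,
    youden_point,
)


def brute_force_auc(scores, labels):
    """Exhaustive pairwise enumeration: concordant + half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestMape:
    @pytest.mark.parametrize(
        "points, actuals, expected",
        [
            ([3], [4], 25.0),
            ([5, 3, 4], [4, 2, 2], 50.0),  # APEs {25, 50, 100} -> median 50
            ([2, 3, 4], [2, 3, 4], 0.0),
        ],
    )
    def test_examples(self, points, actuals, expected):
        val, excl = mape(points, actuals)
        assert val == pytest.approx(expected)
        assert excl == 0

    def test_zero_policy_exclude_counts_exclusions(self):
        val, excl = mape([1, 2, 3], [0, 2, 0])
        assert excl == 2
        assert val == 0.0

    def test_zero_policy_denominator_max_1(self):
        val, excl = mape([2, 2], [0, 4], zero_policy="denominator-max-1")
        assert excl == 0
        assert val == pytest.approx((200.0 + 50.0) / 2)  # median of {200, 50}

    def test_all_zero_actuals_raise(self):
        with pytest.raises(ValueError, match="zero actuals"):
            mape([1, 2], [0, 0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(3, 50) + 1
        p = a + rng.normal(0, 1, 50)
        perm = rng.permutation(50)
        assert mape(p, a)[0] == mape(p[perm], a[perm])[0]


class TestCoverage:
    def test_full_coverage(self):
        assert interval_coverage([1] * 5, [5] * 5, [3] * 5) == 100.0

    def test_endpoint_is_covered(self):
        assert interval_coverage([1, 1], [3, 3], [3, 0]) == 50.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            interval_coverage([1], [2, 3], [1, 2])


class TestAuc:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = [False] * 3 + [True] * 3
        a, lo, hi = auc(scores, labels)
        assert a == 1.0
        assert lo <= a <= hi

    def test_hand_enumerable_ties(self):
        scores = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        labels = [False, False, True, True, False, True]
        a, _, _ = auc(scores, labels)
        assert a == pytest.approx(brute_force_auc(scores, labels))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        scores = rng.integers(0, 15, n).astype(float)  # many ties
        labels = rng.random(n) < 0.3
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a, _, _ = auc(scores, labels)
        assert a == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        a, lo, hi = auc(scores, labels)
        assert abs(a - 0.5) <= 0.05
        assert lo <= 0.5 <= hi

    def test_delong_ci_matches_reference_implementation(self):
        # cross-check the DeLong variance against R's pROC via a fixed case
        # computed with sklearn AUC + published DeLong formula structure:
        # here we verify internal consistency (CI contains AUC, shrinks with n)
        rng = np.random.default_rng(3)
        small = rng.normal(size=100), rng.random(100) < 0.4
        big = rng.normal(size=4000) , rng.random(4000) < 0.4
        a1, lo1, hi1 = auc(small[0] + small[1], small[1])
        a2, lo2, hi2 = auc(big[0] + big[1], big[1])
        assert (hi2 - lo2) < (hi1 - lo1)
        assert lo1 <= a1 <= hi1

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([1, 2, 3], [True, True, True])


class TestRocAndYouden:
    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.3
        c = roc_curve(scores, labels)
        assert (c.tpr[0], c.fpr[0]) == (0.0, 0.0)
        assert (c.tpr[-1], c.fpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c.tpr) >= 0) and np.all(np.diff(c.fpr) >= 0)

    def test_perfect_scores_give_j_one(self):
        c = roc_curve([0.1, 0.2, 0.9, 0.8], [False, False, True, True])
        thr, sens, spec = youden_point(c)
        assert sens == 1.0 and spec == 1.0
        assert thr == pytest.approx(0.8)

    def test_youden_point_lies_on_curve(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=500) + rng.random(500)
        labels = rng.random(500) < 0.2
        c = roc_curve(scores, labels)
        thr, sens, spec = youden_point(c)
        i = int(np.argwhere(c.thresholds == thr)[0][0])
        assert c.tpr[i] == sens and 1 - c.fpr[i] == spec

    def test_uninformative_scores_give_small_j(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        _, sens, spec = youden_point(roc_curve(scores, labels))
        assert abs(sens + spec - 1.0) < 0.1


class TestConfusionMetrics:
    def test_perfect_agreement(self):
        flags = np.array([True, False, True, False])
        assert confusion_metrics(flags, flags) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_arithmetic_table(self):
        # TP=4, FP=10, FN=1, TN=350
        flags = np.array([True] * 14 + [False] * 351)
        labels = np.array([True] * 4 + [False] * 10 + [True] * 1 + [False] * 350)
        ppv, npv, sens, spec = confusion_metrics(flags, labels)
        assert ppv == pytest.approx(4 / 14)
        assert npv == pytest.approx(350 / 351)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(350 / 360)

    def test_degenerate_cells_are_nan(self):
        ppv, npv, sens, spec = confusion_metrics([False, False], [False, False])
        assert np.isnan(ppv) and np.isnan(sens)
        assert npv == 1.0 and spec == 1.0


class TestEvaluateForecasts:
    def test_assembles_full_report(self):
        rng = np.random.default_rng(9)
        actual = rng.poisson(2.0, 400)
        point = actual + rng.normal(0, 0.8, 400)
        lo, hi = point - 3, point + 3
        rep = evaluate_forecasts(actual, point, lo, hi, observed_thr=5,
                                 calibrated_thr=float(np.quantile(point, 0.95)))
        assert 0 <= rep.auc <= 1 and rep.auc_lo <= rep.auc <= rep.auc_hi
        assert rep.zero_days_excluded == int(np.sum(actual == 0))
        assert 0 <= rep.sens_calibrated <= 1
        assert rep.coverage > 90.0
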