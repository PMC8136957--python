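"""ROC statistics: Mann-Whitney AUC, Youden cut-points, and exact
binomial confidence intervals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from biodyn.biomarkers import BiomarkerPanel
from biodyn.errors import DataError, StatisticsError
from biodyn.roc import (
    auc,
    clopper_pearson,
    optimal_cutoff,
    roc_points,
    summaries_to_frame,
    summarize,
)

# score/label configurations mirroring the published misclassification
# structures at n = 10
PERFECT = (np.array([6.0, 7, 8, 9, 10, 11, 12, 1, 2, 3]),
           np.array([True] * 7 + [False] * 3))
ONE_NEG_ABOVE_ALL = (np.array([6.0, 7, 8, 0, 1, 2, 3, 4, 5, 10]),
                     np.array([True] * 3 + [False] * 7))
ONE_NEG_ABOVE_ALL_PLUS_ONE = (np.array([6.0, 7, 8, 0, 1, 2, 3, 4, 6.5, 10]),
                              np.array([True] * 3 + [False] * 7))


def brute_force_auc(scores, labels):
    """O(n^2) pair-counting oracle: ties count 1/2."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc(*PERFECT) == 1.0

    def test_one_negative_above_all_positives(self):
        assert auc(*ONE_NEG_ABOVE_ALL) == pytest.approx(18 / 21)

    def test_one_negative_above_all_plus_one_above_one(self):
        assert auc(*ONE_NEG_ABOVE_ALL_PLUS_ONE) == pytest.approx(17 / 21)

    def test_all_ties_give_half(self):
        assert auc(np.ones(10), np.array([True] * 4 + [False] * 6)) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(StatisticsError):
            auc(np.arange(5.0), np.ones(5, dtype=bool))

    @given(
        n=st.integers(min_value=2, max_value=50),
        seed=st.integers(min_value=0, max_value=2**16),
        ties=st.booleans(),
    )
    def test_matches_brute_force_pair_counting(self, n, seed, ties):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(n)
        if ties:
            scores = np.round(scores, 1)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        for _ in range(20):
            scores = np.round(rng.standard_normal(30), 1)
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    @given(seed=st.integers(min_value=0, max_value=2**16))
    def test_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(12)
        labels = np.array([True] * 5 + [False] * 7)
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)


class TestOptimalCutoff:
    def test_perfect_separation_operating_point(self):
        cut = optimal_cutoff(*PERFECT)
        assert cut.sensitivity == 100.0 and cut.fp_rate == 0.0
        assert cut.accuracy == 1.0 and cut.direction == ">="

    def test_one_misclassified_negative(self):
        cut = optimal_cutoff(*ONE_NEG_ABOVE_ALL)
        assert cut.sensitivity == 100.0
        assert cut.fp_rate == pytest.approx(100 / 7)
        assert cut.accuracy == pytest.approx(0.9)

    def test_two_misclassified_negatives(self):
        cut = optimal_cutoff(*ONE_NEG_ABOVE_ALL_PLUS_ONE)
        assert cut.sensitivity == 100.0
        assert cut.fp_rate == pytest.approx(200 / 7)
        assert cut.accuracy == pytest.approx(0.8)

    def test_direction_flips_for_inverted_scores(self):
        scores, labels = PERFECT
        cut = optimal_cutoff(-scores, labels)
        assert cut.direction == "<="
        assert cut.sensitivity == 100.0 and cut.fp_rate == 0.0
        assert np.array_equal(cut.classify(-scores), labels)

    def test_permutation_null_bias_is_small(self):
        """With labels independent of scores the maximized Youden J stays
        small at n=200 (the maximization makes it positively biased, so it
        approaches 0 only as n grows)."""
        rng = np.random.default_rng(5)
        scores = rng.standard_normal(200)
        labels = np.array([True] * 100 + [False] * 100)
        js = [
            optimal_cutoff(scores, rng.permutation(labels)).youden
            for _ in range(200)
        ]
        assert np.mean(js) < 0.2

    def test_youden_never_negative_at_optimum(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            scores = rng.standard_normal(12)
            labels = rng.random(12) < 0.5
            if labels.all() or not labels.any():
                continue
            assert optimal_cutoff(scores, labels).youden >= 0


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,low,high",
        [
            (10, 10, 0.692, 1.000),
            (9, 10, 0.555, 0.997),
            (8, 10, 0.444, 0.975),
            (0, 10, 0.000, 0.308),
        ],
    )
    def test_published_intervals(self, k, n, low, high):
        lo, hi = clopper_pearson(k, n)
        assert round(lo, 3) == low and round(hi, 3) == high

    @given(
        n=st.integers(min_value=1, max_value=60),
        frac=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_bounds_invert_the_binomial_test(self, n, frac):
        """At the lower bound P(X >= k) = alpha/2; at the upper bound
        P(X <= k) = alpha/2 (within 1e-9)."""
        k = int(round(frac * n))
        lo, hi = clopper_pearson(k, n)
        if k > 0:
            assert stats.binom.sf(k - 1, n, lo) == pytest.approx(0.025, abs=1e-9)
        if k < n:
            assert stats.binom.cdf(k, n, hi) == pytest.approx(0.025, abs=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(DataError):
            clopper_pearson(5, 4)
        with pytest.raises(DataError):
            clopper_pearson(-1, 4)
        with pytest.raises(DataError):
            clopper_pearson(1, 0)


class TestSummarize:
    @staticmethod
    def panel_and_labels():
        labels = pd.Series(
            [True] * 7 + [False] * 3, index=[f"S{i + 1}" for i in range(10)]
        )
        perfect = np.array([1.0, 2, 3, 4, 5, 6, 7, -1, -2, -3])
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            {"Planted": perfect, "Noise": rng.standard_normal(10)},
            index=labels.index,
        )
        panel = BiomarkerPanel(
            values=values, families={"Planted": "local", "Noise": "local"}
        )
        return panel, labels

    def test_planted_perfect_biomarker_row(self):
        panel, labels = self.panel_and_labels()
        rows = {s.biomarker: s for s in summarize(panel, labels, "deep_drop")}
        planted = rows["Planted"]
        assert planted.auc == 1.0
        assert (round(planted.ci_low, 3), planted.ci_high) == (0.692, 1.0)
        assert planted.sensitivity == 100.0 and planted.fp_rate == 0.0
        assert planted.n_pos == 7 and planted.n_neg == 3

    def test_nine_of_ten_accuracy_interval(self):
        scores, labels = ONE_NEG_ABOVE_ALL
        panel = BiomarkerPanel(
            values=pd.DataFrame(
                {"B": scores}, index=[f"S{i}" for i in range(10)]
            ),
            families={"B": "global"},
        )
        s = summarize(panel, pd.Series(labels, index=panel.values.index))[0]
        assert s.accuracy == pytest.approx(0.9)
        assert (round(s.ci_low, 3), round(s.ci_high, 3)) == (0.555, 0.997)

    def test_subject_mismatch_listed(self):
        panel, labels = self.panel_and_labels()
        bad = labels.rename(index={"S10": "S11"})
        with pytest.raises(DataError, match="S10"):
            summarize(panel, bad)

    def test_frame_export(self):
        panel, labels = self.panel_and_labels()
        frame = summaries_to_frame(summarize(panel, labels))
        assert {"biomarker", "auc", "ci_low", "ci_high", "optimal_cutoff",
                "sensitivity", "fp_rate"} <= set(frame.columns)
        assert len(frame) == 2


def test_roc_points_monotone():
    scores, labels = ONE_NEG_ABOVE_ALL
    pts = roc_points(scores, labels)
    assert pts["sensitivity"].is_monotonic_increasing
    assert pts["fp_rate"].is_monotonic_increasing
    assert pts["sensitivity"].iloc[-1] == 1.0 and pts["fp_rate"].iloc[-1] == 1.0
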