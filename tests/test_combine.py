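"""Empirical AUC, score combination, threshold rule, vote, evaluation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cxrtriage import (ScoreMatrix, ThresholdRule, empirical_auc, evaluate_binary,
                       evaluate_triage, fit_combination, fit_threshold_rule,
                       threshold_sweep, triage_vote)
from cxrtriage.combine import ABNORMAL, NORMAL, UNCERTAIN


def brute_force_auc(pos, neg):
    """Independent pairwise count with half-credit for ties."""
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestEmpiricalAUC:
    def test_perfect_separation(self):
        assert empirical_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_tie_convention(self):
        assert empirical_auc([0.5], [0.5]) == 0.5

    def test_four_pair_hand_count(self):
        assert empirical_auc([0.8, 0.6], [0.7, 0.1]) == 0.75

    def test_matches_bruteforce_with_ties(self, rng):
        for _ in range(50):
            pos = rng.integers(0, 5, size=rng.integers(1, 20)).astype(float)
            neg = rng.integers(0, 5, size=rng.integers(1, 20)).astype(float)
            assert empirical_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_invariant_under_monotone_transform(self, data):
        # quarter-integer grid keeps distinct scores distinct after exp()
        grid = st.integers(-20, 20).map(lambda v: v / 4.0)
        pos = np.array(data.draw(st.lists(grid, min_size=1, max_size=15)))
        neg = np.array(data.draw(st.lists(grid, min_size=1, max_size=15)))
        base = empirical_auc(pos, neg)
        assert empirical_auc(np.exp(pos), np.exp(neg)) == pytest.approx(base)
        assert empirical_auc(3 * pos + 7, 3 * neg + 7) == pytest.approx(base)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([], [0.1])


class TestFitCombination:
    def test_duplicate_predictor_gives_zero_beta(self):
        c1 = np.array([0.9, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        model = fit_combination(ScoreMatrix(np.column_stack([c1, c1]), labels))
        assert model.beta[0] == 0.0
        assert model.auc == 1.0

    def test_combined_auc_at_least_c1_alone(self, rng):
        for _ in range(10):
            scores = rng.random((20, 2))
            labels = (rng.random(20) < 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            model = fit_combination(ScoreMatrix(scores, labels))
            c1_auc = empirical_auc(scores[labels == 1, 0], scores[labels == 0, 0])
            assert model.auc >= c1_auc - 1e-12

    def test_matches_exhaustive_double_loop_oracle(self, rng):
        """Small instance, grid {-2..2} step 0.5, vs independent exhaustive search."""
        grid = np.arange(-2.0, 2.5, 0.5)
        scores = rng.random((6, 2))
        labels = np.array([1, 1, 1, 0, 0, 0])
        model = fit_combination(ScoreMatrix(scores, labels), beta_grid=grid)
        best_auc = -1.0
        for b in grid:
            s = scores[:, 0] + b * scores[:, 1]
            auc = brute_force_auc(s[labels == 1], s[labels == 0])
            best_auc = max(best_auc, auc)
        assert model.auc == pytest.approx(best_auc)

    def test_large_beta_recovers_c2(self, rng):
        """With a wide grid the fit can ride an informative C2 despite a null C1."""
        n = 40
        labels = np.array([1] * 20 + [0] * 20)
        c1 = rng.random(n)  # uninformative
        c2 = labels + 0.05 * rng.random(n)  # nearly perfect
        model = fit_combination(ScoreMatrix(np.column_stack([c1, c2]), labels))
        c2_auc = empirical_auc(c2[labels == 1], c2[labels == 0])
        assert model.auc >= c2_auc - 0.02

    def test_grid_without_zero_rejected(self, rng):
        scores = rng.random((4, 2))
        with pytest.raises(ValueError):
            fit_combination(ScoreMatrix(scores, np.array([1, 0, 1, 0])),
                            beta_grid=np.array([1.0, 2.0]))


class TestThresholdRule:
    def test_perfect_probability_any_valid_p(self):
        prob = np.array([0.9, 0.95, 0.1, 0.2])
        err = np.full(4, 0.5)
        labels = np.array([1, 1, 0, 0])
        rule = fit_threshold_rule(prob, err, labels, t_mean=1.0)
        assert rule.auc == 1.0
        assert 0.5 < rule.p < 1.0
        assert 0.0 < rule.t < 1.0

    def test_matches_exhaustive_search(self, rng):
        """5x5 grid on an 8-case instance vs independent exhaustive evaluation."""
        prob = rng.random(8)
        err = rng.random(8)
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        t_mean = 0.8
        rule = fit_threshold_rule(prob, err, labels, t_mean=t_mean, grid_sizes=(5, 5))
        best = None
        for p_thr in [0.5 + 0.5 * j / 6 for j in range(1, 6)]:
            for t_thr in [t_mean * i / 6 for i in range(1, 6)]:
                score = (err > t_thr).astype(int) + (prob > p_thr).astype(int)
                auc = brute_force_auc(score[labels == 1].astype(float),
                                      score[labels == 0].astype(float))
                key = (-auc, p_thr, t_thr)
                if best is None or key < best:
                    best = key
        assert rule.auc == pytest.approx(-best[0])
        assert rule.p == pytest.approx(best[1])
        assert rule.t == pytest.approx(best[2])

    def test_invalid_t_mean_rejected(self):
        with pytest.raises(ValueError):
            fit_threshold_rule(np.array([0.5]), np.array([0.1]), np.array([1, 0]), t_mean=0.0)

    def test_flags_and_votes(self):
        rule = ThresholdRule(t=0.5, p=0.7, t_mean=1.0)
        prob = np.array([0.9, 0.6, 0.1])
        err = np.array([0.6, 0.2, 0.1])
        np.testing.assert_array_equal(rule.flags(prob, err), [2, 0, 0])
        np.testing.assert_array_equal(rule.votes(prob, err), [1, 0, 0])


class TestVote:
    @pytest.mark.parametrize("votes,expected", [
        ([0, 0, 0, 0, 0, 0], NORMAL),
        ([1, 1, 1, 1, 1, 1], ABNORMAL),
        ([0, 1, 0, 0, 0, 0], UNCERTAIN),
    ])
    def test_unanimity_rule(self, votes, expected):
        assert triage_vote([votes]) == [expected]

    def test_too_small_panel_rejected(self):
        with pytest.raises(ValueError):
            triage_vote([[1]])


class TestEvaluate:
    def test_worked_screening_counts(self):
        """390/395 and 83/88 correct definite calls give the published-style
        97.9% pooled precision."""
        truth = np.array([0] * 390 + [1] * 5 + [1] * 83 + [0] * 5)
        levels = [NORMAL] * 395 + [ABNORMAL] * 88
        report = evaluate_triage(levels, truth)
        assert report.precision[NORMAL] == pytest.approx(390 / 395)
        assert report.precision[ABNORMAL] == pytest.approx(83 / 88)
        assert report.precision["total"] == pytest.approx(473 / 483)
        assert round(100 * report.precision[NORMAL], 1) == 98.7
        assert round(100 * report.precision[ABNORMAL], 1) == 94.3
        assert round(100 * report.precision["total"], 1) == 97.9

    def test_binary_metrics_and_confusion(self):
        pred = np.array([1, 1, 0, 0, 1])
        truth = np.array([1, 0, 0, 1, 1])
        report = evaluate_binary(pred, truth)
        assert report.confusion.sum() == 5
        assert report.precision["abnormal"] == pytest.approx(2 / 3)
        assert report.recall["abnormal"] == pytest.approx(2 / 3)
        assert report.precision["normal"] == pytest.approx(1 / 2)

    def test_perfect_prediction(self):
        truth = np.array([0, 1, 0, 1])
        report = evaluate_binary(truth, truth, scores=truth.astype(float))
        assert report.precision["abnormal"] == report.recall["abnormal"] == 1.0
        assert report.f1["normal"] == 1.0
        assert report.auc == 1.0

    def test_no_predicted_positives_warns(self):
        with pytest.warns(UserWarning, match="no predicted positives"):
            report = evaluate_binary(np.zeros(4, int), np.array([0, 1, 0, 1]))
        assert report.precision["abnormal"] == 0.0

    def test_all_uncertain_reports_not_applicable(self):
        report = evaluate_triage([UNCERTAIN] * 4, np.array([0, 1, 0, 1]))
        assert report.precision[NORMAL] is None
        assert report.precision["total"] is None

    def test_exact_triage_no_uncertain(self):
        truth = np.array([0, 1, 1, 0])
        levels = [NORMAL, ABNORMAL, ABNORMAL, NORMAL]
        assert evaluate_triage(levels, truth).precision["total"] == 1.0


class TestThresholdSweep:
    def test_recall_endpoints_and_monotonicity(self, rng):
        for _ in range(10):
            err = rng.random(30)
            labels = (rng.random(30) < 0.4).astype(int)
            if labels.sum() == 0:
                continue
            curve = threshold_sweep(err, labels, n_points=20)
            recalls = curve["recall"]
            below = err.min() - 0.1
            pred = err > below
            assert pred.all()  # t below the minimum flags everything: recall 1
            assert np.nanmax(recalls) <= 1.0
            assert recalls[-1] == 0.0  # t at the maximum flags nothing
            assert np.all(np.diff(recalls) <= 1e-12)

    def test_n_points_validated(self):
        with pytest.raises(ValueError):
            threshold_sweep(np.array([0.1, 0.2]), np.array([0, 1]), n_points=1)
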