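import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mowsense import (MatchCounts, auc_roc, calibration_curve, eos_accuracy,
                      event_accuracy, match_events, probabilities_to_events,
                      season_scores)


class TestDecoding:
    def test_all_zero_gives_no_events(self):
        ev = probabilities_to_events(np.zeros(215))
        assert ev.starts.size == 0

    def test_single_run_start(self):
        p = np.zeros(215)
        p[50:54] = 0.9
        ev = probabilities_to_events(p)
        assert ev.starts.tolist() == [50]
        assert ev.peak_probs[0] == pytest.approx(0.9)

    def test_two_runs_split_by_one_low_day(self):
        p = np.zeros(215)
        p[50:53] = 0.8
        p[53] = 0.2
        p[54:56] = 0.8
        ev = probabilities_to_events(p)
        assert ev.starts.tolist() == [50, 54]

    def test_min_run_days_filters_short_runs(self):
        p = np.zeros(215)
        p[50] = 0.9
        p[60:63] = 0.9
        ev = probabilities_to_events(p, min_run_days=2)
        assert ev.starts.tolist() == [60]

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            probabilities_to_events(np.zeros(10), threshold=1.0)


class TestMatchEvents:
    def test_three_days_early_is_still_a_match(self):
        c = match_events([100], [103])
        assert (c.TP, c.FP, c.FN) == (1, 0, 0)

    def test_second_prediction_in_window_is_fp(self):
        c = match_events([101, 104], [103])
        assert (c.TP, c.FP, c.FN) == (1, 1, 0)

    def test_more_than_six_days_late_misses(self):
        c = match_events([110], [103])
        assert (c.TP, c.FP, c.FN) == (0, 1, 1)

    def test_empty_season_counts_one_tn(self):
        c = match_events([], [])
        assert (c.TP, c.TN, c.FP, c.FN) == (0, 1, 0, 0)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            match_events([50, 40], [30])

    def test_counts_additive_across_fields(self):
        a = match_events([100], [103])
        b = match_events([], [])
        total = a + b
        assert (total.TP, total.TN) == (1, 1)


def _oracle_max_tp(pred, act, early=3, late=6):
    """Exhaustive max-cardinality assignment of predictions to actual events."""
    best = 0
    for k in range(min(len(pred), len(act)), 0, -1):
        for p_sub in itertools.permutations(range(len(pred)), k):
            for a_sub in itertools.combinations(range(len(act)), k):
                if all(act[a] - early <= pred[p] <= act[a] + late
                       for p, a in zip(p_sub, a_sub)):
                    return k
    return best


class TestMatchingOracle:
    def test_greedy_equals_exhaustive_on_toy_seasons(self):
        """Full enumeration of <=2 predicted x <=2 actual starts on a 30-day season."""
        days = range(0, 30, 3)
        subsets = [()] + [(a,) for a in days] + \
            [(a, b) for a in days for b in days if b > a]
        for pred in subsets:
            for act in subsets:
                counts = match_events(list(pred), list(act))
                tp = _oracle_max_tp(list(pred), list(act))
                assert counts.TP == tp, (pred, act)
                assert counts.FP == len(pred) - tp
                assert counts.FN == len(act) - tp


class TestEventAccuracy:
    def test_direct_arithmetic(self):
        assert event_accuracy(MatchCounts(TP=3, TN=1, FP=1, FN=1)) == pytest.approx(4 / 6)

    def test_perfect_and_zero(self):
        assert event_accuracy(MatchCounts(TP=2, TN=1)) == 1.0
        assert event_accuracy(MatchCounts(FP=3, FN=2)) == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            event_accuracy(MatchCounts())


class TestEosAccuracy:
    def test_high_probability_mown_field_correct(self):
        p = np.zeros((1, 215))
        p[0, 100] = 0.9
        assert eos_accuracy(p, [True]) == 1.0

    def test_all_zero_not_mown_correct_and_mown_incorrect(self):
        p = np.zeros((2, 215))
        assert eos_accuracy(p, [False, True]) == 0.5

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            eos_accuracy(np.zeros((2, 215)), [True])

    def test_max_score_method(self):
        p = np.full((1, 215), 0.4)
        # noisy-or saturates to ~1, max stays at 0.4
        assert season_scores(p, "max")[0] == pytest.approx(0.4)
        assert season_scores(p, "noisy_or")[0] > 0.99


class TestAuc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_roc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5

    def test_small_example(self):
        # pairs: (.9>.3), (.9>.8), (.4>.3), (.4<.8) -> 3/4
        assert auc_roc([0.9, 0.4, 0.3, 0.8], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.9], [1, 1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
        flags = rng.integers(0, 2, size=n).astype(bool)
        if flags.all() or not flags.any():
            flags[0] = ~flags[0]
        pos, neg = scores[flags], scores[~flags]
        brute = np.mean([
            1.0 if p > q else 0.5 if p == q else 0.0
            for p in pos for q in neg
        ])
        assert auc_roc(scores, flags) == pytest.approx(brute, abs=1e-12)

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.random(200)
        flags = rng.integers(0, 2, 200)
        assert auc_roc(scores, flags) == pytest.approx(
            roc_auc_score(flags, scores), abs=1e-12)


class TestCalibration:
    def test_bernoulli_sampled_scores_sit_on_diagonal(self):
        rng = np.random.default_rng(0)
        scores = rng.random(5000)
        flags = (rng.random(5000) < scores).astype(float)
        mean_pred, observed, count = calibration_curve(scores, flags, n_bins=10)
        occupied = count > 0
        assert np.nanmax(np.abs(mean_pred[occupied] - observed[occupied])) < 0.05

    def test_single_occupied_bin(self):
        mean_pred, observed, count = calibration_curve([1.0, 1.0], [1.0, 1.0])
        assert count[-1] == 2 and mean_pred[-1] == 1.0 and observed[-1] == 1.0
        assert count[:-1].sum() == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([], [])
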