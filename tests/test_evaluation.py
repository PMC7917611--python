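"""Recognition metrics, ROC and spatiotemporal gait parameters."""

import math

import numpy as np
import pytest

from gaitphase import (
    WindowSpec,
    classification_metrics,
    confusion_matrix,
    gait_parameters,
    left_right_ratio,
    macro_metrics,
    match_states,
    phase_fraction_percent,
    roc_curve,
    swing_ratio_error,
)
from gaitphase.evaluation import ConfusionMatrix


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        truth = [1, 2, 3, 4, 1, 2]
        cm = confusion_matrix(truth, truth)
        assert np.trace(cm.counts) == 6
        assert cm.counts.sum() == 6

    def test_hand_counted(self):
        cm = confusion_matrix([1, 1, 2, 2], [1, 2, 2, 2], n_states=2)
        assert np.array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_row_sums_are_true_label_counts(self, rng):
        truth = rng.integers(1, 5, 200)
        pred = rng.integers(1, 5, 200)
        cm = confusion_matrix(truth, pred)
        assert np.array_equal(cm.counts.sum(axis=1), np.bincount(truth, minlength=5)[1:])

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [])
        with pytest.raises(ValueError):
            confusion_matrix([1, 2], [1])
        with pytest.raises(ValueError):
            confusion_matrix([1, 5], [1, 2])


class TestClassificationMetrics:
    def test_balanced_toy_case(self):
        cm = ConfusionMatrix([[9, 1], [1, 9]])
        m = classification_metrics(cm, 1)
        assert (m.tp, m.fn, m.fp, m.tn) == (9, 1, 1, 9)
        assert m.accuracy == pytest.approx(0.9)
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(0.9)
        assert m.f1 == pytest.approx(0.9)
        assert m.tpr == pytest.approx(0.9)
        assert m.fpr == pytest.approx(0.1)

    def test_perfect_prediction(self):
        cm = confusion_matrix([1, 2, 3, 4], [1, 2, 3, 4])
        for s in (1, 2, 3, 4):
            m = classification_metrics(cm, s)
            assert m.accuracy == m.precision == m.recall == m.f1 == 1.0
            assert m.fpr == 0.0

    def test_no_positive_predictions_undefined_precision(self):
        cm = confusion_matrix([1, 1, 2], [2, 2, 2], n_states=2)
        m = classification_metrics(cm, 1)
        assert math.isnan(m.precision)
        assert m.recall == 0.0

    def test_micro_accuracy_is_trace_over_total(self, rng):
        truth = rng.integers(1, 5, 300)
        pred = rng.integers(1, 5, 300)
        cm = confusion_matrix(truth, pred)
        macro = macro_metrics(cm)
        assert macro["micro_accuracy"] == pytest.approx(np.mean(truth == pred))


class TestRoc:
    def test_perfect_separation_auc_one(self):
        truth = [2, 2, 1, 1]
        _, auc = roc_curve([0.9, 0.8, 0.2, 0.1], truth, positive_state=2)
        assert auc == pytest.approx(1.0)

    def test_uninformative_scores_auc_half(self):
        truth = [2, 2, 1, 1]
        _, auc = roc_curve([0.5] * 4, truth, positive_state=2)
        assert auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_probability(self, rng):
        truth = rng.integers(1, 3, 40)
        scores = rng.random(40)
        pts, auc = roc_curve(scores, truth, positive_state=2)
        pos = scores[truth == 2]
        neg = scores[truth != 2]
        pairs = [(1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg]
        assert auc == pytest.approx(np.mean(pairs), abs=1e-12)
        fprs = [p[0] for p in pts]
        assert fprs == sorted(fprs)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.9], [2, 2], positive_state=2)


def window_path(cycle_counts, n_cycles=1):
    """Window-state path of complete cycles, e.g. counts (3, 8, 2, 7)."""
    one = sum(([s] * c for s, c in zip((1, 2, 3, 4), cycle_counts)), [])
    return np.array(one * n_cycles + [1])  # closing S1 entry completes the last cycle


class TestGaitParameters:
    spec = WindowSpec(10, 5)  # stride 5 samples = 0.05 s at 100 Hz

    def test_constructed_cycle_times(self):
        path = window_path((3, 8, 2, 7), n_cycles=4)
        gp = gait_parameters(path, self.spec, rate_hz=100.0)
        assert gp.n_cycles == 4
        assert gp.cycle_time_s[0] == pytest.approx(20 * 0.05)
        assert gp.swing_time_s[0] == pytest.approx(8 * 0.05)
        assert gp.stance_time_s[0] == pytest.approx(12 * 0.05)
        assert gp.cycle_time_s[1] == 0.0  # identical cycles: sd 0

    def test_swing_plus_stance_equals_cycle(self):
        gp = gait_parameters(window_path((2, 5, 1, 4), 3), self.spec)
        assert gp.swing_time_s[0] + gp.stance_time_s[0] == pytest.approx(gp.cycle_time_s[0])

    def test_no_complete_cycle_raises(self):
        with pytest.raises(ValueError, match="no complete"):
            gait_parameters(np.full(20, 2), self.spec)

    def test_phase_fraction_percent(self):
        path = window_path((3, 8, 2, 7), n_cycles=2)
        assert phase_fraction_percent(path, 2) == pytest.approx(40.0)
        assert phase_fraction_percent(path, 3) == pytest.approx(10.0)


class TestSwingRatioError:
    def test_identical_paths_zero_error(self):
        path = window_path((3, 8, 2, 7), 3)
        errors, mean, mx = swing_ratio_error(path, path)
        assert errors == [0.0, 0.0, 0.0]
        assert mean == 0.0 and mx == 0.0

    def test_one_window_boundary_shift(self):
        truth = window_path((3, 8, 2, 7), 2)
        decoded = truth.copy()
        # delay one swing onset by one window in the first cycle
        first_swing = np.flatnonzero(truth == 2)[0]
        decoded[first_swing] = 1
        errors, mean, mx = swing_ratio_error(truth, decoded)
        assert errors[0] == pytest.approx(100.0 / 20)  # one window of a 20-window cycle
        assert errors[1] == 0.0
        assert mx == pytest.approx(5.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            swing_ratio_error([1, 2], [1, 2, 3])


class TestLeftRight:
    def test_identical_sides_unit_ratios(self):
        gp = gait_parameters(window_path((3, 8, 2, 7), 3), WindowSpec(10, 5))
        ratios = left_right_ratio(gp, gp)
        assert ratios == {"swing": 1.0, "stance": 1.0, "cycle": 1.0}

    def test_hand_divided_ratio(self):
        l = gait_parameters(window_path((3, 8, 2, 7), 2), WindowSpec(10, 5))
        r = gait_parameters(window_path((3, 7, 2, 8), 2), WindowSpec(10, 5))
        ratios = left_right_ratio(l, r)
        assert ratios["swing"] == pytest.approx((8 * 0.05) / (7 * 0.05))
        assert ratios["cycle"] == pytest.approx(1.0)


class TestMatchStates:
    def test_recovers_permutation(self, rng):
        truth = rng.integers(1, 5, 400)
        perm = np.array([3, 1, 4, 2])
        pred = perm[truth - 1]
        mapping = match_states(truth, pred)
        assert np.array_equal(mapping[pred - 1], truth)

    def test_noisy_majority_still_matches(self, rng):
        truth = rng.integers(1, 5, 500)
        pred = truth.copy()
        flip = rng.random(500) < 0.2
        pred[flip] = rng.integers(1, 5, flip.sum())
        mapping = match_states(truth, pred)
        assert np.array_equal(mapping, [1, 2, 3, 4])
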