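"""Recognition metrics and spatiotemporal gait-balance parameters.

Window-level phase recognition is scored with a confusion matrix, one-vs-
rest accuracy/precision/recall/F1/TPR/FPR, and ROC curves built from the
per-window state posteriors.  Decoded state paths are also summarised as
clinically interpretable quantities: swing time, stance time, cycle
duration (mean ± sd per cycle) and left/right symmetry ratios, plus the
per-cycle error of the decoded swing fraction against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as _skm

from .features import WindowSpec

__all__ = [
    "ConfusionMatrix",
    "StateMetrics",
    "GaitParameters",
    "confusion_matrix",
    "classification_metrics",
    "macro_metrics",
    "roc_curve",
    "gait_parameters",
    "phase_fraction_percent",
    "swing_ratio_error",
    "left_right_ratio",
    "match_states",
]

UNDEFINED = float("nan")  # sentinel for zero-division metrics


@dataclass
class ConfusionMatrix:
    """counts[i, j] = number of windows with true state i+1 predicted j+1."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / float(self.counts.sum())


def confusion_matrix(
    truth: Sequence[int], pred: Sequence[int], n_states: int = 4
) -> ConfusionMatrix:
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if len(truth) == 0:
        raise ValueError("empty label sequences")
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lengths differ")
    for arr, name in ((truth, "truth"), (pred, "prediction")):
        if arr.min() < 1 or arr.max() > n_states:
            raise ValueError(f"{name} labels outside 1..{n_states}")
    counts = _skm.confusion_matrix(truth, pred, labels=list(range(1, n_states + 1)))
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class StateMetrics:
    """One-vs-rest metrics for a single positive state.

    Undefined ratios (zero denominators) are reported as NaN sentinels.
    """

    positive_state: int
    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    tpr: float
    fpr: float


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def classification_metrics(cm: ConfusionMatrix, positive_state: int) -> StateMetrics:
    """Reduce the confusion matrix one-vs-rest and evaluate the standard ratios."""
    i = positive_state - 1
    c = cm.counts
    tp = int(c[i, i])
    fn = int(c[i].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    recall = _safe_div(tp, tp + fn)
    return StateMetrics(
        positive_state=positive_state,
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        accuracy=_safe_div(tp + tn, tp + fp + tn + fn),
        precision=_safe_div(tp, tp + fp),
        recall=recall,
        f1=_safe_div(2 * tp, 2 * tp + fp + fn),
        tpr=recall,
        fpr=_safe_div(fp, fp + tn),
    )


def macro_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Unweighted means of the per-state metrics (NaN-aware)."""
    per_state = [classification_metrics(cm, s + 1) for s in range(cm.n_states)]
    out = {}
    for name in ("accuracy", "precision", "recall", "f1", "tpr", "fpr"):
        out[name] = float(np.nanmean([getattr(m, name) for m in per_state]))
    out["micro_accuracy"] = cm.accuracy
    return out


def roc_curve(
    scores: Sequence[float], truth: Sequence[int], positive_state: int = 2
) -> tuple[list[tuple[float, float]], float]:
    """ROC staircase and trapezoidal AUC for one state's posterior score.

    ``scores`` is the per-window posterior probability of the positive
    state; truth labels are binarised against ``positive_state``.
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(truth, dtype=int) == positive_state).astype(int)
    if y.min() == y.max():
        raise ValueError("ROC needs at least one positive and one negative window")
    fpr, tpr, _ = _skm.roc_curve(y, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_skm.auc(fpr, tpr))


@dataclass(frozen=True)
class GaitParameters:
    """Per-cycle swing/stance/cycle durations, mean ± sd over cycles."""

    swing_time_s: tuple[float, float]
    stance_time_s: tuple[float, float]
    cycle_time_s: tuple[float, float]
    n_cycles: int


def _cycle_slices(path: np.ndarray) -> list[slice]:
    """Maximal runs from one entry into S1 to the next; partial ends dropped."""
    entries = np.flatnonzero((path == 1) & (np.r_[0, path[:-1]] != 1))
    return [slice(a, b) for a, b in zip(entries[:-1], entries[1:])]


def gait_parameters(
    path: Sequence[int], window_spec: WindowSpec, rate_hz: float = 100.0
) -> GaitParameters:
    """Swing/stance/cycle times from a decoded window-state sequence.

    Each window advances time by one stride; a cycle runs from an entry
    into S1 to the next entry into S1, swing time is the time spent in S2
    within the cycle and stance is the remainder.
    """
    path = np.asarray(path, dtype=int)
    cycles = _cycle_slices(path)
    if not cycles:
        raise ValueError("no complete gait cycle (S1...S1) in the decoded path")
    dt = window_spec.stride / rate_hz
    cycle_t = np.array([(c.stop - c.start) * dt for c in cycles])
    swing_t = np.array([np.sum(path[c] == 2) * dt for c in cycles])
    stance_t = cycle_t - swing_t
    return GaitParameters(
        swing_time_s=(float(swing_t.mean()), float(swing_t.std())),
        stance_time_s=(float(stance_t.mean()), float(stance_t.std())),
        cycle_time_s=(float(cycle_t.mean()), float(cycle_t.std())),
        n_cycles=len(cycles),
    )


def phase_fraction_percent(path: Sequence[int], state: int) -> float:
    """Mean per-cycle percentage of cycle time spent in ``state``."""
    path = np.asarray(path, dtype=int)
    cycles = _cycle_slices(path)
    if not cycles:
        raise ValueError("no complete gait cycle (S1...S1) in the decoded path")
    fracs = [100.0 * np.mean(path[c] == state) for c in cycles]
    return float(np.mean(fracs))


def swing_ratio_error(
    truth_labels: Sequence[int],
    decoded_path: Sequence[int],
    window_spec: WindowSpec | None = None,
) -> tuple[list[float], float, float]:
    """Per-cycle |decoded − true| swing fraction, in percent of the cycle.

    Cycles are delimited on the ground-truth labels (entries into S1); the
    decoded fraction is measured over the same window range, so the error
    isolates boundary misplacement rather than cycle-counting differences.
    Returns (per-cycle errors, mean, max).
    """
    truth = np.asarray(truth_labels, dtype=int)
    decoded = np.asarray(decoded_path, dtype=int)
    if len(truth) != len(decoded):
        raise ValueError("truth and decoded paths must align")
    cycles = _cycle_slices(truth)
    if not cycles:
        raise ValueError("no complete gait cycle in the ground-truth labels")
    errors = [
        100.0 * abs(float(np.mean(decoded[c] == 2)) - float(np.mean(truth[c] == 2)))
        for c in cycles
    ]
    return errors, float(np.mean(errors)), float(np.max(errors))


def left_right_ratio(left: GaitParameters, right: GaitParameters) -> dict[str, float]:
    """Left/right symmetry ratios of mean swing, stance and cycle times."""
    out = {}
    for name in ("swing_time_s", "stance_time_s", "cycle_time_s"):
        l = getattr(left, name)[0]
        r = getattr(right, name)[0]
        if r == 0:
            raise ZeroDivisionError(f"right {name} is zero")
        out[name.replace("_time_s", "")] = l / r
    return out


def match_states(
    truth: Sequence[int], pred: Sequence[int], n_states: int = 4
) -> np.ndarray:
    """Permutation mapping predicted states onto truth states.

    Unsupervised decoders number their states arbitrarily; the Hungarian
    assignment that maximises label agreement resolves the permutation.
    ``mapping[k]`` is the truth state (1-based) for predicted state k+1;
    apply as ``mapping[pred - 1]``.
    """
    cm = confusion_matrix(truth, pred, n_states).counts
    rows, cols = linear_sum_assignment(-cm)
    mapping = np.empty(n_states, dtype=int)
    mapping[cols] = rows + 1
    return mapping
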