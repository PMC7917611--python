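"""Sliding-window segmentation and time-domain feature extraction.

Gait phases are recognised per window rather than per sample: the signal
is cut into fixed-size windows overlapping by half a window (default), and
each window is summarised by a vector of time-domain statistics.  The
canonical set has 15 features; any subset can be selected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .preprocess import GaitSignal

__all__ = [
    "WindowSpec",
    "FeatureDataset",
    "FeatureScaler",
    "CANONICAL_FEATURES",
    "segment_windows",
    "extract_features",
    "build_feature_dataset",
]


@dataclass(frozen=True)
class WindowSpec:
    """Window size and overlap in samples; default overlap is half a window."""

    size: int
    overlap: int | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("window size must be positive")
        if self.overlap is None:
            object.__setattr__(self, "overlap", self.size // 2)
        if not 0 <= self.overlap < self.size:
            raise ValueError("overlap must satisfy 0 <= overlap < size")

    @property
    def stride(self) -> int:
        return self.size - self.overlap


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    mu = float(np.mean(x))
    d = x - mu
    m2 = float(np.mean(d**2))
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return mu, m2, m3, m4


def _skewness(x: np.ndarray) -> float:
    _, m2, m3, _ = _moments(x)
    return 0.0 if m2 == 0.0 else m3 / m2**1.5


def _kurtosis(x: np.ndarray) -> float:
    # Population, non-excess: Gaussian -> 3.
    _, m2, _, m4 = _moments(x)
    return 0.0 if m2 == 0.0 else m4 / m2**2


def _waveform_factor(x: np.ndarray) -> float:
    am = float(np.mean(np.abs(x)))
    return 0.0 if am == 0.0 else float(np.sqrt(np.mean(x**2))) / am


def _crest_factor(x: np.ndarray) -> float:
    rms = float(np.sqrt(np.mean(x**2)))
    return 0.0 if rms == 0.0 else float(np.max(np.abs(x))) / rms


def _zero_crossing_rate(x: np.ndarray) -> float:
    return float(np.sum(x[1:] * x[:-1] < 0)) / (len(x) - 1)


CANONICAL_FEATURES: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda x: float(np.mean(x)),
    "variance": lambda x: float(np.var(x)),
    "std": lambda x: float(np.std(x)),
    "rms": lambda x: float(np.sqrt(np.mean(x**2))),
    "abs_mean": lambda x: float(np.mean(np.abs(x))),
    "min": lambda x: float(np.min(x)),
    "max": lambda x: float(np.max(x)),
    "range": lambda x: float(np.ptp(x)),
    "median": lambda x: float(np.median(x)),
    "mean_gradient": lambda x: float(np.mean(np.diff(x))),
    "waveform_factor": _waveform_factor,
    "crest_factor": _crest_factor,
    "skewness": _skewness,
    "kurtosis": _kurtosis,
    "zero_crossing_rate": _zero_crossing_rate,
}


@dataclass
class FeatureDataset:
    """Per-window feature vectors with window geometry and optional labels."""

    matrix: np.ndarray  # (T, D)
    feature_names: list[str]
    window_spec: WindowSpec
    window_labels: np.ndarray | None = None
    window_starts: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix must be (n_windows, n_features)")

    def __len__(self) -> int:
        return len(self.matrix)


@dataclass
class FeatureScaler:
    """Per-feature z-scoring fitted on training data.

    Standardisation keeps the EM recursions well-conditioned when feature
    magnitudes differ by orders of magnitude (raw angular velocities reach
    hundreds of deg/s while e.g. zero-crossing rates live in [0, 1]).
    """

    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, dtype=float)
        self.mean_ = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0.0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(x, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.scale_ + self.mean_

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(mean_=np.asarray(d["mean"]), scale_=np.asarray(d["scale"]))


def segment_windows(signal: GaitSignal, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open index ranges [s, s+size) at stride size − overlap.

    Trailing samples that do not fill a whole window are dropped.
    """
    n = len(signal)
    if n < spec.size:
        raise ValueError(f"signal of length {n} shorter than one window ({spec.size})")
    starts = range(0, n - spec.size + 1, spec.stride)
    return [(s, s + spec.size) for s in starts]


def extract_features(window: Sequence[float], names: Sequence[str]) -> np.ndarray:
    """Evaluate the named time-domain features on one window of samples."""
    x = np.asarray(window, dtype=float)
    if len(x) < 2:
        raise ValueError("window must contain at least 2 samples")
    out = np.empty(len(names))
    for i, name in enumerate(names):
        try:
            out[i] = CANONICAL_FEATURES[name](x)
        except KeyError:
            raise ValueError(
                f"unknown feature {name!r}; known: {sorted(CANONICAL_FEATURES)}"
            ) from None
    return out


def _majority_label(labels: np.ndarray) -> int:
    # Ties resolve to the earlier phase in cycle order (lower index).
    counts = np.bincount(labels, minlength=5)[1:]
    return int(np.argmax(counts)) + 1


def build_feature_dataset(
    signal: GaitSignal,
    spec: WindowSpec,
    names: Sequence[str] | None = None,
) -> FeatureDataset:
    """Window the signal and extract features; label windows by majority vote.

    A 3-axis signal must be reduced to one axis first
    (:func:`gaitphase.preprocess.select_axis`).
    """
    if signal.n_axes != 1:
        raise ValueError("feature extraction expects a single-axis signal")
    if names is None:
        names = list(CANONICAL_FEATURES)
    windows = segment_windows(signal, spec)
    matrix = np.stack(
        [extract_features(signal.samples[a:b], names) for a, b in windows]
    )
    starts = np.array([a for a, _ in windows], dtype=int)
    labels = None
    if signal.labels is not None:
        labels = np.array(
            [_majority_label(signal.labels[a:b]) for a, b in windows], dtype=int
        )
    return FeatureDataset(
        matrix=matrix,
        feature_names=list(names),
        window_spec=spec,
        window_labels=labels,
        window_starts=starts,
    )
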