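"""Reading, writing and smoothing of angular-velocity gait signals.

A toe-mounted gyroscope sampled at 100 Hz produces a quasi-periodic
angular-velocity trace; before windowing and feature extraction the raw
trace is smoothed.  Three smoothers are provided — moving average, median
and five-point cubic (a degree-3 Savitzky-Golay-type kernel) — together
with an information-based selection rule that ranks candidates by the
signal-to-noise ratio of the filtered signal against the filtering
residual, breaking ties by RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GaitSignal",
    "FilterReport",
    "FilterSpec",
    "read_gait_csv",
    "write_gait_csv",
    "select_axis",
    "moving_average",
    "median_filter",
    "five_point_cubic",
    "select_filter",
]

PHASE_LABELS = (1, 2, 3, 4)

# Kernel reproduces cubic polynomials exactly on interior points.
_FIVE_POINT_CUBIC_KERNEL = np.array([-3.0, 12.0, 17.0, 12.0, -3.0]) / 35.0


@dataclass
class GaitSignal:
    """Angular-velocity samples (deg/s), one axis or three.

    ``samples`` has shape ``(T,)`` for a single axis or ``(T, 3)`` for a
    full gyroscope.  ``labels``, when present, gives the ground-truth gait
    phase of every sample as an integer in {1..4}:
    1 = heel-off to toe-off, 2 = swing, 3 = heel-strike to foot-flat,
    4 = foot-flat to heel-off.
    """

    samples: np.ndarray
    rate_hz: float = 100.0
    labels: np.ndarray | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D or 2-D (T, 3)")
        if self.samples.ndim == 2 and self.samples.shape[1] != 3:
            raise ValueError("multi-axis signals must have exactly 3 columns")
        if len(self.samples) < 1:
            raise ValueError("signal must contain at least one sample")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.samples):
                raise ValueError("labels must match samples in length")
            bad = ~np.isin(self.labels, PHASE_LABELS)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"label {self.labels[row]} at row {row} outside {{1..4}}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_axes(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate_hz


@dataclass(frozen=True)
class FilterReport:
    """SNR/RMSE of one smoothing candidate against the raw signal."""

    method_name: str
    snr_db: float
    rmse: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


@dataclass(frozen=True)
class FilterSpec:
    """A smoothing method plus its window; ``kind`` is ma | median | 5p3."""

    kind: str
    window: int = 15

    def __post_init__(self) -> None:
        if self.kind not in ("ma", "median", "5p3"):
            raise ValueError(f"unknown filter kind {self.kind!r}")

    @property
    def name(self) -> str:
        return self.kind if self.kind == "5p3" else f"{self.kind}({self.window})"

    def apply(self, signal: GaitSignal) -> GaitSignal:
        if self.kind == "ma":
            return moving_average(signal, self.window)
        if self.kind == "median":
            return median_filter(signal, self.window)
        return five_point_cubic(signal)


def read_gait_csv(path: str | Path, axis: str = "all") -> GaitSignal:
    """Read a gait signal from CSV with columns ``t,gx,gy,gz[,phase]``.

    ``axis`` selects a single gyroscope column by name, ``"all"`` keeps
    every ``g*`` column, and ``"auto"`` picks the axis with the largest
    variance (a proxy for the sagittal plane, which dominates in walking).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    gyro_cols = [c for c in df.columns if c.startswith("g")]
    if not gyro_cols:
        raise ValueError(f"{path}: no gyroscope columns (gx/gy/gz) found")
    for col in gyro_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col].apply(lambda v: not isinstance(v, (int, float))).idxmax()
            raise ValueError(f"{path}: non-numeric value in column {col!r} row {bad}")
    if axis == "all":
        data = df[gyro_cols].to_numpy(dtype=float)
        if data.shape[1] == 1:
            data = data[:, 0]
    elif axis == "auto":
        variances = df[gyro_cols].var()
        data = df[variances.idxmax()].to_numpy(dtype=float)
    else:
        if axis not in df.columns:
            raise ValueError(f"{path}: no column {axis!r}")
        data = df[axis].to_numpy(dtype=float)
    labels = None
    if "phase" in df.columns:
        labels = df["phase"].to_numpy()
    rate = 100.0
    if "t" in df.columns and len(df) > 1:
        dt = float(np.median(np.diff(df["t"].to_numpy(dtype=float))))
        if dt > 0:
            rate = 1.0 / dt
    return GaitSignal(samples=data, rate_hz=rate, labels=labels)


def write_gait_csv(signal: GaitSignal, path: str | Path) -> None:
    """Write a signal as ``t,gx[,gy,gz][,phase]`` CSV."""
    data = {"t": signal.times}
    if signal.n_axes == 1:
        data["gx"] = signal.samples
    else:
        for i, name in enumerate(("gx", "gy", "gz")):
            data[name] = signal.samples[:, i]
    if signal.labels is not None:
        data["phase"] = signal.labels
    pd.DataFrame(data).to_csv(Path(path), index=False)


def select_axis(signal: GaitSignal, axis: int | str = "auto") -> GaitSignal:
    """Reduce a 3-axis signal to the single axis used for segmentation.

    With ``axis="auto"`` the largest-variance axis is chosen; walking
    concentrates rotation in the sagittal plane, so that axis carries the
    gait cycle.
    """
    if signal.n_axes == 1:
        return signal
    if axis == "auto":
        axis = int(np.argmax(signal.samples.var(axis=0)))
    return replace(signal, samples=signal.samples[:, int(axis)])


def _check_window(window: int) -> None:
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")


def _per_axis(signal: GaitSignal, fn) -> GaitSignal:
    x = signal.samples
    if x.ndim == 1:
        out = fn(x)
    else:
        out = np.column_stack([fn(x[:, i]) for i in range(x.shape[1])])
    return replace(signal, samples=out)


def moving_average(signal: GaitSignal, window: int) -> GaitSignal:
    """Centered moving mean with symmetric edge padding; length preserved."""
    _check_window(window)

    def _ma(x: np.ndarray) -> np.ndarray:
        if window == 1:
            return x.copy()
        pad = window // 2
        padded = np.pad(x, pad, mode="symmetric")
        return np.convolve(padded, np.ones(window) / window, mode="valid")

    return _per_axis(signal, _ma)


def median_filter(signal: GaitSignal, window: int) -> GaitSignal:
    """Centered moving median with symmetric edge padding."""
    _check_window(window)

    def _med(x: np.ndarray) -> np.ndarray:
        if window == 1:
            return x.copy()
        return ndimage.median_filter(x, size=window, mode="reflect")

    return _per_axis(signal, _med)


def five_point_cubic(signal: GaitSignal) -> GaitSignal:
    """Five-point cubic smoother (−3, 12, 17, 12, −3)/35.

    Reproduces polynomials up to degree 3 exactly on interior points;
    edges use symmetric padding.  Requires at least 5 samples.
    """
    if len(signal) < 5:
        raise ValueError("five_point_cubic requires at least 5 samples")

    def _fpc(x: np.ndarray) -> np.ndarray:
        padded = np.pad(x, 2, mode="symmetric")
        return np.convolve(padded, _FIVE_POINT_CUBIC_KERNEL[::-1], mode="valid")

    return _per_axis(signal, _fpc)


def snr_db(raw: np.ndarray, filtered: np.ndarray) -> float:
    """SNR of filtered signal vs residual: 10·log10(Σy² / Σ(x−y)²)."""
    noise = float(np.sum((raw - filtered) ** 2))
    power = float(np.sum(filtered**2))
    if noise == 0.0:
        return math.inf
    return 10.0 * math.log10(power / noise)


def rmse(raw: np.ndarray, filtered: np.ndarray) -> float:
    return float(np.sqrt(np.mean((raw - filtered) ** 2)))


def select_filter(
    raw: GaitSignal, candidates: Sequence[FilterSpec]
) -> tuple[FilterSpec, list[FilterReport]]:
    """Rank smoothing candidates by SNR (residual definition), pick the best.

    Returns the winning spec and one :class:`FilterReport` per candidate in
    input order.  Ties in SNR fall back to lower RMSE, then to input order.
    An identity filter yields zero residual and is reported with +inf SNR.
    """
    if not candidates:
        raise ValueError("need at least one filter candidate")
    reports = []
    for spec in candidates:
        y = spec.apply(raw).samples.ravel()
        x = raw.samples.ravel()
        reports.append(FilterReport(spec.name, snr_db(x, y), rmse(x, y)))
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-reports[i].snr_db, reports[i].rmse, i),
    )
    return candidates[order[0]], reports
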