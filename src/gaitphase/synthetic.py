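"""Synthetic quasi-periodic gait signals with ground-truth phase labels.

Normal walking cycles through four phases; measured from a toe-mounted
gyroscope each phase shows a characteristic angular-velocity level, and the
phases occupy roughly fixed fractions of the cycle:

=====  ==========================  ==================
state  phase                       fraction of cycle
=====  ==========================  ==================
S1     heel-off to toe-off         ~15 %
S2     swing (toe-off to strike)   ~40 %
S3     heel-strike to foot-flat    ~10 %
S4     foot-flat to heel-off       ~35 %
=====  ==========================  ==================

The generator emulates exactly this structure: per cycle a duration is
drawn (lognormal, configurable coefficient of variation), split into the
four phases by their fractions, and each phase emits its level times a
template (constant or half-sine bump) plus white Gaussian sensor noise.
Every sample carries the generating phase as its label, so recognition can
be scored without any real recordings.  Cohorts of synthetic "subjects"
perturb the levels and cadence per subject, emulating inter-individual
variation for adaptation experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .preprocess import GaitSignal

__all__ = [
    "GaitSimConfig",
    "CohortVariation",
    "generate_gait_signal",
    "generate_cohort",
]

_TEMPLATES = ("constant", "half_sine")


@dataclass(frozen=True)
class GaitSimConfig:
    """Parameters of the synthetic gait generator.

    Defaults describe an unremarkable adult walker: 1.56 s cycles at
    100 Hz with 5 % cadence jitter, phase fractions 15/40/10/35 % in the
    S1..S4 order above, and phase angular-velocity levels separated by at
    least four noise standard deviations so segmentation is solvable but
    not trivial.  ``subject_shift`` applies ``scale * level + offset`` to
    all phase levels before synthesis (used for multi-subject cohorts).
    """

    rate_hz: float = 100.0
    cycle_s: float = 1.56
    phase_fractions: tuple[float, float, float, float] = (0.15, 0.40, 0.10, 0.35)
    phase_levels: tuple[float, float, float, float] = (-150.0, 250.0, -100.0, 0.0)
    phase_shapes: tuple[str, str, str, str] = ("constant",) * 4
    noise_sd: float = 25.0
    cycle_jitter_cv: float = 0.05
    n_cycles: int = 30
    subject_shift: tuple[float, float] = (0.0, 1.0)  # (offset, scale)
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.phase_fractions, dtype=float)
        if len(fr) != 4 or np.any(fr <= 0):
            raise ValueError("phase_fractions must be 4 positive numbers")
        if abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError("phase_fractions must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")
        for shape in self.phase_shapes:
            if shape not in _TEMPLATES:
                raise ValueError(f"unknown phase shape {shape!r}")

    @property
    def shifted_levels(self) -> np.ndarray:
        offset, scale = self.subject_shift
        return scale * np.asarray(self.phase_levels, dtype=float) + offset


def _phase_template(shape: str, n: int) -> np.ndarray:
    if shape == "constant":
        return np.ones(n)
    # half-sine bump peaking mid-phase, zero-ish at the boundaries
    return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def _cycle_durations(cfg: GaitSimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.cycle_jitter_cv == 0:
        return np.full(cfg.n_cycles, cfg.cycle_s)
    # lognormal parametrised so the arithmetic mean is cycle_s
    sigma2 = math.log(1.0 + cfg.cycle_jitter_cv**2)
    mu = math.log(cfg.cycle_s) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), cfg.n_cycles)


def generate_gait_signal(config: GaitSimConfig) -> GaitSignal:
    """Synthesize one labeled angular-velocity recording.

    Phase sample counts are the rounded fractions of each cycle's length,
    with the rounding residue assigned to the longest phase so counts add
    up exactly.  Raises if any phase would be shorter than one sample.
    """
    rng = np.random.default_rng(config.seed)
    levels = config.shifted_levels
    fractions = np.asarray(config.phase_fractions)
    longest = int(np.argmax(fractions))
    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for duration in _cycle_durations(config, rng):
        n_cycle = int(round(duration * config.rate_hz))
        counts = np.round(fractions * n_cycle).astype(int)
        counts[longest] += n_cycle - counts.sum()
        if np.any(counts < 1):
            raise ValueError(
                "a phase is shorter than one sample at this rate; increase "
                "cycle_s or rate_hz"
            )
        for k in range(4):
            tmpl = _phase_template(config.phase_shapes[k], counts[k])
            chunk = levels[k] * tmpl
            if config.noise_sd > 0:
                chunk = chunk + rng.normal(0.0, config.noise_sd, counts[k])
            chunks.append(chunk)
            labels.append(np.full(counts[k], k + 1, dtype=int))
    return GaitSignal(
        samples=np.concatenate(chunks),
        rate_hz=config.rate_hz,
        labels=np.concatenate(labels),
    )


@dataclass(frozen=True)
class CohortVariation:
    """Inter-subject variation: level offset/scale spread and cadence spread.

    Offsets are drawn N(0, level_offset_sd) in deg/s, scales
    N(1, level_scale_sd), and each subject's mean cycle duration
    N(cycle_s, cadence_sd seconds).
    """

    level_offset_sd: float = 0.0
    level_scale_sd: float = 0.0
    cadence_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.level_offset_sd, self.level_scale_sd, self.cadence_sd) < 0:
            raise ValueError("variation spreads must be non-negative")


def generate_cohort(
    n_subjects: int,
    base: GaitSimConfig,
    variation: CohortVariation = CohortVariation(),
    seed: int = 0,
) -> list[tuple[GaitSignal, GaitSimConfig]]:
    """Draw a cohort of synthetic subjects around a base configuration.

    Each subject gets an independent level offset/scale and cadence from
    the variation spec plus a distinct generator seed; returns the labeled
    signal together with the per-subject configuration actually used.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        offset = rng.normal(0.0, variation.level_offset_sd) if variation.level_offset_sd else 0.0
        scale = rng.normal(1.0, variation.level_scale_sd) if variation.level_scale_sd else 1.0
        cycle = base.cycle_s + (rng.normal(0.0, variation.cadence_sd) if variation.cadence_sd else 0.0)
        cfg = replace(
            base,
            subject_shift=(offset, scale),
            cycle_s=max(cycle, 0.2),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        signal = generate_gait_signal(cfg)
        signal.subject_id = f"subject_{i:02d}"
        out.append((signal, cfg))
    return out
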