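"""A published reference gait HMM used as ground truth in recovery benchmarks.

The model describes the windowed-mean feature of a toe gyroscope during
normal walking with four phase states on the circular left-to-right
topology: strong self-transitions, a forced start in the heel-off state,
and one univariate Gaussian per state.  Simulating from it and refitting
with Baum-Welch checks that the estimator recovers known parameters.
"""

from __future__ import annotations

import numpy as np

from .hmm import GaussianEmission, HmmModel, circular_left_right_topology

__all__ = [
    "REFERENCE_TRANSITIONS",
    "REFERENCE_START",
    "REFERENCE_MEANS",
    "REFERENCE_VARIANCES",
    "reference_gait_model",
]

REFERENCE_TRANSITIONS = np.array(
    [
        [0.8460, 0.1540, 0.0, 0.0],
        [0.0, 0.8253, 0.1747, 0.0],
        [0.0, 0.0, 0.7395, 0.2605],
        [0.1649, 0.0, 0.0, 0.8351],
    ]
)

REFERENCE_START = np.array([1.0, 0.0, 0.0, 0.0])

# Windowed-mean emission moments per state (standardised feature units).
REFERENCE_MEANS = np.array([-2.6518, 3.7528, -1.0578, -0.1528])
REFERENCE_VARIANCES = np.array([3.9164, 2.4664, 0.7880, 0.0146])


def reference_gait_model() -> HmmModel:
    """The reference four-state univariate-Gaussian gait HMM."""
    emission = GaussianEmission(
        means=REFERENCE_MEANS[:, None],
        covs=REFERENCE_VARIANCES[:, None, None],
    )
    return HmmModel(
        pi=REFERENCE_START.copy(),
        transitions=REFERENCE_TRANSITIONS.copy(),
        emission=emission,
        topology_mask=circular_left_right_topology(4, allow_wrap=True),
    )
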