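"""Reproducible benchmark experiments exercising the whole package.

Three seeded, self-contained experiments:

* :func:`reference_model_recovery` — simulate observation sequences from
  the published reference gait HMM, refit by Baum-Welch from a jittered
  initialisation, and report the recovered parameters after nearest-mean
  state alignment.
* :func:`swing_fraction_pipeline` — run the full synthetic pipeline
  (generate → featurize → train → Viterbi decode) and measure the
  per-cycle percentage of time decoded as each phase.
* :func:`adaptation_benefit` — train on a synthetic cohort, then decode
  held-out subjects whose angular-velocity levels are shifted by one noise
  standard deviation, with and without MLLR+MAP adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import match_states, phase_fraction_percent
from .features import WindowSpec
from .hmm import align_states_by_means, fit_baum_welch, jitter_model, simulate
from .pipeline import GaitPhaseModel, adapt_gait_model, train_gait_model
from .reference import reference_gait_model
from .synthetic import CohortVariation, GaitSimConfig, generate_cohort, generate_gait_signal

__all__ = [
    "reference_model_recovery",
    "swing_fraction_pipeline",
    "adaptation_benefit",
]


@dataclass(frozen=True)
class RecoveryResult:
    transitions: np.ndarray  # aligned fitted transition matrix
    means: np.ndarray  # aligned fitted state means (4,)
    variances: np.ndarray  # aligned fitted state variances (4,)
    loglik_trace: list[float]
    n_samples: int


def reference_model_recovery(
    seed: int = 7,
    n_sequences: int = 20,
    sequence_length: int = 400,
    max_iter: int = 200,
) -> RecoveryResult:
    """Simulate from the reference model, refit, align, report parameters.

    Initialisation is the true model perturbed by seeded jitter (means
    shifted by half a state SD, variances scaled lognormally, transition
    rows mixed halfway to uniform-on-mask), so the fit must genuinely
    re-estimate the parameters.  Fitted states are matched to the
    generating states by nearest emission mean.
    """
    truth = reference_gait_model()
    rng = np.random.default_rng(seed)
    sequences = [
        simulate(truth, sequence_length, seed=rng)[0] for _ in range(n_sequences)
    ]
    init = jitter_model(truth, seed=rng)
    fitted, trace = fit_baum_welch(init, sequences, tol=1e-7, max_iter=max_iter)
    perm = align_states_by_means(fitted, truth)
    A = fitted.transitions[np.ix_(perm, perm)]
    means = fitted.emission.means[perm, 0]
    variances = np.array([fitted.emission.covs[p][0, 0] for p in perm])
    return RecoveryResult(
        transitions=A,
        means=means,
        variances=variances,
        loglik_trace=trace,
        n_samples=n_sequences * sequence_length,
    )


@dataclass(frozen=True)
class PipelineResult:
    phase_percent: dict[int, float]  # state -> mean per-cycle % of the cycle
    accuracy: float  # window-level agreement with ground truth
    model: GaitPhaseModel
    n_windows: int


def swing_fraction_pipeline(
    seed: int = 11,
    n_cycles: int = 30,
    window: WindowSpec = WindowSpec(10, 5),
    feature_names=("mean", "variance", "rms"),
) -> PipelineResult:
    """Full pipeline on default synthetic gait: generate, train, decode.

    Training follows the annotated-data path (labeled-moment bootstrap plus
    capped Baum-Welch refinement).  Decoded states are identified with the
    generating phases by Hungarian matching against the ground-truth window
    labels — a safeguard against label switching — and each phase's mean
    per-cycle share of the cycle is measured from the decoded path.
    """
    config = GaitSimConfig(n_cycles=n_cycles, seed=seed)
    signal = generate_gait_signal(config)
    model, _ = train_gait_model(
        [signal], window=window, feature_names=feature_names, seed=seed
    )
    path, ds = model.decode(signal)
    mapping = match_states(ds.window_labels, path)
    aligned = mapping[path - 1]
    percents = {s: phase_fraction_percent(aligned, s) for s in (1, 2, 3, 4)}
    accuracy = float(np.mean(aligned == ds.window_labels))
    return PipelineResult(
        phase_percent=percents,
        accuracy=accuracy,
        model=model,
        n_windows=len(ds),
    )


@dataclass(frozen=True)
class AdaptationBenefitResult:
    unadapted_accuracy: list[float]
    adapted_accuracy: list[float]

    @property
    def wins(self) -> int:
        """Held-out subjects on which adaptation did not hurt."""
        return sum(
            a >= u
            for a, u in zip(self.adapted_accuracy, self.unadapted_accuracy)
        )


def adaptation_benefit(
    seed: int = 0,
    n_train_subjects: int = 6,
    n_test_subjects: int = 10,
    n_cycles: int = 30,
    tau: float = 10.0,
) -> AdaptationBenefitResult:
    """MLLR+MAP adaptation versus no adaptation on shifted held-out subjects.

    A pooled model is trained on a homogeneous cohort; each held-out
    subject's phase levels are shifted by one noise SD (random sign).  The
    first half of the subject's recording serves as unlabeled adaptation
    data; window accuracy is scored on the second half.
    """
    base = GaitSimConfig(n_cycles=n_cycles, seed=seed)
    rng = np.random.default_rng(seed)
    train = generate_cohort(
        n_train_subjects, base, CohortVariation(), seed=int(rng.integers(2**31 - 1))
    )
    model, _ = train_gait_model([sig for sig, _ in train], seed=seed)
    # anchor trained state numbering to the phase labels once, on training data
    path0, ds0 = model.decode(train[0][0])
    mapping = match_states(ds0.window_labels, path0)

    unadapted, adapted = [], []
    for _ in range(n_test_subjects):
        shift = float(base.noise_sd) * float(rng.choice([-1.0, 1.0]))
        cfg = replace(
            base, subject_shift=(shift, 1.0), seed=int(rng.integers(2**31 - 1))
        )
        signal = generate_gait_signal(cfg)
        x, ds = model.featurize(signal)
        half = len(x) // 2
        truth_eval = ds.window_labels[half:]

        path, _ds = model.decode(signal)
        unadapted.append(float(np.mean(mapping[path - 1][half:] == truth_eval)))

        sub_model = adapt_gait_model(
            model,
            [_half_signal(signal, half, model.window)],
            method="mllr+map",
            tau=tau,
        )
        path_a, _ = sub_model.decode(signal)
        adapted.append(float(np.mean(mapping[path_a - 1][half:] == truth_eval)))
    return AdaptationBenefitResult(unadapted, adapted)


def _half_signal(signal, n_windows: int, window: WindowSpec):
    """First samples covering the leading ``n_windows`` windows."""
    n_samples = (n_windows - 1) * window.stride + window.size
    from .preprocess import GaitSignal

    return GaitSignal(
        samples=signal.samples[:n_samples],
        rate_hz=signal.rate_hz,
        labels=None,
        subject_id=signal.subject_id,
    )
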