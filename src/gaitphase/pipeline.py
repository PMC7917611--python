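"""End-to-end gait-phase pipeline: featurize, train, decode, adapt.

Bundles the fitted HMM with everything needed to apply it to a raw
signal — the window geometry, the feature list and the z-scoring fitted on
the training windows — and serialises the bundle to a single JSON document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .adaptation import MapConfig, map_adapt, mllr_adapt, mllr_then_map
from .features import FeatureDataset, FeatureScaler, WindowSpec, build_feature_dataset
from .hmm import (
    HmmModel,
    estimate_cycle_length,
    fit_baum_welch,
    initial_model,
    supervised_initial_model,
    viterbi,
)
from .preprocess import GaitSignal, select_axis

__all__ = ["GaitPhaseModel", "train_gait_model", "adapt_gait_model"]

DEFAULT_FEATURES = ("mean", "variance", "rms")


@dataclass
class GaitPhaseModel:
    """A trained phase recogniser: HMM + feature recipe + scaler."""

    hmm: HmmModel
    scaler: FeatureScaler
    window: WindowSpec
    feature_names: list[str]

    def featurize(self, signal: GaitSignal) -> tuple[np.ndarray, FeatureDataset]:
        """Window a signal and return (standardised features, raw dataset)."""
        ds = build_feature_dataset(select_axis(signal), self.window, self.feature_names)
        return self.scaler.transform(ds.matrix), ds

    def decode(self, signal: GaitSignal) -> tuple[np.ndarray, FeatureDataset]:
        """Viterbi-decode a signal into a 1-based window phase sequence."""
        x, ds = self.featurize(signal)
        path, _ = viterbi(self.hmm, x)
        return path + 1, ds

    def to_dict(self) -> dict:
        return {
            "hmm": self.hmm.to_dict(),
            "scaler": self.scaler.to_dict(),
            "window": {"size": self.window.size, "overlap": self.window.overlap},
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaitPhaseModel":
        return cls(
            hmm=HmmModel.from_dict(d["hmm"]),
            scaler=FeatureScaler.from_dict(d["scaler"]),
            window=WindowSpec(d["window"]["size"], d["window"]["overlap"]),
            feature_names=list(d["feature_names"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GaitPhaseModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_gait_model(
    signals: Sequence[GaitSignal],
    window: WindowSpec = WindowSpec(10, 5),
    feature_names: Sequence[str] = DEFAULT_FEATURES,
    n_states: int = 4,
    emission: str = "gaussian",
    n_components: int = 1,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int | None = None,
    jitter: float = 1.0,
    use_labels: bool = True,
    label_refine_iters: int = 5,
    n_restarts: int = 4,
) -> tuple[GaitPhaseModel, list[float]]:
    """Featurize the training signals and fit a circular left-to-right HMM.

    When every training signal carries ground-truth phase labels (and
    ``use_labels`` is set) the model is bootstrapped from the labeled
    window moments and label transition counts, then refined by at most
    ``label_refine_iters`` Baum-Welch passes — the usual procedure for
    annotated training data, and the one that pins state numbers to phase
    numbers.  Refinement is capped because the unconstrained likelihood
    rewards re-purposing a state for phase-boundary windows, which slowly
    un-anchors the bootstrap.  Otherwise training is
    fully unsupervised: EM is restarted from ``n_restarts`` seeded
    initialisations (uniform-duration segmentation of each estimated gait
    cycle, plus mean jitter) and the restart with the best final
    log-likelihood wins; unsupervised state numbering is then arbitrary up
    to the cyclic order.  Returns the model bundle and the EM
    log-likelihood trace.
    """
    datasets = [
        build_feature_dataset(select_axis(s), window, feature_names) for s in signals
    ]
    scaler = FeatureScaler().fit(np.concatenate([d.matrix for d in datasets]))
    sequences = [scaler.transform(d.matrix) for d in datasets]

    if use_labels and all(d.window_labels is not None for d in datasets):
        init = supervised_initial_model(
            sequences,
            [d.window_labels for d in datasets],
            n_states=n_states,
            emission=emission,
            n_components=n_components,
        )
        hmm, trace = fit_baum_welch(
            init, sequences, tol=tol, max_iter=min(max_iter, label_refine_iters)
        )
    else:
        cycle_length = estimate_cycle_length(sequences[0])
        best: tuple[HmmModel, list[float]] | None = None
        for k, child in enumerate(np.random.SeedSequence(seed).spawn(max(n_restarts, 1))):
            init = initial_model(
                sequences,
                n_states=n_states,
                emission=emission,
                n_components=n_components,
                seed=int(child.generate_state(1)[0] % 2**31),
                jitter=0.0 if k == 0 else jitter,
                cycle_length=cycle_length,
            )
            fit = fit_baum_welch(init, sequences, tol=tol, max_iter=max_iter)
            if best is None or fit[1][-1] > best[1][-1]:
                best = fit
        hmm, trace = best
    model = GaitPhaseModel(
        hmm=hmm,
        scaler=scaler,
        window=window,
        feature_names=list(feature_names),
    )
    return model, trace


def adapt_gait_model(
    model: GaitPhaseModel,
    signals: Sequence[GaitSignal],
    method: str = "mllr+map",
    tau: float = 10.0,
    n_em_iters: int = 3,
) -> GaitPhaseModel:
    """Adapt a trained model to a new subject's unlabeled recordings.

    ``method`` is ``mllr``, ``map`` or ``mllr+map`` (MLLR output used as
    the MAP prior).  The feature recipe and scaler are reused unchanged so
    adapted and unadapted decodings stay directly comparable.
    """
    sequences = [model.featurize(s)[0] for s in signals]
    if method == "mllr":
        hmm, _ = mllr_adapt(model.hmm, sequences, n_em_iters=n_em_iters)
    elif method == "map":
        hmm = map_adapt(model.hmm, sequences, MapConfig(tau=tau))
    elif method == "mllr+map":
        hmm = mllr_then_map(
            model.hmm, sequences, MapConfig(tau=tau), n_em_iters=n_em_iters
        )
    else:
        raise ValueError(f"unknown adaptation method {method!r}")
    return GaitPhaseModel(
        hmm=hmm,
        scaler=model.scaler,
        window=model.window,
        feature_names=list(model.feature_names),
    )
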