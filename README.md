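# gaitphase

Gait-phase segmentation of wearable gyroscope recordings with circular
left-to-right hidden Markov models.

Clinical gait analysis scores how a person walks by splitting every gait
cycle into phases and timing them: abnormal phase durations and left/right
asymmetry are indicators used in the assessment of neurological and
orthopedic conditions.  This package segments the cycle into the four
sub-phases of walking — **S1** heel-off→toe-off, **S2** swing, **S3**
heel-strike→foot-flat, **S4** foot-flat→heel-off — from a single
toe-mounted gyroscope sampled at 100 Hz, and derives swing/stance/cycle
times and symmetry ratios from the result.  In normal gait the four phases
occupy roughly 15/40/10/35 % of the cycle.

## Method

The angular-velocity trace is smoothed (moving-average, median or
five-point cubic filter, chosen by signal-to-noise ratio against the
filtering residual), cut into sliding windows overlapping by half a
window, and summarised per window by time-domain features (15 canonical
features; mean, variance and RMS by default).  Phases are the hidden
states of an HMM θ = (π, A, B) with a *circular left-to-right* topology:
a phase may persist (aᵢᵢ) or advance to the next phase (aᵢ,ᵢ₊₁), and the
last phase wraps to the first, matching the cyclic order of walking;
recordings start at heel-off, so π = (1, 0, 0, 0).  Emissions B per state
are categorical, Gaussian, or diagonal Gaussian mixtures.  Parameters are
estimated by Baum–Welch (EM with scaled forward–backward recursions;
posteriors γ, ξ and, for mixtures, η), and phase sequences are decoded
with the Viterbi algorithm.

Two adaptation schemes transfer a trained model to a new walker from a
small amount of *unlabeled* data, changing only emission means and
variances: **MLLR** (one global affine transform μ′ = W[1; μ] plus a
diagonal variance scaling, estimated from occupancy-weighted normal
equations) and **MAP** (per-state shrinkage of occupancy-weighted sample
statistics toward the prior with strength τ), optionally chained with the
MLLR output serving as the MAP prior.

A synthetic-gait generator produces labeled quasi-periodic signals
(per-phase angular-velocity levels, cadence jitter, sensor noise,
inter-subject level shifts), so every stage is testable without real
recordings.

## Worked example

```python
from gaitphase import (GaitSimConfig, generate_gait_signal,
                       train_gait_model, confusion_matrix,
                       phase_fraction_percent)

signal = generate_gait_signal(GaitSimConfig(n_cycles=30, seed=11))
model, trace = train_gait_model([signal], seed=11)
path, dataset = model.decode(signal)
print(confusion_matrix(dataset.window_labels, path).accuracy)
for s in (1, 2, 3, 4):
    print(s, round(phase_fraction_percent(path, s), 1))
```

prints

```
0.9633
1 17.5
2 39.7
3 11.8
4 30.9
```

96.3 % of windows receive the correct phase, and the decoded shares of the
cycle (17.5/39.7/11.8/30.9 %) sit close to the generator's 15/40/10/35 %
profile — the ~40 % swing share is the headline normality indicator.  The
scripts in `examples/` walk through the other capabilities: filter
selection, parameter recovery, subject adaptation (window accuracy on a
shifted subject rises from 0.791 to 0.914 with MLLR+MAP) and the
spatiotemporal balance report.  A thin CLI mirrors the pipeline
(`gaitphase simulate | preprocess | featurize | train | decode | adapt |
evaluate`).

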