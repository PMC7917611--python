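# Methods

## Model

Walking is modelled as a first-order hidden Markov chain over four phase
states in fixed cyclic order: S1 heel-off→toe-off, S2 swing (toe-off to
heel-strike), S3 heel-strike→foot-flat, S4 foot-flat→heel-off.  The
topology is circular left-to-right — transitions are restricted to self
(aᵢᵢ) and next-phase (aᵢ,ᵢ₊₁), with S4 wrapping to S1 so a single chain
spans arbitrarily many cycles.  Recordings are assumed to begin at
heel-off, so the start distribution is the point mass π = (1, 0, 0, 0);
it is frozen during training by default (re-estimation via the standard
π ← γ₁ update is available behind a flag).  Observations are per-window
feature vectors; emission families are categorical tables, per-state full-
covariance Gaussians, or per-state diagonal-covariance Gaussian mixtures
(full covariance for the single-Gaussian family because the feature
dimension is small; diagonal for mixtures to keep many-component fits
well-conditioned on little data).

The model assumes homogeneous transitions and conditionally independent
observations given the state.  Both are wrong in detail for real gait —
phase durations are not geometric and neighbouring windows share samples
through the overlap — but the chain structure captures exactly the
constraint that matters for phase decoding: phases occur in order, without
skips.

## Signal path

* **Smoothing** — moving average, moving median, or the five-point cubic
  kernel (−3, 12, 17, 12, −3)/35, which reproduces cubic polynomials on
  interior points.  All filters use edge-inclusive symmetric padding, so
  length and alignment are preserved, and act per axis on 3-axis signals.
  Filter selection computes, for each candidate, SNR = 10·log₁₀(Σy²/Σ(x−y)²)
  and RMSE of the residual x−y (the noise reference is the filtering
  residual, making selection self-contained); highest SNR wins, ties fall
  to lower RMSE, then input order.  Default window 15 samples (0.15 s).
* **Axis choice** — for 3-axis recordings the largest-variance axis is
  used by default; in level walking the sagittal-plane rotation dominates.
* **Windowing** — sliding windows, default 10 samples with overlap 5 (half
  a window).  The default window does not exceed the shortest phase
  (~15 samples at 100 Hz), so most windows are phase-pure.
* **Features** — 15 canonical time-domain features (mean, variance, std,
  RMS, absolute mean, min, max, range, median, mean gradient, waveform
  factor = RMS/absolute-mean, crest factor, population skewness,
  population non-excess kurtosis, zero-crossing rate); the default subset
  is mean/variance/RMS.  Features are z-scored with training-set
  statistics — raw angular velocities reach hundreds of deg/s while rates
  live in [0, 1], and unscaled magnitudes destabilise the recursions —
  and the scaler is stored in the model bundle.

## Estimation

Forward–backward uses per-time normalisation with an additional per-frame
rescaling of emission likelihoods by their row maximum, so sequences of
any length neither underflow nor overflow; log-likelihoods are exact sums
of the log normalisers.  Baum–Welch pools sufficient statistics across
sequences; the transition update preserves the structural zeros of the
topology mask.  Variances are floored at 1e−6 of the per-dimension data
variance, applied by *clipping* rather than adding: a floor added
unconditionally perturbs the exact M-step and breaks the non-decreasing
log-likelihood trace at the 1e−6 level, whereas clipping only engages
when a component actually collapses.  States with near-zero occupancy are
re-seeded from global data statistics with a warning.  Viterbi ties
resolve to the lowest state index.

**Initialisation.**  Two regimes:

* *Annotated training data* (the default when labels are present): state
  emissions are bootstrapped from the labeled window moments and the
  transition matrix from consecutive-label counts, then refined by at
  most 5 Baum–Welch passes.  The cap is deliberate: the unconstrained
  likelihood rewards re-purposing a state for the high-variance windows
  that straddle phase boundaries (such a "boundary state" solution can
  exceed the labeled solution's likelihood substantially), and long
  refinement slowly un-anchors the bootstrap.  Five passes refine the
  moments while keeping states pinned to phases.
* *Unlabeled data*: the dominant cycle period is estimated from the first
  autocorrelation peak of the leading feature, each cycle is split into
  equal-duration segments, and segment k seeds state k, so state order
  follows phase order.  EM is restarted from several seeded
  initialisations (mean jitter in units of the segment SD) and the best
  final likelihood wins.  Because of the boundary-state issue above,
  unsupervised state identity is only guaranteed up to the cyclic
  rotation, and evaluation matches decoded states to reference labels by
  Hungarian assignment.

## Adaptation

Only emission means and variances are adapted; transitions, start
distribution and mixture weights are fixed (phase order does not change
between subjects, and the little adaptation data available estimates
means far better than transition rates).

* **MLLR** uses a single global regression class — with at most a few
  dozen Gaussian components there is no data to support more.  Transform
  rows solve occupancy-weighted normal equations in the
  diagonal-covariance closed form (full covariances contribute their
  diagonals); singular rows fall back to identity with a warning.
  Variances are adapted by a shared diagonal scaling H from
  occupancy-weighted residual moments, applied as Σ′ = H^½ Σ H^½ to
  preserve positive definiteness.  Three EM passes by default;
  per-iteration transforms are composed so the reported W maps the
  original means.  Reliable shift recovery needs the shift to be moderate
  relative to state separations; beyond that, state correspondence on the
  adaptation data itself breaks down.
* **MAP** interpolates prior and occupancy-weighted data statistics with
  a single strength τ (default 10, in effective frame counts — roughly
  the occupancy at which data and prior weigh equally).  μ′ is a convex
  combination of prior mean and weighted data mean; Σ′ shrinks the
  weighted scatter about μ′ toward the prior covariance.  Zero-occupancy
  components keep their prior values.
* **MLLR→MAP** chains the two, with the MLLR output as the MAP prior:
  the global transform moves every component, MAP refines the
  well-observed ones.

## Synthetic gait generator

Each cycle draws a duration from a lognormal with mean 1.56 s and a 5 %
coefficient of variation, splits it into the four phases at fractions
15/40/10/35 % (S1..S4; rounding residue goes to the longest phase), and
emits per-phase level × template plus white Gaussian noise.  Defaults:
levels (−150, 250, −100, 0) deg/s, noise SD 25 deg/s, constant templates
(half-sine bumps available).  Adjacent phase levels differ by ≥ 4 noise
SDs, making segmentation solvable but not trivial; note S1 and S3 — not
adjacent in the cycle — are deliberately closer (2 SDs), so the temporal
model genuinely contributes over pure clustering.  Cohorts perturb levels
(additive/multiplicative) and cadence per subject to emulate
inter-individual variation.

What the generator does *not* emulate: within-phase waveform detail of
real toe-gyroscope traces, correlated (non-white) sensor noise, drift,
pathological phase sequences, and double-support asymmetries.  Passing
tests therefore demonstrate correctness of the estimator and pipeline
machinery under the stated generative assumptions, not clinical accuracy
on real recordings.

## Evaluation

Window-level recognition is scored by confusion matrix and one-vs-rest
accuracy, precision, recall, F1, TPR and FPR (zero-denominator ratios are
reported as NaN sentinels, never silently as 0), plus ROC staircases and
trapezoidal AUC using the state's posterior γ as the score.  Decoded
paths are summarised per cycle: a cycle runs from one entry into S1 to
the next (S1 is the forced start state, so the boundary is well defined),
swing time is the time decoded as S2 within the cycle, stance is the
remainder, and times convert to seconds via the window stride.  With this
definition swing + stance = cycle by construction.  The swing-fraction
error compares decoded against true swing share per ground-truth cycle,
in percent of the cycle.

## Benchmark problem sizes

The packaged benchmarks use 20 sequences × 400 observations for parameter
recovery, 30 synthetic cycles (~930 windows) for the pipeline profile,
and 6 training + 10 held-out subjects × 30 cycles for the adaptation
comparison — sizes at which the recovered quantities are stable to a few
percent across seeds while the whole benchmark suite completes in
seconds.

## Known limitations

* First-order chain: no phase-duration modelling beyond geometric
  dwell times and no longer-range context.
* Unsupervised training can prefer a "boundary state" over the shortest
  phase (see Initialisation); supervised bootstrap is the robust path
  when any annotated data exists.
* MLLR shift recovery degrades for shifts large relative to state
  separations.
* The discrete emission family is implemented and tested for correctness
  but is not part of the gait pipeline defaults; continuous features fit
  gait data better.
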