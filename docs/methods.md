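# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `materialdecode`.

## Paradigm model

A trial is a 300 ms static presentation of a video's first frame followed
by 47 played frames of 41.2 ms each. The material behavior is revealed on
the 12th frame, i.e. at 300 + (12 - 2) x 41.2 = 712 ms after stimulus
onset; `ParadigmSpec` carries these constants and derives the impact
latency. Epochs span -500 to 2800 ms. Target (luminance-dim) trials —
drawn to peak near the 33rd frame (1577 ms) — exist only to be flagged and
excluded from analysis; the behavioral task itself is not modeled.

The stimulus set crosses 4 objects with 2 material behaviors within two
object pairs: pair 1 = {chair, milk} x {rigid, splash}, pair 2 =
{custard, glass} x {wobble, shatter}. Chair-rigid, milk-splash,
custard-wobble and glass-shatter are the *expected* combinations; the four
swapped combinations are *unexpected*. A full session has 8 x 108 = 864
analysis trials plus 96 targets (960 total), every video equally often,
fully randomized. The per-video repetition count is configurable because
the validation suites run at reduced counts (below).

## Synthetic data generator

Per participant, data are

    X[i, c, t] = noise[i, c, t] + sum_e A_e(i) * env_e(t) * P_e(level_e(i))[c]

- **Noise**: i.i.d. Gaussian (`noise_sd`, default 1), made temporally
  dependent by a stationary AR(1) over timepoints (coefficient 0.3 at the
  10 ms analysis step) and spatially dependent by mixing channels with
  (1 - alpha) I + alpha G, G random, alpha = 0.3, rows renormalized so the
  marginal channel scale stays ~1.
- **Effects**: each `EffectSpec` names a factor (object / material /
  expectation / video), a temporal window, and an amplitude. `P_e(level)`
  is a unit-norm channel pattern drawn once per participant per factor
  level — patterns are deliberately *not* shared across participants,
  because the group statistics operate on within-participant accuracies,
  not on shared topographies. For video-factor effects the amplitude is
  multiplied by (1 + `boost_on_unexpected`) on unexpected trials.
- **Envelope**: raised-cosine ramps within a boxcar window (boxcar
  selectable). `onset_ms` is the time of the first nonzero signal; the
  ramp spans [onset, onset + ramp]. The default ramp is 20 ms: it is
  smooth enough to avoid ringing-like artifacts in decoding onsets while
  keeping the half-amplitude latency within one 10 ms analysis sample of
  the nominal onset. With substantially longer ramps the first detectable
  signal lags the nominal onset by several samples regardless of
  statistical power, which systematically biases onset recovery late —
  with 50 ms ramps we measured a saturated detection lag of +28 to +38 ms
  that no increase in trial count removed.
- **Default effect set** (ground truth for the validation suites): object
  from 90 ms (amplitude 1.4); pair-general expectation from impact + 150 =
  862 ms (1.2); video identity from impact + 190 = 902 ms (0.7, x2.5 on
  unexpected trials); object-general material behavior from impact + 240 =
  952 ms (1.8); all to the epoch end. Amplitudes were calibrated once so
  that single-participant 4-way decoding plateaus at ~0.35-0.45 accuracy
  at the validation-suite trial counts, and then frozen.
- **Generation rate**: cohorts are generated directly on the 100 Hz
  analysis grid (331 timepoints) by default, which is what the decoding
  consumes; setting `rate_hz=500` generates at the acquisition rate and
  exercises the full preprocessing decimation chain instead.

What the generator does *not* emulate: realistic EEG spectra (1/f), eye
and muscle artifacts, bad channels, drifting noise covariance, shared
anatomical topographies, or stimulus low-level confounds. Passing tests
therefore demonstrate correctness and calibration of the *analysis*, not
robustness to real-data pathologies; preprocessing steps that were manual
in practice (ICA, visual channel rejection) are represented only by a
declarative channel-exclusion list.

## Preprocessing

Fixed order: band-stop notch (only when the line frequency is below
Nyquist at the current rate, so the default 100 Hz path skips it) →
average reference → decimation chain → baseline correction → trial and
channel selection. Decisions:

- **Decimation by block averaging** for integer rate ratios, carrying the
  time stamp of each block's first sample. No anti-alias filter is used,
  consistent with the no-temporal-filtering policy. The standard chain
  500 → 200 Hz is not an integer ratio; that stage uses polyphase
  resampling (`scipy.signal.resample_poly`), the same approach common EEG
  toolboxes use, and the 200 → 100 Hz stage is a factor-2 block mean.
- **Notch**: zero-phase 2nd-order Butterworth band-stop, 2 Hz half-width.
- **Baseline after re-referencing**, over the full prestimulus window
  (-500 to 0 ms, inclusive); both steps are linear so the order only
  matters for bookkeeping, and it is recorded in the config.

## Decoding

Features are the raw voltages across all channels at a single timepoint.
The classifier is LDA with the Gaussian equal-covariance rule, equal
priors (designs are balanced; empirical priors available), and shrinkage
regularization Sigma = (1 - gamma) S + gamma (tr S / p) I with pooled
unbiased within-class S. The default gamma = 0.01 is a small fixed ridge
of the kind common MVPA toolboxes apply; with 64 channels and a few dozen
training trials per class, S alone is singular or near-singular. gamma is
configurable and a Ledoit-Wolf analytic estimate is available for
single-timepoint fits. With gamma = 0 a singular S raises an error rather
than silently pseudo-inverting. If tr S = 0 (noiseless degenerate input),
the rule falls back to nearest-mean (Sigma = I). Ties in the argmax
resolve to the first class in sorted label order.

Three equivalent evaluation paths exist and are tested to agree exactly:
a per-timepoint reference fit, a batched direct path that builds
(T, p, p) covariances, and a batched dual path that applies the Woodbury
identity to Sigma = a I + U U' so all per-fold work is done in
n-dimensional dual space. For small datasets a per-participant
trial-by-trial Gram tensor is precomputed once and shared across folds and
schemes; this is what makes hundreds of replicate cohorts tractable on one
CPU. Float32 is used in the batched paths; accuracy values are identical
to the float64 reference on the tested instances.

Fold construction depends only on the trial table and a seed, never on the
data (no leakage; tested). Within-video k-fold splits shuffle each video's
trials with the scheme's seeded stream and chunk them with sizes differing
by at most one. The 16-assignment cross-generalization schemes enumerate
one video per object (or per material behavior) for training; the
enumeration is closed under complementation, so both train/test directions
are already contained in the 16 folds and are not run twice. The
material-across-objects scheme is 4-way (all behaviors at once), mirroring
the object scheme; a pairwise reading can be obtained by subsetting
labels. Accuracies are averaged over folds (unweighted), then smoothed per
participant with the 3-point moving average (shrinking at the edges)
*before* group statistics.

## Group statistics

Per timepoint: one-sample t of accuracy minus chance across participants,
one-sided (accuracy > chance); scheme contrasts use paired two-sided t.
Zero-variance timepoints get t = +/-inf (0 if the mean is also 0) and are
flagged. FDR correction is Benjamini-Hochberg across all timepoints of the
epoch (Benjamini-Yekutieli by flag); BH was chosen as the field default.
Selection rules then drop timepoints before stimulus onset and runs
shorter than 2 consecutive timepoints. The peak is the maximum t within
significant timepoints (global max, flagged, if nothing is significant);
Cohen's d = t / sqrt(n) for both one-sample and paired tests.

**Onset estimator.** The reported *primary onset* is the start of the
significant interval containing the peak, not the first significant point
anywhere: when a strong effect elevates the BH step-up threshold,
autocorrelated accuracy time courses (AR noise plus the smoothing window)
routinely produce isolated spurious 2-point runs far from the effect, and
the first-point rule then reports those. Conversely, a sustained effect
region is occasionally interrupted by single non-significant samples;
since the 30 ms smoothing window cannot resolve features narrower than
itself, intervals separated by gaps of at most 30 ms are merged before the
peak-containing interval is selected (the raw interval list is reported
unmerged). All intervals are still listed in every summary. Latencies are
reported relative to stimulus onset, with impact-relative values
(t - 712 ms) alongside.

## Validation suites and problem sizes

`materialdecode.validation` runs two simulation studies, used by the test
suite:

- **Null calibration**: 200 pure-noise cohorts, 25 participants, 64
  channels, 331 timepoints, 4 trials per video, 2-fold within-video
  splits. Checks that each scheme's family-wise rate of reporting any
  post-onset significant interval stays within 3 Monte-Carlo standard
  errors of alpha = 0.05 and that grand-mean accuracy is at chance within
  3 standard errors.
- **Onset recovery**: 50 cohorts with the default effect set, 25
  participants, 6 trials per video, 3-fold splits. Checks that the
  detected onsets of the four injected effects fall within +/-30 ms of
  ground truth in at least 80% of replicates and that the latency cascade
  (expectation before the unexpected>expected difference before
  cross-object material) is reproduced.

The reduced per-participant trial counts are the package's chosen
simulation sizes: they keep hundreds of replicate cohorts tractable while
leaving the group-level analysis (the object under test) at full size.
Accuracies at these counts are lower than a full 108-repetition session
would give; the calibration band above refers to these sizes.

## Known limitations

- The generator's linear additive patterns cannot produce genuinely
  nonlinear class structure; LDA is therefore well-specified by
  construction, and the suites do not probe classifier misspecification.
- Cross-generalization schemes inherit interference by construction: a
  pattern that anti-generalizes (e.g. expectation status is swapped
  between the exhibiting objects of a material) depresses accuracy below
  chance in parts of the epoch. This is a property of the design, not a
  bug; one-sided tests are unaffected, but it can delay detectable onsets
  of weaker effects.
- Temporal generalization (train-time x test-time) matrices, searchlight
  analyses, cluster-based permutation statistics, and import of raw EEG
  interchange formats (BrainVision/EDF) are out of scope; the epoched
  container is the interchange point for external data.
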