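# Methods

## Problem and data model

`insolegait` classifies seven gait types — walking, fast walking, running,
stair climbing, stair descending, hill climbing, hill descending — from a
pair of instrumented shoe insoles sampled at 100 Hz. Each insole carries an
8-sensor plantar-pressure array quantized to three levels (0 = no contact,
1/2 = increasing pressure), a 3-axis accelerometer and a 3-axis gyroscope.
A recording is the synchronized triple of a `frames × 16` pressure array,
`frames × 6` acceleration array and `frames × 6` gyro array, left-foot
channels first.

## Unit-step segmentation and swing-phase cleaning

The gait cycle alternates a *stance* phase (foot on the ground, some
pressure sensors non-zero) and a *swing* phase (foot airborne, all eight
sensors of that foot zero). Segmentation uses the left foot only:

* a **swing start** is the first frame of each maximal run where the sum of
  the 8 left-foot pressure channels is zero (after being non-zero, or at
  frame 0);
* the following **stance start** is the first frame with ≥ 2 non-zero
  left-foot sensors — requiring two sensors makes a single faulty channel
  unable to fake a heel strike;
* a **unit step** spans one swing start to the end of the following stance
  phase; because phases tile the recording contiguously, that end is
  exactly the next swing start, so steps cover the recording without gaps
  or overlaps. A final step whose stance runs into the end of the recording
  is dropped as truncated.

Insole hardware occasionally reports a non-zero value on one sensor during
swing (electrical cross-talk/heating). Such a frame splits one zero-run in
two and would double-count a step. The cleaning rule: any frame strictly
inside a `[swing_start, stance_start)` interval whose left-foot sum is
**exactly 1** is an artifact, and the offending channel is zeroed.
Segmentation runs detection → cleaning → re-detection. The rule is applied
literally: a lone sensor at level 2 (sum 2) is *not* cleaned — two sensors
at 1 would have triggered a stance start instead, so sum 2 from a single
sensor is ambiguous and we leave it untouched rather than extend the rule.

## Normalization, flattening, assembly, standardization

Steps vary in duration with walking speed, which is a nuisance for
classifying gait *type*. Every step is resampled channel-wise to `t`
frames (default `t = 63`, the shortest step of the reference data) by
linear interpolation on a uniform grid; pressure is then rounded and
clipped back into {0, 1, 2}. Linear interpolation is the minimal-assumption
resampler for short quantized and band-limited signals; it preserves
constants exactly. A normalized step flattens time-major into vectors of
length `63·16 = 1008` (pressure) and `63·6 = 378` (accel, gyro).

A classifier sample is `k` consecutive normalized steps stacked into a
`(t·k) × W` array per modality. Windows are non-overlapping with the
remainder dropped — the reference sample counts (13,531 steps → 6,742
two-step samples) are consistent only with that convention.

Features (each time-channel cell) are standardized to zero mean and unit
variance with statistics fitted on the **training split only**; the same
affine transform is applied to test data, and zero-variance features map
to 0. Standardization is refit inside every evaluation split so no test
statistics leak into training.

## Network architecture

One convolutional feature extractor per sensor array: three valid
(unpadded) conv layers with 32, 64 and 128 filters, filter height 20
frames; the first layer's filter spans the full sensor width W, later
layers are 1 × 20 along time. The first-layer stride follows the sample
depth: `s = 1` for `k ∈ {1,2}`, `s = 2` for `k ∈ {3,4,5}` (stride applies
to layer 1 only; the later layers' published configuration fixes only
filter count and 1×20 size). There are no pooling layers — stride provides
the only downsampling, matching the concrete three-conv-layer
configuration rather than the generic CNN recipe. Each conv layer applies
ReLU then batch normalization — an unconventional but deliberate ordering
kept as part of the fixed architecture. With
`k = 1` the chain of feature-map lengths for any modality is
63 → 44 → 25 → 6, giving a flattened feature vector of 6·128 = 768.

The flattened features feed a fully connected network of two hidden
layers (defaults 256 and 128; the hidden sizes are free parameters),
dropout (default rate 0.5, explored range 0.5–0.7) applied
after the second hidden layer just before the output, and a softmax
output with 7 nodes. Weights are initialized with Xavier-uniform.

**Multi-modal fusion.** Single-modal networks are trained independently;
their conv stacks are then frozen and the flattened feature vectors of
2–3 modalities concatenated into a fresh two-hidden-layer head trained
from scratch. An end-to-end joint variant (unfrozen, fresh stacks) is
available via `build_multi_modal(..., pretrained=None)`.

**Accel/gyro width.** Stored arrays have 6 columns (both feet), while the
per-array width could equally be read as 3 (one foot). Default: `W = 6`,
one branch over both feet. `ModelSpec(split_feet=True)` instead builds two
3-wide branches per array and concatenates their features, the W = 3
reading.

**Training.** Categorical cross-entropy minimized by Adam at learning
rate 1e-4, batch size 32, default 50 epochs with optional early stopping
on a held-out 10% of the training split (patience 5). The network engine
is a self-contained numpy implementation (im2col convolution,
batch-norm running statistics, inverted dropout); training is
deterministic given the seeds for initialization, batch order and dropout.

## Evaluation protocols

* **Repeated random subsampling**: disjoint train/test draws without
  replacement (defaults 1000/1000), repeated (default 20×).
* **K-fold cross validation**: K = 7 (the class count), fold sizes
  ⌊n/K⌋ or ⌈n/K⌉, each fold tested once, repeated (default 10×) with fresh
  shuffles. At n = 13,531 and K = 7 every fold has 1,933 test and 11,598
  training samples.

Splits are stratified by class by default (configurable off). The
reference protocol does not state stratification; it is enabled here so
small synthetic runs cannot produce class-empty training sets, and it is
flagged in each run's manifest via the recorded configuration.

## Synthetic data generator

No public dataset accompanies the reference measurements, so the
package ships a generator that reproduces the *structural* assumptions of
the pipeline with exact ground truth:

* per-class step durations are truncated-Gaussian per step (means 60–110
  frames: walking ≈ 1.0 s/step, fast walking ≈ 0.8 s, running ≈ 0.6 s,
  stairs/hills 0.9–1.1 s; sd 6–9 frames, minimum 4 frames), with stance
  fractions 0.40 (running, reflecting the aerial phase) to 0.66 (stair
  climbing);
* left-foot stance activates sensors heel-to-toe: heel channels at stance
  onset (guaranteeing the ≥ 2-sensor heel-strike rule fires at the true
  boundary), midfoot/forefoot from 20–30% of stance, toes from 50%,
  ramping 1 → 2 → 1 within each sensor's window; the right foot is the
  left pattern shifted by half a step;
* accel/gyro channels are sums of three harmonics locked to the step
  phase with class-specific amplitudes (0.6×–2.2×) and harmonic weights,
  plus white Gaussian noise (sd 0.15 in units of the base amplitude);
* swing artifacts: each frame strictly inside a swing is set to 1 on the
  left third sensor with probability 0.05.

Artifact injection deliberately skips the first frame of each swing: an
artifact coinciding with the zero-crossing shifts the *measurable* swing
onset itself, which no post-hoc sum-1 rule can restore, so exact
boundary recovery is only a well-posed requirement for interior
artifacts. Each recording ends with a 5-frame zero tail so the final
stance demonstrably ends and all `n_steps` ground-truth intervals are
recoverable.

What the generator does **not** model: subject-specific gait signatures,
inter-subject variability, kinematic consistency between pressure and
inertial channels, sensor drift, or the per-class step-count imbalance of
real data collection. Classes are separable by construction (distinct
dominant frequencies and amplitudes); the generator's class-separability
level is a free choice fixed once at these defaults. Passing tests
therefore demonstrate that the pipeline and classifier behave correctly
on data satisfying the stated structural assumptions — not that these
accuracies transfer to real insole recordings.

## Problem sizes and numerical choices

The shipped experiments use 200 one-step samples per class (10 simulated
recordings × 20 steps), a single stratified 1000-train/400-test split and
30 training epochs for the headline accuracy; the comparison of fused
vs. single-modal classifiers uses 60 samples per class, 5 seeds and 6
epochs. These sizes give stable results for a method whose training
dynamics saturate quickly on separable synthetic data.

Ties in the arg-max prediction resolve to the lowest class code. Batch
normalization uses eps = 1e-5 and momentum 0.9 for running statistics;
evaluation always uses running statistics. Resampling a degenerate
one-frame step is an error rather than a silent repeat. Recordings with
no complete swing→stance cycle segment to an empty step list, not an
error.

## Known limitations

* The swing-cleaning rule handles only sum-1 artifacts, per its
  definition; a two-level artifact on one sensor (sum 2) survives
  cleaning and can split a swing. Real hardware faults of that kind would
  need a wider rule.
* Accuracy figures obtained on the synthetic benchmark are upper bounds
  of convenience: class-conditional signal differences are cleaner than
  any real cohort's.
* The numpy training engine is single-threaded aside from BLAS matmuls
  and is sized for the shipped experiment scales, not for large-scale
  hyperparameter sweeps.
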