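# Methods

This note documents the models, numerical choices and known limitations of
`fnftremor`. It is written for a reader who wants to know *why* the code
does what it does, not just what it computes.

## The measurement model

A finger–nose–finger (FNF) recording is reduced to a per-frame fingertip
trajectory \((x_i, y_i)\) in image coordinates (origin top-left, x right,
y down, 30 fps by default). All downstream quantities — six kinematic
features, a rule-based severity verdict, and cross-validated class
predictions — are functions of this trajectory alone. The pixel scale at
the default camera distance (1–1.5 m) is taken as **10 px ≈ 1 cm**,
configurable; it maps the clinical severity anchors (ET upper-limb tremor
≥ 1 cm, CD FNF tremor ≥ 2 cm ⇒ severe) onto synthetic amplitudes of 10 and
20 px.

## Synthetic kinematics: what the generator emulates

The generator is the package's test bed and study-condition definition.
Each recording is `n_cycles` round trips: dwell at the nose, initial
transit to the examiner's finger, dwell there (a *touch epoch*), return
transit. Defaults: 2 s per cycle, 3 cycles, 400 px travel, 15% of each
cycle in each dwell.

**Transit profile.** Healthy FNF movement is smooth with near-constant
speed, so a transit follows a velocity profile that ramps up with a
minimum-jerk (smoothstep) shape over the first 10% of the transit, holds a
constant plateau, and ramps down symmetrically; position is the closed-form
integral. A pure minimum-jerk position profile was rejected because its
peak speed is 1.875× the mean — far from the near-constant pace of a
healthy subject — and because its long slow tails interact badly with
threshold-based segmentation (disproportionate truncation of slower
transits biases the recovered time ratio).

**ET (essential tremor).** A regular vertical sinusoid
\(A\sin(2\pi f t)\) rides on the transit; default \(f = 6\) Hz (the
clinical band is roughly 4–12 Hz), \(A = 8\) px. During touch epochs the
amplitude is multiplied by 2 (tremor is most visible when the finger rests
on the examiner's finger). A `slowdown_gain` warps the approach phase so
progress decelerates near the target. The frequency must lie below the
Nyquist limit (fps/2); parameters violating this are rejected.

**CD (cerebellar disorder).** Irregular tremor is modeled as band-limited
Gaussian displacement: white noise low-pass filtered (2nd-order
Butterworth, zero-phase) with cutoff \(f_{\text{tremor}}(1 +
\text{irregularity})\), normalized to unit variance, then scaled so its RMS
equals \(A/\sqrt2\) — the RMS of a sine of peak amplitude \(A\) — so ET/CD
comparisons at matched `tremor_amp_px` are fair. The jitter amplitude is
multiplied by an intention ramp \(1 + g\cdot\text{proximity}\) (proximity =
normalized progress toward the target), and a horizontal component at 0.35×
the vertical RMS makes the path irregular in both axes.
`return_asymmetry` (default 1.5 for CD) stretches the initial transit
relative to the return. No canonical spectrum or amplitude distribution
exists for CD tremor in this test; these parameters are modeling choices,
fixtures rather than claims about patients.

**What the generator does *not* emulate:** hands (the marker is an ideal
disk), occlusion, motion blur, lighting changes, camera shake, examiner
movement, fatigue drift. Tests passing on synthetic data therefore
establish correctness of the *computational chain*, not clinical accuracy.

**Rendering.** Frames are a plain gray or smooth textured background, a
filled disk of the tape color (default radius 6 px) at the ground-truth
coordinate, optional seeded Gaussian pixel noise, and optionally a static
square patch of near-marker hue (a "distractor") for noise-filter and
region-selection tests. The default distractor (7×7 px) is deliberately
smaller than the marker so the first-frame largest-area rule is well-posed.

## Tracking: numerical choices

- **HSV convention**: hue in degrees on [0, 360), S/V in [0, 1]; red is two
  intervals, (0, 25) ∪ (335, 360), because hue wraps at red. S/V bounds
  default to near-pass-through (S ≥ 0.25 rejects gray backgrounds).
- **Background**: per-pixel median over the first 30 frames (the marker is
  small and moving, so the median sees the scene behind it), or a provided
  image. Foreground requires mean absolute RGB distance > 25 (configurable;
  `None` disables differencing).
- **Connectivity**: 8-connected components; centroid is the unweighted mean
  of member pixels. Components below 20 px are dropped as noise.
- **Aspect-ratio filter**: bounding-box width/height within (0.4, 2.5); a
  fingertip patch is roughly square, elongated blobs are furniture edges
  and cables.
- **Selection**: nearest centroid to the previous position; ties break to
  the larger area, then the smaller x (determinism). First frame: largest
  area.
- **Gaps**: internal runs of marker-less frames up to 5 frames are filled
  by even division of the coordinate difference (exact for linear motion);
  leading/trailing gaps are trimmed, never extrapolated; longer gaps abort
  the recording rather than invent data.

On noiseless synthetic renders the end-to-end RMS error is ~0.1 px (the
residual is binarization asymmetry of the disk at sub-pixel positions);
with pixel noise of sd 5 and a distractor it stays well under 2 px. The
nearest-previous rule is only sound while the true marker remains the
nearest candidate: a distractor inside the tremor's single-frame jump
radius, or overlapping the path (occlusion), defeats it by construction.

## Features: conventions and edge cases

- **RMSD** fits y as a quadratic in x (the transit arc). x is centered and
  scaled before the least-squares solve for conditioning; fitted values are
  unchanged. Constant x is an error. Interpolated frames participate.
- **Acceleration** is the first difference of scalar speed (not vector
  acceleration): the feature targets *variations in pace*. The variance is
  population (divide by n).
- **Histogram feature** uses 4 equal-width bins over the observed x range;
  the median of four counts is the mean of the middle two. The alternative
  reading — binning over the range of bin *frequencies* rather than x
  *values* — is not meaningful for a histogram of positions and was
  rejected. n is the total frame count of the recording for both this
  feature and RMSD.
- **Angular feature**: atan2 honors the full [-180°, 180°] range; the
  bands ±(30°, 150°) are symmetric about the horizontal, so the y-down
  image convention needs no sign flip. Zero-displacement steps are not
  counted. Both the raw count and the per-step fraction are emitted; the
  count is the rule's native input, the fraction is
  recording-length-independent.
- **Segmentation** thresholds the *transport speed*: the absolute first
  difference of a 5-frame centered moving average of x. Raw per-frame
  displacement was rejected because severe tremor keeps it above any sane
  threshold even while the finger rests on the examiner's finger, making
  touch epochs undetectable — the transit is horizontal and tremor is
  oscillatory, so smoothing x isolates transport. Default threshold: 25%
  of the 95th-percentile transport speed, recomputed per recording and
  recorded in the output metadata (scale-covariant by construction).
  Cleanup: sub-threshold blips < 3 steps inside a transit are bridged,
  moving runs < 3 steps are discarded, and each surviving run is eroded by
  `window//2` per side — exactly the widening the moving average
  introduces, so measured transit durations are unbiased (verified by
  recovering a 1.5 initial/return asymmetry to within ~3% in the median).
  Touch-epoch *boundaries* come from the un-eroded mask, where the
  widening and slow-ramp truncation nearly cancel (±1 frame on noiseless
  kinematics).
- **Average travel distance** uses only the first two touch epochs, as the
  four bounds \(m_1..m_4\) of the formula imply; later touches are ignored.
  \(d_i\) is the displacement *into* frame i, so each epoch contributes
  \(m_2-m_1+1\) terms, matching the denominator.

Invariances (tested): translation leaves all six features unchanged;
scaling coordinates by s scales RMSD and travel distance by s, acceleration
variance by s², and leaves the histogram, angular and time-ratio features
unchanged.

## Severity

Points rules: ET — histogram, angular, travel distance, severe at ≥ 2
points; CD — RMSD plus those three, severe at ≥ 3 points. A value exactly
at the threshold scores the point. The ET rule takes the angular *count* by
default (configurable to the fraction). There are no canonical reference threshold
values, so `calibrate_thresholds` defines a reproducible procedure:
per feature, the midpoint between the mild-group maximum and severe-group
minimum, falling back to the pooled median when the groups overlap.
Calibrations are kept rule-specific (ET and CD thresholds never share
training data), and thresholds travel with every result they produce.

## Classification

Stratified k-fold (k = 5 default) with per-fold standardization fitted on
training folds only; accuracy is pooled correct/total. Classifier
hyperparameters (no canonical reference values; serialized into every
report): SVM = RBF
kernel, C = 1, gamma = "scale", one-vs-rest; k-NN k = 3; logistic
regression lbfgs with one-vs-rest. When the smallest class is below k the
splitter falls back to unstratified folds with a warning. The synthetic
three-class cohort (30/class) is nearly perfectly separable — a property of
the generator's clean class structure, not a claim about the ~77–87%
accuracies attainable on clinical recordings.

## Problem sizes

Defaults used by the test suite and the acceptance script: feature-oracle
agreement on 100 random recordings; tracking fidelity on 20 one-cycle
renders at 160×240 (240×320+strip with distractor); 30-recording/class
classification cohorts; 20-seed parameter-recovery panels. These sizes give
stable medians and sub-minute runtimes per panel on one CPU.

## Known limitations

- Markerless or multi-finger tracking, nose/examiner-finger detection, and
  frequency-domain (FFT) features are out of scope.
- The severity rules are binary (mild/severe); no granular grades.
- Feature magnitudes depend on camera distance via the pixel scale; no
  automatic normalization is applied (the travel-distance feature in
  particular scales with proximity to the camera).
- The CD tremor model is a fixture: plausible, parameterized, and clearly
  labeled synthetic — not fitted to patient data.
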