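# fnftremor

Video-based kinematic analysis of the **finger–nose–finger (FNF) test** for
tremor assessment — non-contact quantification of what a neurologist watches
for when differentiating **essential tremor (ET)** from **cerebellar
disorder (CD)**.

In the FNF test the subject moves their index finger back and forth between
their own nose and the examiner's finger. ET produces a *regular* action
tremor (typically 4–12 Hz) that worsens near the target; CD produces
*irregular* tremor with an intention component (amplitude grows as the limb
approaches its goal) and impaired targeting. These differences are subtle to
the eye but measurable in the fingertip's pixel trajectory.

`fnftremor` implements the full chain:

1. **Tracking** — the fingertip is wrapped in red or green tape; each video
   frame is converted to HSV, thresholded on hue/saturation/value,
   intersected with an ROI and a background-difference mask,
   connected-component labeled, filtered by bounding-box aspect ratio
   (a fingertip patch is roughly square), and the candidate nearest the
   previous position is selected. Short detection gaps are bridged by
   linear interpolation.
2. **Features** — six scalar kinematics per recording
   (trajectory \\((x_i, y_i)\\), \\(n\\) frames, displacement
   \\(d_i = \lVert p_i - p_{i-1}\rVert\\)):
   - **RMSD**: \\(\sqrt{\tfrac1n\sum_i (y_i-\hat y_i)^2}\\) about a
     least-squares quadratic \\(\hat y(x)\\) — vertical deviation from the
     ideal transit arc;
   - **acceleration variance**: \\(\tfrac1n\sum_i(a_i-\bar a)^2\\) with
     \\(a_i\\) the first difference of speed — raggedness of the pace;
   - **histogram feature**: \\((h_{\max}-h_{\mathrm{med}})/n\\) over a
     4-equal-bin histogram of \\(x\\) — time piled up near the target;
   - **vertical swing count**: steps whose direction
     \\(\theta=\operatorname{atan2}(\Delta y,\Delta x)\\) falls in
     \\((30°,150°)\\) or \\((-150°,-30°)\\);
   - **time ratio**: \\(\bar f_0/\bar f_r\\), mean initial-path over mean
     return-path duration in frames;
   - **average travel distance**:
     \\(\bar d = \bigl(\sum_{m_1}^{m_2} d_i + \sum_{m_3}^{m_4} d_i\bigr) /
     \bigl((m_2{-}m_1)+(m_4{-}m_3)+2\bigr)\\) over the first two touch
     epochs — shaking while "resting" on the examiner's finger.
3. **Severity** — threshold-point rules: the ET rule awards one point per
   feature (histogram, angular, travel distance) at/above its threshold,
   2+ points ⇒ severe; the CD rule adds RMSD, 3+ points ⇒ severe.
   Thresholds are calibrated from labeled examples by a midpoint rule.
4. **Classification** — LDA, logistic regression, RBF-SVM and k-NN with
   stratified k-fold cross-validation on three tasks: healthy vs tremor,
   ET vs CD, three-class.

Because clinical FNF videos cannot be redistributed, the package ships a
first-class **synthetic generator**: ground-truth FNF kinematics for the
three subject classes (regular sinusoidal tremor for ET, band-limited
irregular jitter with an intention ramp for CD) and a renderer that turns
them into marker videos. Every stage is validated against this ground truth
and against independently coded brute-force oracles.

## Worked example

```python
from fnftremor import KinematicsParams, generate_trajectory, extract_features

for cls in ("healthy", "et", "cd"):
    truth = generate_trajectory(KinematicsParams.for_class(cls, seed=5))
    fv = extract_features(truth.trajectory)
    print(cls, fv.rmsd, fv.accel_variance, fv.time_ratio)
```

Running `python examples/03_extract_features.py` prints:

```
feature                      healthy          et          cd
rmsd                           0.000       6.713      19.796
accel_variance                13.360      39.335     307.007
histogram_feature              0.083       0.175       0.086
vertical_swing_count           0.000      71.000     134.000
time_ratio                     1.000       0.882       1.475
avg_travel_distance            0.366      10.373      21.910
```

Read: the healthy transit is a flat line (RMSD 0, no vertical swings); the
ET subject oscillates vertically (71 swing steps) and shakes on the
examiner's finger (travel 10.4 px/frame ≈ 1 cm at the default 10 px/cm
scale); the CD subject is irregular (acceleration variance 307), strays far
from the arc (RMSD 19.8 px) and needs 1.48× longer to reach the target than
to return — the 1.5 asymmetry built into the CD generator, recovered by the
segmentation.

The other examples cover generation (`01`), video tracking (`02`, RMS error
0.066 px on a noisy render), severity calibration (`04`, 19/20 held-out
verdicts correct) and cross-validated classification (`05`). A thin CLI
mirrors the stages: `fnf synth | track | features | severity | classify |
run` (see `fnf --help`).

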