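# Methods

## Pose model and conventions

A head pose is a rigid transform (R, t) from the face-model frame to the
camera frame. The camera frame follows the imaging convention: x right,
y down, z forward into the scene, image origin top-left, pixel centres on
integer coordinates. The model frame coincides with the camera frame at
the null pose, so a subject squarely facing the camera has all angles
zero; the nose tip has negative z in the model frame.

The rotation is parameterised by intrinsic Euler angles applied in the
order **yaw → pitch → roll**, with the clinical sign convention:

* yaw > 0: face turned toward the subject's **left**;
* pitch > 0: **chin up**;
* roll > 0: head tilted toward the subject's **right shoulder**.

Because the camera frame has y down and z forward, the anatomical up and
out-of-face axes are −y and −z, giving R = Ry(−yaw) Rx(−pitch) Rz(−roll).
No standard exists for these conventions in the clinical literature, so
one is fixed here and used consistently in every file format, CLI help
string and result object. At gimbal lock (|pitch| = 90°) the decomposition
reports the representative with roll = 0, folding the ambiguity into yaw.
All interfaces use degrees and millimetres; radians never appear in files.

Pose is reported **relative to the camera**. The clinical reading
(posture relative to shoulders and visual axis) assumes the usual set-up:
camera levelled at head height, subject's shoulders square against the
chair back, chair facing the camera.

## Canonical face model

The 68 landmarks follow the standard annotation scheme (17 jawline, 5+5
eyebrows, 9 nose, 6+6 lid margins, 20 lips). No reference 3D table for
these landmarks is published, so the package ships its own: a fixed,
versioned CSV of average adult facial proportions, authored to satisfy
four structural invariants that the estimator and tests rely on —

1. exactly 68 points with the standard region counts;
2. exact mirror symmetry about the midsagittal plane under the left-right
   index pairing (all coordinates are multiples of 0.5 mm, so the
   symmetry is exact in binary floating point);
3. pupil-centroid separation of exactly 65.0 mm (the centroid of each
   eye's six lid-margin points stands in for the pupil centre);
4. origin at the midpoint of the two pupil centroids.

Nothing else about the shape is contractual; tests deliberately avoid
depending on individual coordinates. The 65 mm interpupillary distance is
the metric anchor: monocular landmarks determine translation only up to
scale, and fixing the model IPD resolves it. A subject whose true IPD is
d mm is therefore reported at a distance biased by the factor 65/d
(about ±5% across the adult population); angles are unaffected.

## Pose estimation

Estimation inverts the pinhole projection u = cx + f·X/Z,
v = cy + f·Y/Z of the rigid model by minimising the sum of squared
reprojection errors over the six pose parameters, using only the
landmarks marked visible (at least 6, the number needed to
over-determine 6 degrees of freedom).

**Initialisation** is closed-form weak perspective: a least-squares
affine fit of the 3D model points to the pixels, whose 2×3 linear part is
orthonormalised (SVD projection) to the nearest rotation and whose scale
s gives the depth tz = f/s. The approximation ignores within-face depth
variation, so it is biased by a few degrees and a few percent in depth,
but reliably lands inside the refinement basin for face-like geometry.
Rank deficiency of the affine system (collinear visible landmarks) is a
degenerate-configuration error.

**Refinement** is damped Gauss–Newton (Levenberg–Marquardt via
`scipy.optimize.least_squares(method="lm")`) over (yaw, pitch, roll, tx,
ty, tz), capped at 50 iterations with tolerances far below the reporting
precision (successive-update targets: 1e-6°, 1e-4 mm). Depths are clamped
at 1 mm inside the residual so that a wild intermediate step cannot
produce non-finite residuals. On a noiseless frame the fit is exact to
numerical precision (observed ~1e-13° over a ±30° yaw / ±20° pitch /
±50° roll grid at 0.8–1.5 m); with 1 px landmark noise at a focal length
of 1000 px and 1.2 m standoff the mean absolute angle error is ~0.25°.
Failures (divergence, non-convergence, degenerate input) never raise from
the public entry point; they surface as `tracked = False` with NaN pose.

**Confidence** is a goodness-of-fit score:
confidence = clamp(1 − residual/residual_scale, 0, 1), where the residual
is the RMS reprojection error divided by the projected inter-pupil pixel
distance. The normalisation makes the score invariant to image
resolution and subject distance, so one threshold is meaningful across
cameras. Defaults: residual_scale = 0.10 (confidence reaches 0 when the
RMS misfit is 10% of the inter-pupil distance) and a tracking threshold
of 0.75. At the default camera (focal = image width = 1920 px) a clean
fit under 1 px noise scores ≈ 0.87 and uniform-random "landmarks" score
0. The original system derives its confidence from the landmark
detector's fit likelihood; this package has no detector, so the
reprojection-residual surrogate preserves the semantics (degraded by
occlusion, noise and extreme pose) but not the numeric scale of any
particular published confidence figure.

A frame is `tracked` when the optimiser converged and confidence meets
the threshold. Distance to the subject is ‖t‖ and requires a tracked
frame. No temporal smoothing is applied: frames are independent, so the
package adds no uncontrolled dynamics to whatever landmark provider
feeds it.

## Synthetic data

The generator emulates the two validation settings without any external
data.

*Subjects* are the canonical model plus i.i.d. Gaussian per-point
perturbation (default used in tests: 0–2 mm), rescaled exactly to a
chosen true IPD. *Sequences* project a subject along a pose trajectory
and apply the stressors reported for real head-pose video: i.i.d.
Gaussian pixel noise, random per-landmark occlusion, and dropped frames
(empty observations with ground truth still recorded). An optional
degradation term grows the noise SD linearly with pose eccentricity (the
largest absolute Euler angle), emulating the empirical pattern that
landmark localisation deteriorates as the face turns away. All
generators are deterministic per seed.

*The fixation protocol* enumerates 43 targets per subject: yaw 0, ±5 …
±40° (17), pitch likewise (17), roll −40 … +40° by 10° (9); the null
target appears once per axis series, the only accounting consistent with
43 trials and 68/68/36 per-axis observations over four subjects. The
*protocol study* simulator draws, per subject × trial, a true executed
pose (target + Gaussian execution error, default SD 3°, reflecting that
subjects fixate targets with their heads rather than being clamped to the
target angle) and two instrument readings (truth + independent Gaussian
noise, default SD 1° each, of the order of a mechanical inclinometer's 2°
dial gradations). Defaults: subject 1.2 m from a 1920×1080 camera with
focal length 1920 px.

What the generator does **not** model: photorealistic appearance (and
hence real landmark-detector error structure, which is correlated across
landmarks and heavy-tailed), motion blur, strap-fit bias of the
mechanical comparator, identity-specific non-rigid shape. Passing tests
on this synthetic data therefore validate the geometry and statistics of
the pipeline, not the end-to-end accuracy of any particular landmark
detector on real video.

## Evaluation statistics

Per-frame absolute errors are computed per axis on the circle
(differences wrapped into (−180, 180]). Untracked frames are excluded
from error statistics and reported as a separate retention rate, the
same separation used when a confident-recognition percentage is quoted
alongside accuracy. The **combined** error of a frame is the mean of its
three per-axis absolute errors, making the combined mean the grand mean
of all per-axis errors; medians are also reported because rapid-motion
and occlusion frames produce heavy upper tails.

The **operational range** of an axis is the largest symmetric ±L
(multiple of the 5° bin width) such that every populated bin with
|centre| ≤ L has mean combined error below the threshold (5° default).
Empty bins inside a candidate range pass vacuously; if even the central
bin fails, the axis gets range 0 with a warning flag. The rule is
monotone in the threshold.

**Single-axis subanalysis** assigns a frame to axis A when |A| strictly
exceeds both other magnitudes and those two are at most the dominance
threshold (10° default; "predominantly one axis" has no standard
definition, so the rule is explicit and configurable).

**Repeated-pose reliability** collects, for a list of target values on
one axis, tracked estimates whose true pose deviates only on that axis
(others within tolerance, default 2.5° = half the 5° protocol step) and
whose axis value is within tolerance of the target, requiring a fixed
number of repeats per pose; the resulting poses × repeats matrix feeds
the ICC.

## Agreement statistics

Pearson r carries a two-sided p-value from the exact t transform with
n − 2 degrees of freedom. The calibration line is ordinary least squares
of the tracker on the comparator; R² equals r² identically for simple
OLS with intercept. Bland–Altman uses differences d = tracker −
comparator, bias = mean(d), limits = bias ± 1.96·SD(d) (sample SD),
plotted against the per-pair mean. Restricting pairs to an operational
range filters on the comparator's reading, the natural reference
instrument. The ICC is the two-way random-effects, absolute-agreement
form — ICC(2,1) and ICC(2,k) from the ANOVA mean squares — because
absolute agreement is the stricter, conventional choice for instrument
reproducibility; the consistency variants ICC(3,1)/ICC(3,k) are
available behind a flag. The implementation is authored from the mean
squares directly and is cross-checked in the test suite against an
explicit sum-of-squares oracle (to 1e-12) and against
`pingouin.intraclass_corr`.

## Study designs used by `scripts/acceptance.py`

Problem sizes are chosen so the whole script runs in seconds on one CPU:

* exact-recovery grid: 3 yaw × 3 pitch × 5 roll × 2 depths = 90 fits,
  focal 1000 px;
* noise Monte Carlo: 100 replicates at 1 px, focal 1000 px, 1.2 m;
* tracking rate: 200 frames, random poses inside ±30/±20/±30°, 1 px
  noise, 10% occlusion, 5% dropped frames, default camera, model-matched
  subject (see limitations);
* protocol study: 4 subjects × 43 trials, execution SD 3°, instrument
  SDs 1°;
* reliability: 8 repeats of each of 14 pitch targets (−30 … +35° by 5°)
  under 1 px noise, default camera;
* eccentricity analysis: per axis, 8 repeats of each target −40 … +40°
  by 5°, noise 0.5 px + 0.8 px per degree of eccentricity, focal
  1000 px, estimator in a benchmarking configuration
  (confidence_threshold 0.01, residual_scale 1.0) so extreme-pose fits
  are retained and filtered explicitly rather than dropped. The 0.8
  px/deg gain was set from the measured sensitivity of the estimator
  (~0.25° mean absolute error per px of noise at this camera) so that
  the 5° threshold is crossed in mid-range, yielding a finite
  operational range strictly inside the sweep.

## Known limitations

* The confidence surrogate counts model-shape mismatch as misfit: a
  subject whose face differs from the canonical shape by ~1 mm per
  landmark already sits near the default 0.75 threshold at the default
  camera. For benchmarking heterogeneous subjects, lower the threshold
  or raise `residual_scale` and filter by confidence afterwards.
* Distance is biased by the ratio of true to assumed IPD (exactly, in
  the weak-perspective limit).
* Camera intrinsics are assumed known up to the default focal-length
  heuristic (focal = image width); no lens-distortion model.
* The estimator is per-frame; videos with rapid motion gain nothing from
  temporal context here.
* Euler angles degenerate at |pitch| = 90°, far outside the clinical
  range; the gimbal-lock tie-break is documented but such poses are not
  meaningfully comparable.
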