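# Methods

This note documents the models, conventions, numerical choices and
known limitations of `swimkin`.  It is the place to look when a default
looks arbitrary or a property of the pipeline seems too good (or not
good enough) to be true.

## Frames and conventions

* Quaternions are scalar-first `[w, x, y, z]`, Hamilton convention;
  `q` rotates sensor-frame vectors into world-frame vectors.
* The fusion filter works in a world frame with z up; all joint math
  happens in a body-fixed frame with **x down** (along gravity),
  **y forward**, **z right**.  The fixed change of convention is a −90°
  rotation about y.
* Neutral standing = every segment frame coincides with the body frame;
  all joint angles are 0° by construction in that pose.  Flexion is the
  intrinsic Z rotation of the distal relative to the proximal segment,
  positive in the direction the synthetic generator flexes; abduction/
  adduction is the subsequent Y rotation (hip only).  Euler order is
  Z–Y–X with the dominant (sagittal) rotation extracted first, which
  keeps the middle angle small and gimbal-free for breaststroke.

## Attitude estimation (6-axis)

Magnetometers are useless in an indoor pool (reinforced concrete,
pumps), so orientation comes from gyro + accelerometer only and
absolute heading is unobservable.  The estimator is a gradient-descent
complementary filter:

* Gyro propagation uses the exact quaternion exponential
  `q ← q ⊗ exp(dt/2·ω)` rather than a first-order Euler step, so pure
  gyro integration (β = 0) matches the closed-form integration oracle
  to machine precision.
* The gravity correction steps along the tangent-projected, normalized
  objective gradient with step size β·dt.  Two deliberate departures
  from the textbook form:
  1. **Tangent projection.**  The ambient 4-vector gradient of the
     usual quadratic-form objective has a radial component that is a
     parameterization artifact.  Removing it makes the filter *exactly*
     equivariant under constant sensor re-mounting and under world
     heading rotations — the mounting-invariance guarantee of the
     calibration then holds to floating-point precision instead of to
     a few degrees.
  2. **Regularized step.**  A fixed-size normalized-gradient step never
     shrinks, so at convergence the estimate limit-cycles around the
     optimum with amplitude β·dt (over 1° at the static-window gain).
     Below a gradient norm of 0.02 (~0.6° attitude error) the step
     becomes proportional to the gradient, which removes the chatter
     smoothly.
* Gains: β = 2.0 during the static calibration window (fast
  convergence from the accelerometer-only initial attitude), β = 0.05
  during swimming.  The movement gain is deliberately low: the constant
  gyro bias — the dominant drift source — is estimated over the static
  window and subtracted, after which the correction only needs to track
  slow residual drift, and a stronger gain lets propulsion-phase linear
  accelerations leak into the attitude.  Both gains were calibrated on
  the synthetic testbed (that is what it is for) and are exposed in
  `AnalysisOptions`.
* A zero-norm accelerometer sample skips the correction (gyro-only
  update).  An optional accelerometer-magnitude trust band exists but
  is off by default: accelerations perpendicular to gravity barely
  change the magnitude, so the gate rejects the wrong samples.
* Initial attitude: shortest-arc rotation from the mean static
  accelerometer direction to vertical (zero heading); the static window
  must be ≥ 1 s long with gyro RMS < 0.1 rad/s or calibration fails.

## Calibration and its observability limits

Heading is pinned by the right-thigh reference sensor: every sensor's
heading over the static window is rotated to match the reference's.
The sensor-to-segment offset is the inverse of each sensor's mean
static orientation (chordal mean, SVD-projected onto SO(3)), so joint
angles average zero over the window by construction.

What this can and cannot absorb, exactly:

* **Inclination (tilt) mounting offsets** — the body-curvature effect
  the static calibration exists to remove — are absorbed exactly for
  every non-reference sensor (verified to < 0.5°, in practice ~1e-6,
  in the test suite).
* **Strap twist about gravity (mounting yaw)** is mathematically
  indistinguishable from heading in 6-axis tracking; it enters joint
  angles as a conjugation of the relative rotation.  The same applies
  to the reference sensor's own mounting, which *defines* "forward".
  A 10° heading error distorts a 95° knee flexion by ≲ 2°.  The
  synthetic sensor model therefore draws mounting yaw from ±10°
  (careful strapping) and tilt from ±15°, and the 5° validation bound
  below includes this effect.
* Relative yaw drift between sensors (bias residue after static
  debiasing) is uncorrected; trials are ≤ ~90 s, which keeps it small.

Gimbal proximity (middle Euler angle within 1° of ±90°) is flagged and
linearly interpolated over; breaststroke abduction stays far from this.

## Stroke segmentation

Cycle starts are minima of the sagittal knee angle (maximum knee
extension), detected with `scipy.signal.find_peaks` on a zero-lag
4th-order 6 Hz Butterworth-filtered copy: prominence ≥ 10° rejects
tremor minima, spacing ≥ 1 s rejects within-cycle wobbles (stroke rates
are well below 1 Hz).  Cycles are the half-open intervals between
consecutive events (n events → n−1 cycles; boundary partial cycles are
implicitly discarded) and are linearly resampled onto a uniform
100-point grid — linear rather than spline interpolation because it is
monotone and cannot overshoot the sharp propulsion peak.  Fewer than
two qualifying minima raises a "no strokes detected" error, mirroring
the exclusion of swimmers without sufficient knee flexion.

## Parameters

* All per-stroke quantities are means over all strokes; SDs are
  additionally reported for stroke duration, ACC and phase shift.
* Velocity = configured lap length × laps / (last − first detected
  event), not integrated displacement; distance per stroke = velocity ×
  mean stroke duration.  Without lap metadata both report unavailable.
* ACC: per consecutive cyclogram point pair, the frame-to-frame step
  direction θ = atan2(Δy, Δx) per cycle; the mean resultant length of
  those directions across cycles, averaged over the 99 steps.
  Zero-length steps carry no direction and are excluded pointwise.  The
  reported ACC "SD" is the dispersion of the 99 per-point resultant
  lengths — the profile of consistency along the cycle.
* SSD operates on centered cyclograms only (enforced); the healthy
  reference cyclogram is the pointwise mean of the reference cohort's
  mean cyclograms.  Asymmetry SSD is the SSD between mean left and mean
  right cyclograms.
* Phase shift: for each left-leg event, the signed offset to the
  nearest right-leg event as a fraction of the current left stroke
  duration, wrapped to [−50, +50)% (a shift cannot exceed half a cycle
  in either direction); the mean of absolute values is reported, their
  SD is the variability.
* Asymmetry % is computed on RoM: 100·|L − R| / mean(L, R), defined as
  0 when both sides are 0.
* Ankle displacement: the ankle-worn sensor's specific force is rotated
  to the body frame, gravity re-added, and double-integrated per
  propulsion window (peak knee flexion → next maximum extension, the
  leg-extension thrust phase), with a linear velocity de-drift pinning
  v = 0 at both window ends (the ankle is momentarily at rest at both
  extremes).  Windows shorter than 0.2 s are skipped.  Axes: vertical =
  gravity (x), horizontal = swim direction (y), lateral = z.  Double
  integration of consumer-grade accelerometers is the least accurate
  part of the pipeline and is validated only to ±10% on clean synthetic
  motion.

## Statistics and phenotyping

* Kruskal–Wallis uses the tie-corrected H; ε² = H·(n+1)/(n²−1).
  Identical samples short-circuit to H = 0, p = 1.
* Holm–Bonferroni via statsmodels; Mann–Whitney U via scipy with
  rank-biserial r = 1 − 2U/(n_x·n_y); Fisher's exact test uses scipy
  for 2×2 and full enumeration of the margin polytope for 2×k.
* PCA (sklearn) on standardized parameters keeps the smallest number of
  components reaching the target cumulative explained variance
  (default 0.70); constant columns are dropped with a warning.
* k-means (k-means++, n_init = 50, fixed seed) over k = 2…min(8, n−1).
  Elbow = maximal curvature of the WCSS curve anchored at the k = 1
  total sum of squares, ties toward smaller k; silhouette and gap
  curves (B = 50 uniform reference draws over the data's bounding box)
  are reported for override.
* **Selection-aware feature testing.**  k-means clusters are chosen to
  maximize separation, so naively Kruskal–Wallis-testing parameters
  between them is circular and would declare "significant" differences
  in perfectly homogeneous cohorts essentially always.
  `discriminative_features` therefore gates on a parametric bootstrap:
  the observed max-H over the top-5-loading candidate parameters is
  compared with its null distribution from re-running the *entire*
  PCA → k-means → candidate-selection → KW pipeline on standard-normal
  cohorts of the same shape (B = 50).  Only if the gate rejects at α
  are candidates tested (Holm-corrected) and post hoc Mann–Whitney
  comparisons attached.  This controls the family-wise null rate at ≤ α
  (verified empirically over 200 null replicates) while recovering
  planted two-phenotype structure (ARI ≥ 0.9 on 30-subject cohorts).
* An optional rank-based covariate adjustment (age/BMI style) is out of
  scope of the current release; group comparisons are unadjusted.

## The synthetic generator

The generator is first-class, tested code, and the study conditions it
encodes are fixed:

* Joint waveforms are smooth raised-cosine segments on a 100-point
  cycle: knee flexion peaking at 95° mid-cycle (a 92° recovery–
  propulsion bump plus a shallow 3° full-cycle baseline — a real knee
  never holds an exactly constant angle through glide, and the unique
  minimum anchors event detection), hip flexion 40°, hip abduction 18°,
  ankle dorsiflexion 20° followed by 25° plantarflexion.  Stroke
  duration 2 s; default swim speed 0.4 m/s.
* Impairment dials: per-joint, per-leg RoM scaling; right-vs-left phase
  lag in % of cycle; stroke-duration CV; per-cycle amplitude jitter.
  One unjittered "ghost" stroke precedes the first and follows the last
  measured stroke so the bounding maximum-extension events are interior
  minima — a swimmer enters the first measured cycle from a preceding
  stroke, not from a flat glide out of nowhere.
* The chain (pelvis → thigh 0.42 m → shank 0.43 m → foot 0.20 m,
  anthropometric defaults) yields segment orientations; gyro = exact
  body angular velocity (unskewed R ᵀṘ) plus white noise (σ = 0.01
  rad/s) and a per-sensor constant bias (σ = 0.005 rad/s); accel =
  specific force from gravity plus the sensor's linear acceleration
  (second derivative of its chain position) plus white noise (σ = 0.15
  m/s²); mounting offsets per sensor (tilt ≤ 15°, yaw ≤ 10°).  A 5 s
  motionless standing lead-in provides the calibration window.
* Cohort phenotypes ("healthy", "cluster1_like" with a mild distal
  deficit and preserved synchrony, "cluster2_like" with a strong
  ankle/knee deficit plus high phase and duration variability) draw
  subject-level template parameters from fixed between-subject
  distributions; subject parameters are computed by running the
  angle-level analysis on the generated ground-truth kinematics, with
  optional forward-simulated IMU streams.

What the generator does **not** emulate: hydrodynamic drag and thrust
forces, soft-tissue artifact, sensor-strap slippage over time, trunk
and arm motion, or turning at lap ends.  Passing the synthetic
validation therefore demonstrates the correctness of the *algorithms*
under realistic noise, bias and mounting conditions — not the clinical
accuracy of the sensors on human tissue.

## Validation scales and reproducibility

The default validation fixture is 10–12 strokes (~25–30 s at 200 Hz,
eight sensors), which keeps the complete test suite around a minute and
the acceptance script a few seconds while leaving every error source
(drift, noise accumulation, cycle variability) enough time to express
itself.  Headline bounds, all enforced in the test suite:

* noiseless round trip: knee RMSE < 0.5°;
* noisy round trip (default noise, bias, random mounting): knee and hip
  flexion/extension RMSE ≤ 5° — the clinically motivated envelope for
  joint-angle agreement between measurement systems;
* parameter recovery: RoM within ±2°, phase lag within ±1% of cycle,
  stroke-duration CV within ±0.02, velocity within 5%;
* phenotype recovery: ARI ≥ 0.9 on a planted two-cluster cohort; null
  cohorts yield discriminative features at rate ≤ α.

All randomness flows from explicit integer seeds; identical seeds give
byte-identical outputs, including through the CLI.
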