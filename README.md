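# swimkin

Lower-limb breaststroke kinematics from body-worn inertial sensors.

People with incomplete spinal cord injury (and other neurological
conditions) often retain movement abilities in water that are hard to
see on land: buoyancy unloads the joints, and breaststroke kicking on a
kickboard isolates the legs.  `swimkin` turns raw gyroscope +
accelerometer streams from eight waterproof IMUs (left/right thigh,
ankle-worn shank sensor, foot, plus upper and lower back, 200 Hz) into
a quantitative swim profile: joint angles, stroke-cycle timing, range
of motion, intra- and inter-limb coordination, left/right asymmetry,
and a cluster-based phenotyping of movement patterns across a cohort.
It is written for movement scientists and rehabilitation researchers
who want an end-to-end, testable reference pipeline — and it ships with
a synthetic breaststroke generator that provides exact ground truth for
every quantity the pipeline estimates.

## The algorithm

1. **Attitude estimation.** Each sensor's orientation quaternion
   q_ES(t) is estimated by a gradient-descent complementary filter
   (6-axis; no magnetometer — pools are magnetically hostile): the gyro
   is integrated exactly via the quaternion exponential and corrected
   toward the accelerometer gravity direction with gain β (β = 2.0
   during the static calibration window, 0.05 during swimming).  The
   constant gyro bias is estimated over the static window and removed.
2. **Calibration.** All sensors are expressed in a body-fixed frame
   (x down, y forward, z right); headings are pinned to the right-thigh
   reference sensor, and a static standing pose (joints neutral = 0°)
   yields the constant sensor-to-segment offset of each sensor.
3. **Joint angles.** For each joint, the relative rotation
   R_rel(t) = R_prox(t)ᵀ R_dist(t) is decomposed in intrinsic Z–Y–X
   order: the z-angle is flexion/extension (dorsi/plantarflexion at the
   ankle), the y-angle hip abduction/adduction; extended knee = 0°.
4. **Stroke cycles.** Cycle starts are minima of the sagittal knee
   angle (maximum knee extension), detected on a 6 Hz low-pass-filtered
   signal with prominence ≥ 10° and spacing ≥ 1 s; each cycle is
   resampled to exactly 100 points.
5. **Parameters.** Velocity, stroke rate, stroke duration (mean, SD),
   distance per stroke, joint extrema and RoM, ankle displacement
   during propulsion, angle–angle cyclograms (ankle–knee, knee–hip)
   with their SSD shape deviation, the ACC consistency statistic
   (mean resultant length of frame-to-frame cyclogram directions across
   cycles, ∈ [0, 1]), left/right asymmetry, and the inter-limb phase
   shift (% of cycle; 0% = synchronized).  Profiles are z-scored
   against a healthy reference: Z = (x − μ)/σ.
6. **Statistics & phenotyping.** Kruskal–Wallis with ε² effect size and
   Holm–Bonferroni correction, Mann–Whitney U with rank-biserial r,
   Fisher's exact test (2×k); PCA to a target explained variance, then
   k-means with elbow / silhouette / gap-statistic diagnostics and a
   bootstrap-calibrated selection of discriminative parameters.

## Worked example

Simulate a swimmer with a left-leg deficit (knee RoM scaled to 0.8,
ankle to 0.75, 6% inter-leg phase lag), forward-simulate the eight
noisy sensor streams, and run the full pipeline:

```python
from swimkin import (default_template, generate_kinematics,
                     kinematics_to_imu, analyze_trial)

tmpl = default_template(duration_cv=0.06, cycle_jitter=0.04, phase_lag=6.0,
                        rom_scale={("knee", "L"): 0.8, ("ankle", "L"): 0.75})
kin = generate_kinematics(tmpl, n_strokes=12, seed=7)
streams = kinematics_to_imu(kin, seed=8)
res = analyze_trial(streams, kin.static_window, kin.lap_length, kin.n_laps)
for k in ("velocity", "rom_knee_L", "rom_knee_R", "asym_knee",
          "phase_shift_mean", "acc_ankle_knee_L"):
    print(k, round(res.params[k], 3))
```

prints

```
velocity 0.397
rom_knee_L 73.567
rom_knee_R 93.071
asym_knee 23.408
phase_shift_mean 8.562
acc_ankle_knee_L 0.777
```

Reading: the swimmer covers 0.40 m/s; the left knee moves through 73.6°
versus 93.1° on the right (ground truth 73.8°/93.8°), a 23% asymmetry;
the legs are out of phase by ~8.6% of a stroke cycle; and the left
ankle–knee coordination pattern repeats with ACC 0.78 (1 would be
perfectly repeatable).  The injected deficits are recovered within the
documented tolerances despite sensor noise, gyro bias and random
mounting offsets.

The same pipeline is available from the shell:

```sh
swimkin simulate --scenario cluster2_like --seed 3 --out trial/
swimkin angles   --data trial/ --config trial/session.yaml --out angles/
swimkin params   --data trial/ --config trial/session.yaml --out params.json
```

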