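"""End-to-end trial analysis.

Two entry points:

* :func:`analyze_angles` — the angle-level half of the pipeline: stroke
  event detection, cycle normalization and the full swim-parameter set,
  given joint-angle series (from the IMU pipeline or from ground-truth
  kinematics).
* :func:`analyze_trial` — the full sensor pipeline: per-sensor attitude
  fusion, common-frame alignment, sensor-to-segment calibration, joint
  angles, then :func:`analyze_angles` plus ankle displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import params as pm
from .cycles import (NormalizedCycle, StrokeEvent, detect_stroke_events,
                     extract_cycles)
from .fusion import (Placement, QuaternionSeries, SensorStream,
                     fuse_orientation, static_attitude_init)
from .joints import (JOINTS, JointAngleSeries, SegmentFrame,
                     align_common_frame, joint_angles,
                     sensor_to_segment_offset)
from .params import SwimParameterSet

__all__ = ["AnalysisOptions", "TrialResult", "analyze_angles",
           "analyze_trial", "parameters_from_kinematics"]

#: cyclogram pairs: name -> (x joint, y joint), sagittal plane
CYCLOGRAM_PAIRS = {"ankle_knee": ("ankle", "knee"),
                   "knee_hip": ("knee", "hip")}


@dataclass
class AnalysisOptions:
    """Tunable thresholds of the analysis pipeline."""

    min_prominence: float = 10.0    # deg, stroke-event prominence
    min_period: float = 1.0         # s, minimum stroke spacing
    lowpass_cutoff: float = 6.0     # Hz, pre-detection filter
    beta_move: float = 0.05         # fusion gain during movement (rad/s);
                                    # with the gyro bias removed over the
                                    # static window only slow drift needs
                                    # correcting, and a low gain keeps
                                    # propulsion accelerations from
                                    # leaking into the attitude

    beta_static: float = 2.0        # fusion gain during static calibration
    reference: Placement = Placement.THIGH_R
    gyro_rms_threshold: float = 0.1  # rad/s, static-window motion check


@dataclass
class TrialResult:
    params: SwimParameterSet
    angles: dict[tuple[str, str, str], JointAngleSeries]
    events: dict[str, list[StrokeEvent]]
    cycles: dict[tuple[str, str, str], list[NormalizedCycle]]
    frames: dict[Placement, SegmentFrame] = field(default_factory=dict)
    orientations: dict[Placement, QuaternionSeries] = field(default_factory=dict)


def analyze_angles(angles: dict[tuple[str, str, str], JointAngleSeries],
                   lap_length: float | None = None,
                   n_laps: int | None = None,
                   options: AnalysisOptions | None = None,
                   reference_cyclograms: dict | None = None) -> TrialResult:
    """Swim parameters from joint-angle series.

    ``angles`` maps (joint, plane, leg) — e.g. ``("knee", "flex_ext",
    "L")`` — to a :class:`JointAngleSeries`.  Stroke events are detected
    per leg on the sagittal knee angle.  ``reference_cyclograms``, if
    given, maps ``(pair, leg)`` to a centered healthy-reference
    :class:`~swimkin.params.Cyclogram` for the SSD deviation metric.
    """
    opt = options or AnalysisOptions()
    events = {}
    for leg in ("L", "R"):
        events[leg] = detect_stroke_events(
            angles[("knee", "flex_ext", leg)], leg,
            min_prominence=opt.min_prominence, min_period=opt.min_period)

    cycles: dict[tuple[str, str, str], list[NormalizedCycle]] = {}
    for (joint, plane, leg), series in angles.items():
        cycles[(joint, plane, leg)] = extract_cycles(series, events[leg])

    values: dict[str, float | None] = {}
    values.update(pm.temporal_params(events, lap_length, n_laps))
    values.update(pm.phase_shift(events["L"], events["R"]))

    rom = {}
    for joint in ("ankle", "knee", "hip"):
        for leg in ("L", "R"):
            r = pm.range_of_motion(cycles[(joint, "flex_ext", leg)])
            rom[(joint, leg)] = r["rom"]
            values["rom_%s_%s" % (joint, leg)] = r["rom"]
            values["angle_min_%s_%s" % (joint, leg)] = r["angle_min"]
            values["angle_max_%s_%s" % (joint, leg)] = r["angle_max"]
        values["asym_%s" % joint] = pm.asymmetry_pct(rom[(joint, "L")],
                                                     rom[(joint, "R")])

    for pair, (jx, jy) in CYCLOGRAM_PAIRS.items():
        per_leg = {}
        for leg in ("L", "R"):
            cgs = [pm.build_cyclogram(cx, cy, pair)
                   for cx, cy in zip(cycles[(jx, "flex_ext", leg)],
                                     cycles[(jy, "flex_ext", leg)])]
            per_leg[leg] = [pm.center_cyclogram(c) for c in cgs]
            prof = _acc_profile(per_leg[leg])
            values["acc_%s_%s" % (pair, leg)] = float(np.nanmean(prof))
            values["acc_%s_%s_sd" % (pair, leg)] = float(np.nanstd(prof, ddof=1))
            if reference_cyclograms and (pair, leg) in reference_cyclograms:
                values["ssd_%s_%s" % (pair, leg)] = pm.ssd(
                    pm.mean_cyclogram(per_leg[leg]),
                    reference_cyclograms[(pair, leg)])
        values["asym_ssd_%s" % pair] = pm.asymmetry_ssd(per_leg["L"],
                                                        per_leg["R"])

    return TrialResult(SwimParameterSet(values), angles, events, cycles)


def _acc_profile(cyclograms) -> np.ndarray:
    """Per-point mean resultant lengths underlying the ACC (99 values)."""
    pts = np.stack([c.points for c in cyclograms])
    d = np.diff(pts, axis=1)
    nonzero = (d != 0).any(axis=2)
    theta = np.arctan2(d[..., 1], d[..., 0])
    out = np.full(d.shape[1], np.nan)
    for i in range(d.shape[1]):
        m = nonzero[:, i]
        if m.any():
            c = np.cos(theta[m, i]).mean()
            s = np.sin(theta[m, i]).mean()
            out[i] = np.sqrt(c * c + s * s)
    return out


def parameters_from_kinematics(kin, options: AnalysisOptions | None = None
                               ) -> SwimParameterSet:
    """Angle-level pipeline applied to ground-truth kinematics."""
    angles = {}
    for (joint, plane, leg) in kin.angles:
        angles[(joint, plane, leg)] = kin.joint_series(joint, plane, leg)
    res = analyze_angles(angles, kin.lap_length, kin.n_laps, options)
    return res.params


def analyze_trial(streams: dict[Placement, SensorStream],
                  calibration_window: tuple[float, float],
                  lap_length: float | None = None,
                  n_laps: int | None = None,
                  options: AnalysisOptions | None = None,
                  reference_cyclograms: dict | None = None) -> TrialResult:
    """Full pipeline from raw sensor streams to the swim-parameter set.

    Parameters
    ----------
    streams
        One stream per placement; all eight placements are accepted but
        only the lower-limb sensors and the lower back enter the joint
        math.
    calibration_window
        ``(t0, t1)`` of the motionless standing phase, seconds.
    lap_length, n_laps
        Lap metadata; if omitted, velocity and distance per stroke are
        reported as unavailable.
    """
    opt = options or AnalysisOptions()
    t0, t1 = calibration_window

    orientations = {}
    for plc, stream in streams.items():
        static = stream.slice_window(t0, t1)
        q0 = static_attitude_init(static, opt.gyro_rms_threshold)
        # constant gyro bias is observable while motionless; removing it
        # suppresses heading drift, which accel fusion cannot correct
        debiased = SensorStream(stream.placement, stream.t,
                                stream.gyro - static.gyro.mean(axis=0),
                                stream.accel, stream.rate)
        beta = np.where((stream.t >= t0) & (stream.t <= t1),
                        opt.beta_static, opt.beta_move)
        orientations[plc] = fuse_orientation(debiased, beta, q0)

    frames = align_common_frame(orientations, (t0, t1), opt.reference)
    for frame in frames.values():
        frame.offset = sensor_to_segment_offset(frame, (t0, t1))

    angles: dict[tuple[str, str, str], JointAngleSeries] = {}
    for spec in JOINTS.values():
        joint, leg = spec.name.rsplit("_", 1)
        series = joint_angles(frames[spec.proximal], frames[spec.distal], spec)
        for plane, ja in series.items():
            angles[(joint, plane, leg)] = ja

    result = analyze_angles(angles, lap_length, n_laps, opt,
                            reference_cyclograms)
    result.frames = frames
    result.orientations = orientations

    # ankle displacement during propulsion, from the ankle-worn sensor
    for leg in ("L", "R"):
        shank = Placement["SHANK_%s" % leg]
        if shank not in streams:
            continue
        windows = pm.propulsion_windows(result.cycles[("knee", "flex_ext", leg)])
        try:
            disp = pm.ankle_displacement(streams[shank], frames[shank], windows)
        except ValueError:
            continue
        for axis, v in disp.items():
            result.params.values["ankle_disp_%s_%s" % (axis, leg)] = v
    return result
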