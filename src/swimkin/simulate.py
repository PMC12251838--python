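"""Synthetic breaststroke ground-truth generator.

Builds quasi-periodic lower-limb joint-angle trajectories following the
breaststroke phase structure (glide → recovery → propulsion), composes
them along the pelvis → thigh → shank → foot kinematic chain, and
forward-simulates the eight body-worn sensors: gyroscope = exact
segment angular velocity plus noise and a per-sensor constant bias,
accelerometer = gravity expressed in the sensor frame plus the segment's
linear acceleration from the chain geometry, with a constant random
mounting rotation per sensor.  Configurable impairments — reduced joint
range of motion, inter-leg phase lag, stroke-duration variability,
cycle-shape jitter and left/right asymmetry — make it the test bed for
the whole analysis pipeline: every generated stream is accompanied by
the exact true value of each recoverable parameter.

What it does *not* model: hydrodynamic drag forces, soft-tissue
artifact, or trunk motion (the pelvis is held stationary, emulating
swimming on a kickboard).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .cycles import StrokeEvent
from .fusion import GRAVITY, Placement, SensorStream
from .joints import JointAngleSeries

__all__ = [
    "KinematicTemplate",
    "SensorModel",
    "ChainGeometry",
    "Kinematics",
    "default_template",
    "generate_kinematics",
    "kinematics_to_imu",
    "cohort_scenarios",
    "Phenotype",
    "PHENOTYPES",
    "SyntheticSubject",
]

_PHASE_GRID = np.linspace(0.0, 1.0, 100)

#: joint waveform keys: (joint, plane)
_WAVE_KEYS = [("knee", "flex_ext"), ("hip", "flex_ext"),
              ("hip", "abd_add"), ("ankle", "flex_ext")]


def _bump(p0: float, p1: float, peak: float) -> np.ndarray:
    """Raised-cosine bump on the phase grid: 0 outside [p0, p1], smooth
    (zero slope) at both ends, maximum ``peak`` at the midpoint."""
    w = np.zeros_like(_PHASE_GRID)
    m = (_PHASE_GRID >= p0) & (_PHASE_GRID <= p1)
    w[m] = peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * (_PHASE_GRID[m] - p0)
                                      / (p1 - p0)))
    return w


@dataclass
class KinematicTemplate:
    """Per-joint base cycle waveforms and impairment dials.

    ``waveforms`` maps (joint, plane) to a 100-point base shape in
    degrees over one cycle (periodic: first = last value).  ``rom_scale``
    scales each joint's excursion per leg (1 = template amplitude);
    ``phase_lag`` shifts the right leg's cycle starts by a percentage of
    the stroke duration; ``duration_cv`` is the coefficient of variation
    of per-stroke durations; ``cycle_jitter`` is the relative SD of the
    per-cycle amplitude perturbation (within-subject shape noise).
    """

    waveforms: dict[tuple[str, str], np.ndarray]
    stroke_duration: float = 2.0
    rom_scale: dict[tuple[str, str], float] = field(default_factory=dict)
    phase_lag: float = 0.0          # % of cycle, right vs left
    duration_cv: float = 0.0
    cycle_jitter: float = 0.0
    velocity: float = 0.4           # m/s, sets the lap metadata

    def __post_init__(self) -> None:
        if self.stroke_duration <= 0:
            raise ValueError("stroke duration must be positive")
        if not -50.0 <= self.phase_lag <= 50.0:
            raise ValueError("phase lag must lie in [-50, 50] % of cycle")
        if self.duration_cv < 0 or self.cycle_jitter < 0:
            raise ValueError("variability parameters must be nonnegative")
        for key, w in self.waveforms.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (100,):
                raise ValueError("waveform %s must have 100 points" % (key,))
            if not np.isclose(w[0], w[-1]):
                raise ValueError("waveform %s is not periodic" % (key,))
            self.waveforms[key] = w
        for v in self.rom_scale.values():
            if v < 0:
                raise ValueError("rom_scale must be nonnegative")

    def scale(self, joint: str, leg: str) -> float:
        return self.rom_scale.get((joint, leg), 1.0)

    def base_rom(self, joint: str, plane: str = "flex_ext") -> float:
        w = self.waveforms[(joint, plane)]
        return float(w.max() - w.min())


def default_template(**overrides) -> KinematicTemplate:
    """Healthy breaststroke template.

    Knee flexion peaks at 95° mid-cycle; the hip flexes to ~40° and
    abducts ~18° during recovery; the ankle dorsiflexes ~20° while the
    legs are drawn in, then plantarflexes ~25° through propulsion.
    Glide occupies the first ~quarter of the cycle (angles near 0, legs
    extended).  The knee carries a shallow 3° full-cycle baseline on top
    of the recovery–propulsion bump: a real knee never holds an exactly
    constant angle through glide, and the unique minimum at 0% cycle is
    what anchors stroke-event detection.
    """
    baseline = 3.0 * 0.5 * (1.0 - np.cos(2.0 * np.pi * _PHASE_GRID))
    waves = {
        ("knee", "flex_ext"): _bump(0.25, 0.75, 92.0) + baseline,
        ("hip", "flex_ext"): _bump(0.25, 0.80, 40.0),
        ("hip", "abd_add"): _bump(0.35, 0.85, 18.0),
        ("ankle", "flex_ext"): _bump(0.25, 0.60, 20.0) - _bump(0.55, 0.90, 25.0),
    }
    return KinematicTemplate(waveforms=waves, **overrides)


@dataclass
class SensorModel:
    """Noise, bias, rate and mounting model of the simulated IMUs."""

    gyro_noise_sd: float = 0.01     # rad/s
    accel_noise_sd: float = 0.15    # m/s^2
    gyro_bias_sd: float = 0.005     # rad/s, constant per sensor
    rate: float = 200.0             # Hz
    mounting_tilt_max: float = 15.0  # deg, inclination from body curvature
    mounting_yaw_max: float = 10.0   # deg, strap twist about the segment axis

    def __post_init__(self) -> None:
        if min(self.gyro_noise_sd, self.accel_noise_sd, self.gyro_bias_sd) < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class ChainGeometry:
    """Segment lengths (m) and sensor positions along the chain."""

    thigh: float = 0.42
    shank: float = 0.43
    foot: float = 0.20
    hip_half_width: float = 0.09
    thigh_sensor_frac: float = 0.67   # fraction of thigh length below the hip
    shank_sensor_frac: float = 0.90   # ankle-worn sensor, just above malleolus
    surface_offset: float = 0.04      # sensor stand-off from the bone axis


@dataclass
class Kinematics:
    """Ground-truth joint-angle trajectories of one synthetic trial."""

    t: np.ndarray
    angles: dict[tuple[str, str, str], np.ndarray]  # (joint, plane, leg) -> deg
    events: dict[str, np.ndarray]                   # leg -> event times (s)
    template: KinematicTemplate
    truth: dict
    rate: float
    static_window: tuple[float, float]
    lap_length: float
    n_laps: int

    def joint_series(self, joint: str, plane: str, leg: str) -> JointAngleSeries:
        return JointAngleSeries("%s_%s" % (joint, leg), plane, self.t,
                                self.angles[(joint, plane, leg)])

    def stroke_events(self, leg: str) -> list[StrokeEvent]:
        idx = np.searchsorted(self.t, self.events[leg])
        return [StrokeEvent(float(self.t[i]), int(i), leg) for i in idx]


def generate_kinematics(template: KinematicTemplate, n_strokes: int,
                        seed: int, rate: float = 200.0,
                        static_lead: float = 5.0) -> Kinematics:
    """Generate a synthetic trial: a static standing lead-in (for
    calibration) followed by ``n_strokes`` breaststroke cycles.

    Per-stroke durations are drawn with the template's CV; the right
    leg's cycle starts are shifted by the injected phase lag; per cycle,
    per leg and per joint, the amplitude is perturbed by the cycle
    jitter.  The returned ``truth`` dict records the exact values of
    every recoverable parameter.
    """
    if n_strokes < 2:
        raise ValueError("need at least 2 strokes")
    rng = np.random.default_rng(seed)
    d0 = template.stroke_duration
    durations = d0 * (1.0 + template.duration_cv * rng.standard_normal(n_strokes))
    durations = np.clip(durations, 0.4 * d0, 2.0 * d0)

    # one unjittered "ghost" stroke precedes the first measured event and
    # one follows the last, so the bounding maximum-extension minima are
    # interior and detectable (a swimmer enters the first measured cycle
    # from a preceding stroke, not from rest)
    first = static_lead + 1.0 + d0
    ev_L = first + np.concatenate([[0.0], np.cumsum(durations)])
    lag_frac = template.phase_lag / 100.0
    ev_R = ev_L + lag_frac * np.concatenate([durations, durations[-1:]])

    T = max(ev_L[-1], ev_R[-1]) + d0 + 0.5
    t = np.arange(0.0, T, 1.0 / rate)

    jitter = {}
    for leg in ("L", "R"):
        for joint, plane in _WAVE_KEYS:
            jitter[(joint, plane, leg)] = np.clip(
                1.0 + template.cycle_jitter * rng.standard_normal(n_strokes),
                0.1, None)

    angles = {}
    rom_truth = {}
    for leg, ev in (("L", ev_L), ("R", ev_R)):
        ev_full = np.concatenate([[ev[0] - d0], ev, [ev[-1] + d0]])
        for joint, plane in _WAVE_KEYS:
            wave = template.waveforms[(joint, plane)]
            scale = template.scale(joint, leg)
            amps = np.concatenate([[scale], scale * jitter[(joint, plane, leg)],
                                   [scale]])
            y = np.zeros_like(t)
            per_cycle_rom = []
            for k in range(len(ev_full) - 1):
                m = (t >= ev_full[k]) & (t < ev_full[k + 1])
                phase = (t[m] - ev_full[k]) / (ev_full[k + 1] - ev_full[k])
                y[m] = amps[k] * np.interp(phase, _PHASE_GRID, wave)
                if 1 <= k <= n_strokes:   # measured strokes only
                    per_cycle_rom.append(amps[k] * (wave.max() - wave.min()))
            angles[(joint, plane, leg)] = y
            rom_truth[(joint, plane, leg)] = float(np.mean(per_cycle_rom))

    active = float(ev_L[-1] - ev_L[0])
    lap_length = template.velocity * active
    truth = {
        "durations": durations,
        "stroke_duration_mean": float(durations.mean()),
        "stroke_duration_sd": float(durations.std(ddof=1)),
        "duration_cv": float(durations.std(ddof=1) / durations.mean()),
        "phase_lag": template.phase_lag,
        "velocity": template.velocity,
        "distance_per_stroke": template.velocity * float(durations.mean()),
        "rom": {("%s_%s" % (j, leg), plane): v
                for (j, plane, leg), v in rom_truth.items()},
    }
    return Kinematics(t, angles, {"L": ev_L, "R": ev_R}, template, truth,
                      rate, (0.5, static_lead - 0.5), lap_length, 1)


# ---------------------------------------------------------------------------
# forward IMU simulation
# ---------------------------------------------------------------------------

def _angular_velocity_body(R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Body-frame angular velocity from a rotation series: unskew(R^T Ṙ)."""
    Rdot = np.gradient(R, t, axis=0)
    S = np.einsum("nji,njk->nik", R, Rdot)
    return np.stack([(S[:, 2, 1] - S[:, 1, 2]) / 2,
                     (S[:, 0, 2] - S[:, 2, 0]) / 2,
                     (S[:, 1, 0] - S[:, 0, 1]) / 2], axis=1)


def _mounting(rng: np.random.Generator, model: SensorModel) -> np.ndarray:
    tilt = model.mounting_tilt_max
    yaw = model.mounting_yaw_max
    return Rotation.from_euler(
        "XYZ",
        [rng.uniform(-yaw, yaw), rng.uniform(-tilt, tilt),
         rng.uniform(-tilt, tilt)], degrees=True).as_matrix()


def kinematics_to_imu(kin: Kinematics, geometry: ChainGeometry | None = None,
                      sensor_model: SensorModel | None = None,
                      seed: int = 0,
                      mounting_overrides: dict[Placement, np.ndarray] | None = None,
                      ) -> dict[Placement, SensorStream]:
    """Forward-simulate the eight sensor streams from a kinematic trial.

    Segment orientations are composed along the pelvis → thigh → shank →
    foot chain in the body-fixed frame (x down, y forward, z right;
    neutral standing = identity); sensor linear acceleration follows
    from the chain geometry by differentiating the sensor positions.
    """
    geom = geometry or ChainGeometry()
    model = sensor_model or SensorModel()
    if not np.isclose(model.rate, kin.rate):
        raise ValueError("sensor model rate must match the kinematics rate")
    rng = np.random.default_rng(seed)
    t = kin.t
    n = t.size
    deg = np.pi / 180.0

    eye = np.broadcast_to(np.eye(3), (n, 3, 3))
    g_vec = np.array([GRAVITY, 0.0, 0.0])  # gravity acceleration, x down

    def euler_zy(z_deg: np.ndarray, y_deg: np.ndarray) -> np.ndarray:
        return Rotation.from_euler(
            "ZYX", np.column_stack([z_deg, y_deg, np.zeros_like(z_deg)]),
            degrees=True).as_matrix()

    streams: dict[Placement, SensorStream] = {}

    overrides = mounting_overrides or {}

    def emit(placement: Placement, R_seg: np.ndarray, pos: np.ndarray) -> None:
        M = _mounting(rng, model)
        if placement in overrides:
            M = np.asarray(overrides[placement], dtype=float)
        R_ps = R_seg @ M
        omega_seg = _angular_velocity_body(np.ascontiguousarray(R_seg), t)
        omega = omega_seg @ M            # M^T applied row-wise
        a_lin = np.gradient(np.gradient(pos, t, axis=0), t, axis=0)
        f_world = a_lin - g_vec
        f_sensor = np.einsum("nji,nj->ni", R_ps, f_world)
        bias = model.gyro_bias_sd * rng.standard_normal(3)
        gyro = omega + bias + model.gyro_noise_sd * rng.standard_normal((n, 3))
        accel = f_sensor + model.accel_noise_sd * rng.standard_normal((n, 3))
        streams[placement] = SensorStream(placement, t, gyro, accel, model.rate)

    pelvis_R = np.ascontiguousarray(eye)
    origin = np.zeros((n, 3))

    emit(Placement.BACK_LOWER, pelvis_R, origin + np.array([0.0, -0.08, 0.0]))
    emit(Placement.BACK_UPPER, pelvis_R, origin + np.array([-0.45, -0.08, 0.0]))

    for leg, sign in (("L", -1.0), ("R", 1.0)):
        hip_flex = kin.angles[("hip", "flex_ext", leg)]
        hip_abd = kin.angles[("hip", "abd_add", leg)]
        knee_flex = kin.angles[("knee", "flex_ext", leg)]
        ankle_flex = kin.angles[("ankle", "flex_ext", leg)]

        R_thigh = pelvis_R @ euler_zy(hip_flex, hip_abd)
        R_shank = R_thigh @ euler_zy(knee_flex, np.zeros(n))
        R_foot = R_shank @ euler_zy(ankle_flex, np.zeros(n))

        hip_pos = origin + np.array([0.05, 0.0, sign * geom.hip_half_width])
        knee_pos = hip_pos + np.einsum(
            "nij,j->ni", R_thigh, np.array([geom.thigh, 0.0, 0.0]))
        ankle_pos = knee_pos + np.einsum(
            "nij,j->ni", R_shank, np.array([geom.shank, 0.0, 0.0]))

        thigh_sensor = hip_pos + np.einsum(
            "nij,j->ni", R_thigh,
            np.array([geom.thigh_sensor_frac * geom.thigh,
                      geom.surface_offset, 0.0]))
        shank_sensor = knee_pos + np.einsum(
            "nij,j->ni", R_shank,
            np.array([geom.shank_sensor_frac * geom.shank,
                      geom.surface_offset, 0.0]))
        foot_sensor = ankle_pos + np.einsum(
            "nij,j->ni", R_foot,
            np.array([0.03, 0.5 * geom.foot, 0.0]))

        emit(Placement["THIGH_%s" % leg], R_thigh, thigh_sensor)
        emit(Placement["SHANK_%s" % leg], R_shank, shank_sensor)
        emit(Placement["FOOT_%s" % leg], R_foot, foot_sensor)

    return streams


# ---------------------------------------------------------------------------
# cohort scenarios
# ---------------------------------------------------------------------------

@dataclass
class Phenotype:
    """Between-subject distribution of template parameters for one group.

    Each field is a (mean, sd) pair; subject-level values are drawn
    once per subject.  ``rom_knee``/``rom_ankle``/``rom_hip`` are
    multiplicative range-of-motion scales; ``rom_asym_sd`` adds an
    independent left/right perturbation creating inter-leg asymmetry.
    """

    velocity: tuple[float, float] = (0.50, 0.06)
    stroke_duration: tuple[float, float] = (2.0, 0.2)
    duration_cv: tuple[float, float] = (0.04, 0.01)
    phase_lag: tuple[float, float] = (0.0, 1.5)
    cycle_jitter: tuple[float, float] = (0.04, 0.01)
    rom_knee: tuple[float, float] = (1.0, 0.05)
    rom_ankle: tuple[float, float] = (1.0, 0.05)
    rom_hip: tuple[float, float] = (1.0, 0.05)
    rom_asym_sd: float = 0.02


#: Named cohort phenotypes.  "healthy" has full range of motion and tight
#: timing; "cluster1_like" has a mild knee/ankle deficit with preserved
#: synchrony; "cluster2_like" has a strong distal deficit plus high
#: phase-shift and stroke-duration variability.
PHENOTYPES: dict[str, Phenotype] = {
    "healthy": Phenotype(),
    "healthy_comfort": Phenotype(velocity=(0.39, 0.05),
                                 stroke_duration=(2.4, 0.25)),
    "cluster1_like": Phenotype(
        velocity=(0.35, 0.05), stroke_duration=(2.2, 0.2),
        duration_cv=(0.06, 0.015), phase_lag=(2.0, 1.0),
        cycle_jitter=(0.06, 0.015),
        rom_knee=(0.85, 0.05), rom_ankle=(0.80, 0.06), rom_hip=(0.95, 0.05),
        rom_asym_sd=0.04),
    "cluster2_like": Phenotype(
        velocity=(0.18, 0.04), stroke_duration=(2.6, 0.3),
        duration_cv=(0.15, 0.03), phase_lag=(8.0, 2.5),
        cycle_jitter=(0.14, 0.03),
        rom_knee=(0.62, 0.06), rom_ankle=(0.50, 0.07), rom_hip=(0.88, 0.06),
        rom_asym_sd=0.08),
}


@dataclass
class SyntheticSubject:
    subject_id: str
    phenotype: str
    template: KinematicTemplate
    kinematics: Kinematics
    params: "object"       # SwimParameterSet (filled by cohort_scenarios)
    streams: dict | None = None


def _draw(rng: np.random.Generator, pair: tuple[float, float],
          lo: float | None = None) -> float:
    v = rng.normal(pair[0], pair[1])
    return float(max(v, lo) if lo is not None else v)


def subject_template(phenotype: Phenotype,
                     rng: np.random.Generator) -> KinematicTemplate:
    """Draw one subject's template from a phenotype distribution."""
    rom_scale = {}
    for joint, pair in (("knee", phenotype.rom_knee),
                        ("ankle", phenotype.rom_ankle),
                        ("hip", phenotype.rom_hip)):
        base = _draw(rng, pair, lo=0.1)
        for leg in ("L", "R"):
            rom_scale[(joint, leg)] = max(
                base + phenotype.rom_asym_sd * rng.standard_normal(), 0.1)
    return default_template(
        stroke_duration=_draw(rng, phenotype.stroke_duration, lo=0.8),
        duration_cv=_draw(rng, phenotype.duration_cv, lo=0.0),
        phase_lag=float(np.clip(abs(rng.normal(*phenotype.phase_lag)), 0, 45)),
        cycle_jitter=_draw(rng, phenotype.cycle_jitter, lo=0.0),
        velocity=_draw(rng, phenotype.velocity, lo=0.05),
        rom_scale=rom_scale,
    )


def cohort_scenarios(spec: dict[str, int], seed: int, n_strokes: int = 12,
                     include_imu: bool = False,
                     ) -> list[SyntheticSubject]:
    """Generate a cohort of synthetic subjects.

    ``spec`` maps phenotype names (keys of :data:`PHENOTYPES`) to subject
    counts.  Each subject's swim parameters are computed by running the
    angle-level analysis pipeline on the generated ground-truth
    kinematics; set ``include_imu`` to also attach forward-simulated
    sensor streams.  Fully reproducible from (spec, seed).
    """
    from .pipeline import parameters_from_kinematics

    rng = np.random.default_rng(seed)
    subjects = []
    for name, count in spec.items():
        phen = PHENOTYPES[name]
        for i in range(count):
            tmpl = subject_template(phen, rng)
            kin = generate_kinematics(tmpl, n_strokes,
                                      seed=int(rng.integers(2 ** 31)))
            params = parameters_from_kinematics(kin)
            streams = None
            if include_imu:
                streams = kinematics_to_imu(kin, seed=int(rng.integers(2 ** 31)))
            subjects.append(SyntheticSubject(
                "%s_%02d" % (name, i), name, tmpl, kin, params, streams))
    return subjects
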