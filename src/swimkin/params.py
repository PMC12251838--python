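"""Spatiotemporal and coordination swimming parameters.

Implements the full per-trial parameter set: velocity, stroke rate,
stroke duration (mean, SD), distance per stroke, joint-angle extrema and
range of motion, ankle displacement during propulsion, cyclogram shape
deviation (SSD), cyclogram consistency (ACC), left/right asymmetry,
inter-limb phase shift, and z-scored swim profiles against a healthy
reference.  All per-stroke quantities are reported as the mean over all
strokes; variability (SD) is additionally reported for stroke duration,
ACC and phase shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .cycles import CYCLE_POINTS, NormalizedCycle, StrokeEvent
from .fusion import GRAVITY, SensorStream
from .joints import SegmentFrame

__all__ = [
    "Cyclogram",
    "SwimParameterSet",
    "SwimProfile",
    "temporal_params",
    "range_of_motion",
    "ankle_displacement",
    "build_cyclogram",
    "center_cyclogram",
    "mean_cyclogram",
    "ssd",
    "asymmetry_ssd",
    "acc",
    "phase_shift",
    "asymmetry_pct",
    "zscore_profile",
]

#: Gravity direction in the body-fixed frame (x points down).
_G_BODY = np.array([GRAVITY, 0.0, 0.0])


# ---------------------------------------------------------------------------
# temporal parameters
# ---------------------------------------------------------------------------

def temporal_params(events: dict[str, list[StrokeEvent]],
                    lap_length: float | None = None,
                    n_laps: int | None = None) -> dict:
    """Velocity, stroke rate, stroke duration and distance per stroke.

    Stroke durations are the gaps between consecutive cycle-start events,
    pooled over both legs.  Velocity is total distance divided by active
    swim time (first to last event across legs); it requires lap
    metadata (``lap_length`` in metres and ``n_laps``) and is reported
    as None when that is missing — the temporal parameters are still
    computed.  Distance per stroke is velocity × mean stroke duration.
    """
    durations = []
    all_times = []
    for evs in events.values():
        ts = np.array([e.t for e in evs])
        all_times.append(ts)
        if ts.size >= 2:
            durations.append(np.diff(ts))
    if not durations:
        raise ValueError("need at least 2 events on at least one leg")
    durations = np.concatenate(durations)
    all_times = np.concatenate(all_times)
    mean_dur = float(durations.mean())
    out = {
        "stroke_duration_mean": mean_dur,
        "stroke_duration_sd": float(durations.std(ddof=1)) if durations.size > 1 else 0.0,
        "stroke_rate": 60.0 / mean_dur,
        "velocity": None,
        "distance_per_stroke": None,
    }
    if lap_length is not None and n_laps is not None:
        if lap_length <= 0:
            raise ValueError("lap_length must be positive")
        active = float(all_times.max() - all_times.min())
        if active > 0:
            v = lap_length * n_laps / active
            out["velocity"] = v
            out["distance_per_stroke"] = v * mean_dur
    return out


def range_of_motion(cycles: list[NormalizedCycle]) -> dict:
    """Per-cycle max−min averaged over cycles, plus mean extrema."""
    if not cycles:
        raise ValueError("need at least one cycle")
    pts = np.stack([c.points for c in cycles])
    mins = pts.min(axis=1)
    maxs = pts.max(axis=1)
    return {
        "rom": float((maxs - mins).mean()),
        "angle_min": float(mins.mean()),
        "angle_max": float(maxs.mean()),
    }


# ---------------------------------------------------------------------------
# ankle displacement during propulsion
# ---------------------------------------------------------------------------

def ankle_displacement(stream: SensorStream, frame: SegmentFrame,
                       windows: list[tuple[float, float]],
                       min_window: float = 0.2) -> dict:
    """Peak-to-peak ankle displacement per body-frame axis during the
    propulsion phase, averaged over strokes.

    The ankle sensor's specific force is rotated to the body-fixed frame
    with the calibrated orientation, gravity is added back to recover
    linear acceleration, and each propulsion window (peak knee flexion →
    next maximum knee extension) is double-integrated independently.
    Integration drift is removed per window by constraining the linear
    velocity to zero at both window ends (the ankle is momentarily at
    rest relative to the water at maximum extension and peak flexion).

    Returns mean peak-to-peak displacement in metres: ``vertical`` is
    the gravity (x) axis, ``horizontal`` the swim direction (y), and
    ``lateral`` the z axis.  Windows shorter than ``min_window`` seconds
    are skipped.
    """
    R = frame.segment_rotations()
    # linear acceleration in the body frame: a = R f + g
    a_world = np.einsum("nij,nj->ni", R, stream.accel) + _G_BODY
    disp = []
    for t0, t1 in windows:
        if t1 - t0 < min_window:
            continue
        m = (stream.t >= t0) & (stream.t <= t1)
        if m.sum() < 4:
            continue
        t = stream.t[m]
        a = a_world[m]
        v = cumulative_trapezoid(a, t, axis=0, initial=0.0)
        # linear de-drift so v(start) = v(end) = 0
        frac = ((t - t[0]) / (t[-1] - t[0]))[:, None]
        v = v - frac * v[-1]
        p = cumulative_trapezoid(v, t, axis=0, initial=0.0)
        disp.append(p.max(axis=0) - p.min(axis=0))
    if not disp:
        raise ValueError("no usable propulsion windows")
    d = np.stack(disp).mean(axis=0)
    return {"vertical": float(d[0]), "horizontal": float(d[1]),
            "lateral": float(d[2])}


def propulsion_windows(knee_cycles: list[NormalizedCycle]) -> list[tuple[float, float]]:
    """Propulsion phase of each stroke: from peak knee flexion to the
    next maximum knee extension (cycle end)."""
    out = []
    for c in knee_cycles:
        i_peak = int(np.argmax(c.points))
        t_peak = c.t_start + (i_peak / (CYCLE_POINTS - 1)) * c.duration
        out.append((t_peak, c.t_end))
    return out


# ---------------------------------------------------------------------------
# cyclograms and coordination metrics
# ---------------------------------------------------------------------------

@dataclass
class Cyclogram:
    """Angle–angle trajectory of one cycle (e.g. ankle–knee), 100 points."""

    pair: str          # "ankle_knee" or "knee_hip"
    leg: str
    points: np.ndarray  # (100, 2) degrees
    centered: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (CYCLE_POINTS, 2):
            raise ValueError("cyclogram must have shape (%d, 2)" % CYCLE_POINTS)
        if self.centered and not np.allclose(self.points.mean(axis=0), 0,
                                             atol=1e-9):
            raise ValueError("cyclogram marked centered but centroid != 0")


def build_cyclogram(cycle_x: NormalizedCycle, cycle_y: NormalizedCycle,
                    pair: str) -> Cyclogram:
    """Pair two normalized cycles of the same leg and stroke into an
    angle–angle trajectory."""
    if cycle_x.leg != cycle_y.leg:
        raise ValueError("cyclogram legs do not match")
    if not (np.isclose(cycle_x.t_start, cycle_y.t_start)
            and np.isclose(cycle_x.t_end, cycle_y.t_end)):
        raise ValueError("cyclogram cycle grids do not match")
    return Cyclogram(pair, cycle_x.leg,
                     np.column_stack([cycle_x.points, cycle_y.points]))


def center_cyclogram(c: Cyclogram) -> Cyclogram:
    """Subtract the centroid; idempotent."""
    pts = c.points - c.points.mean(axis=0)
    return Cyclogram(c.pair, c.leg, pts, centered=True)


def mean_cyclogram(cyclograms: list[Cyclogram]) -> Cyclogram:
    """Pointwise mean of centered cyclograms (re-centered)."""
    if not cyclograms:
        raise ValueError("empty cyclogram set")
    cs = [center_cyclogram(c) if not c.centered else c for c in cyclograms]
    pts = np.stack([c.points for c in cs]).mean(axis=0)
    pts -= pts.mean(axis=0)
    return Cyclogram(cs[0].pair, cs[0].leg, pts, centered=True)


def ssd(c1: Cyclogram, c2: Cyclogram) -> float:
    """Sum of squared distances between two centered cyclograms (deg²).

    Symmetric, nonnegative, zero iff the shapes are identical."""
    if not (c1.centered and c2.centered):
        raise ValueError("SSD requires centered cyclograms")
    d = c1.points - c2.points
    return float(np.sum(d * d))


def asymmetry_ssd(left: list[Cyclogram], right: list[Cyclogram]) -> float:
    """SSD between the mean left-leg and mean right-leg cyclograms."""
    return ssd(mean_cyclogram(left), mean_cyclogram(right))


def acc(cyclograms: list[Cyclogram]) -> float:
    """Angular component of the coefficient of correspondence.

    Vector-coding circular statistic of cyclogram consistency across
    cycles: for each of the 99 consecutive point pairs, the direction of
    the frame-to-frame step ``θ = atan2(Δy, Δx)`` is computed per cycle;
    the mean resultant length of those directions across cycles,

        a_i = sqrt( mean(cos θ)² + mean(sin θ)² ),

    measures their agreement, and the ACC is the average of ``a_i`` over
    the 99 steps.  1 means an identical stepping pattern in every cycle;
    uniformly random directions drive it toward 0.  Zero-length steps
    carry no direction and are excluded at that point index.
    """
    if len(cyclograms) < 2:
        raise ValueError("ACC requires at least 2 cycles")
    pts = np.stack([c.points for c in cyclograms])   # (n_cycles, 100, 2)
    d = np.diff(pts, axis=1)                          # (n_cycles, 99, 2)
    nonzero = (d != 0).any(axis=2)                    # (n_cycles, 99)
    theta = np.arctan2(d[..., 1], d[..., 0])
    a = np.empty(d.shape[1])
    for i in range(d.shape[1]):
        m = nonzero[:, i]
        if not m.any():
            a[i] = np.nan
            continue
        c = np.cos(theta[m, i]).mean()
        s = np.sin(theta[m, i]).mean()
        a[i] = np.sqrt(c * c + s * s)
    val = float(np.nanmean(a))
    return min(max(val, 0.0), 1.0)


# ---------------------------------------------------------------------------
# inter-limb and left/right comparisons
# ---------------------------------------------------------------------------

def phase_shift(events_L: list[StrokeEvent],
                events_R: list[StrokeEvent]) -> dict:
    """Inter-limb phase shift: timing offset of the right leg's cycle
    starts relative to the left leg's, as a percentage of stroke
    duration.

    For every left event with a defined stroke duration, the signed
    offset to the nearest right event is divided by the current left
    stroke duration, expressed in percent and wrapped to [−50, +50).
    The mean of absolute values is the phase shift (0% = perfect
    synchronization); their SD across strokes is its variability.
    """
    if len(events_L) < 2 or len(events_R) < 2:
        raise ValueError("need at least 2 events per leg")
    tL = np.array([e.t for e in events_L])
    tR = np.array([e.t for e in events_R])
    if tR.max() < tL.min() or tL.max() < tR.min():
        raise ValueError("left and right event series do not overlap in time")
    shifts = []
    for k in range(len(tL) - 1):
        dur = tL[k + 1] - tL[k]
        delta = tR[np.argmin(np.abs(tR - tL[k]))] - tL[k]
        frac = 100.0 * delta / dur
        frac = ((frac + 50.0) % 100.0) - 50.0
        shifts.append(abs(frac))
    shifts = np.array(shifts)
    return {
        "phase_shift_mean": float(shifts.mean()),
        "phase_shift_sd": float(shifts.std(ddof=1)) if shifts.size > 1 else 0.0,
    }


def asymmetry_pct(rom_L: float, rom_R: float) -> float:
    """Percentage left/right difference, normalized by the mean of the
    two sides; 0 when both sides are zero.  Symmetric under leg swap."""
    if rom_L < 0 or rom_R < 0:
        raise ValueError("range of motion cannot be negative")
    denom = 0.5 * (rom_L + rom_R)
    if denom == 0:
        return 0.0
    return 100.0 * abs(rom_L - rom_R) / denom


# ---------------------------------------------------------------------------
# parameter container and z-scored profiles
# ---------------------------------------------------------------------------

@dataclass
class SwimParameterSet:
    """Flat named parameter values for one trial.

    Keys follow the pattern ``rom_knee_L``, ``acc_ankle_knee_L_mean``,
    ``phase_shift_mean`` etc.; ``values()`` returns the plain dict.
    """

    values: dict[str, float | None] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float | None:
        return self.values[key]

    def as_vector(self, names: list[str]) -> np.ndarray:
        missing = [n for n in names if self.values.get(n) is None]
        if missing:
            raise KeyError("parameters unavailable: %s" % ", ".join(missing))
        return np.array([self.values[n] for n in names], dtype=float)


@dataclass
class SwimProfile:
    """Z-scored parameter vector against a healthy reference."""

    z: dict[str, float]
    mu: dict[str, float]
    sigma: dict[str, float]


def zscore_profile(params: SwimParameterSet | dict,
                   mu: dict[str, float],
                   sigma: dict[str, float]) -> SwimProfile:
    """Standardize parameters by the healthy reference: Z = (x − μ)/σ.

    A value equal to the healthy mean maps to 0; the magnitude of Z is
    the number of healthy SDs from that mean.  Raises if any reference
    SD is nonpositive, naming the parameter.
    """
    vals = params.values if isinstance(params, SwimParameterSet) else params
    z = {}
    for name, mu_k in mu.items():
        sd = sigma[name]
        if sd <= 0:
            raise ValueError("reference SD is not positive for parameter %r"
                             % name)
        x = vals.get(name)
        if x is None:
            continue
        z[name] = (x - mu_k) / sd
    return SwimProfile(z, dict(mu), dict(sigma))


def reference_stats(cohort: list[SwimParameterSet | dict],
                    names: list[str]) -> tuple[dict, dict]:
    """Healthy-reference mean and SD per parameter from a cohort."""
    mu, sigma = {}, {}
    for n in names:
        xs = []
        for p in cohort:
            vals = p.values if isinstance(p, SwimParameterSet) else p
            if vals.get(n) is not None:
                xs.append(vals[n])
        xs = np.asarray(xs, dtype=float)
        if xs.size < 2:
            raise ValueError("reference cohort has < 2 values for %r" % n)
        mu[n] = float(xs.mean())
        sigma[n] = float(xs.std(ddof=1))
    return mu, sigma
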