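"""Quaternion algebra and gravity-referenced attitude estimation.

Orientation of each body-worn sensor is estimated from its tri-axial
gyroscope and accelerometer only (6-axis fusion).  Magnetometer data are
deliberately not used: in an indoor pool the magnetic field is heavily
distorted by building steel and pump machinery, so heading is observable
only *relatively* (see :mod:`swimkin.joints` for how a reference sensor
pins the shared heading).

The estimator is a gradient-descent complementary filter: the gyroscope
is integrated through the quaternion kinematic equation and, at every
step, the estimate is nudged toward the orientation whose predicted
gravity direction matches the (normalized) accelerometer reading.  The
step size ``beta`` (rad/s) trades gyro trust against accelerometer
trust; ``beta = 0`` reduces the filter to pure gyro integration.

Conventions
-----------
* Quaternions are scalar-first ``[w, x, y, z]``, Hamilton convention.
* The filter's world frame ``W`` has its z-axis up (opposite gravity);
  heading (rotation about world z) is arbitrary per sensor and is fixed
  later during frame alignment.
* A quaternion ``q`` in a :class:`QuaternionSeries` rotates sensor-frame
  vectors into world-frame vectors: ``v_W = R(q) @ v_S``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "GRAVITY",
    "Placement",
    "SensorStream",
    "QuaternionSeries",
    "CalibrationError",
    "quat_multiply",
    "quat_conjugate",
    "quat_normalize",
    "quat_to_rotmat",
    "quat_from_axis_angle",
    "fuse_orientation",
    "static_attitude_init",
]

#: Standard gravity used throughout (m/s^2).
GRAVITY = 9.81

#: Gradient norm below which the correction step becomes proportional
#: instead of fixed-size (~0.6° residual attitude error).
_GRAD_FLOOR = 0.02


class Placement(str, Enum):
    """The eight sensor attachment sites."""

    THIGH_L = "thigh_L"
    THIGH_R = "thigh_R"
    SHANK_L = "shank_L"
    SHANK_R = "shank_R"
    FOOT_L = "foot_L"
    FOOT_R = "foot_R"
    BACK_UPPER = "back_upper"
    BACK_LOWER = "back_lower"


class CalibrationError(ValueError):
    """Raised when a static calibration window is unusable."""


@dataclass
class SensorStream:
    """Synchronized gyro/accel samples from one attachment site.

    Parameters
    ----------
    placement
        Attachment site of the sensor.
    t
        Sample times in seconds, strictly increasing.
    gyro
        Angular velocity in the sensor frame, rad/s, shape (n, 3).
    accel
        Specific force in the sensor frame, m/s^2, shape (n, 3).
        A motionless sensor reads ``+g`` along the world up direction.
    rate
        Nominal sampling rate in Hz (default 200).
    """

    placement: Placement
    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    rate: float = 200.0

    def __post_init__(self) -> None:
        self.placement = Placement(self.placement)
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.t.shape[0]
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise ValueError("gyro and accel must have shape (n, 3) matching t")
        if not (np.isfinite(self.t).all() and np.isfinite(self.gyro).all()
                and np.isfinite(self.accel).all()):
            raise ValueError("non-finite sample in stream %s" % self.placement.value)
        dt = np.diff(self.t)
        if n > 1 and dt.min() <= 0:
            raise ValueError("timestamps must be strictly increasing")
        if n > 1 and dt.max() > 2.0 / self.rate:
            i = int(np.argmax(dt))
            raise ValueError(
                "gap of %.4f s in stream %s at t=%.3f s"
                % (dt.max(), self.placement.value, self.t[i])
            )

    def __len__(self) -> int:
        return self.t.shape[0]

    def slice_window(self, t0: float, t1: float) -> "SensorStream":
        """Return the sub-stream with ``t0 <= t <= t1``."""
        m = (self.t >= t0) & (self.t <= t1)
        return SensorStream(self.placement, self.t[m], self.gyro[m],
                            self.accel[m], self.rate)


@dataclass
class QuaternionSeries:
    """Sensor-to-world orientation ``q(t)``, one unit quaternion per sample."""

    t: np.ndarray
    q: np.ndarray  # (n, 4) scalar-first

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (self.t.shape[0], 4):
            raise ValueError("q must have shape (n, 4)")

    def __len__(self) -> int:
        return self.t.shape[0]

    def to_rotmats(self) -> np.ndarray:
        """Rotation-matrix series, shape (n, 3, 3)."""
        return np.stack([quat_to_rotmat(qi) for qi in self.q])


# ---------------------------------------------------------------------------
# quaternion algebra
# ---------------------------------------------------------------------------

def _check_finite(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError("quaternion must be a 4-vector")
    if not np.isfinite(q).all():
        raise ValueError("non-finite quaternion component")
    return q


def quat_multiply(a, b) -> np.ndarray:
    """Hamilton product ``a ⊗ b``, renormalized to unit length."""
    a = _check_finite(a)
    b = _check_finite(b)
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    out = np.array([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ])
    return quat_normalize(out)


def quat_conjugate(q) -> np.ndarray:
    q = _check_finite(q)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_normalize(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = math.sqrt(float(np.dot(q, q)))
    if n == 0.0 or not math.isfinite(n):
        raise ValueError("cannot normalize zero/non-finite quaternion")
    return q / n


def quat_to_rotmat(q) -> np.ndarray:
    """Rotation matrix of a unit quaternion (v_world = R @ v_sensor)."""
    w, x, y, z = quat_normalize(_check_finite(q))
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quat_from_axis_angle(axis, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    axis = axis / n
    h = 0.5 * angle_rad
    return np.concatenate([[math.cos(h)], math.sin(h) * axis])


# ---------------------------------------------------------------------------
# attitude estimation
# ---------------------------------------------------------------------------

def fuse_orientation(stream: SensorStream, beta=0.1,
                     q0: np.ndarray | None = None,
                     accel_trust_band: float | None = None) -> QuaternionSeries:
    """Estimate sensor-to-world orientation by gyro integration with a
    gravity-direction correction.

    Parameters
    ----------
    stream
        Input samples; must be nonempty.
    beta
        Gradient step size in rad/s; scalar, or an (n,) array giving a
        per-sample gain (a large gain is typically used during the
        static calibration window for fast convergence, a small one
        during movement).  ``beta = 0`` is pure gyro integration.
    q0
        Initial unit quaternion; identity if omitted.
    accel_trust_band
        The accelerometer only measures the gravity direction while the
        sensor is not accelerating linearly, so the correction step is
        applied only when the accelerometer magnitude lies within this
        fraction of g.  ``None`` (default) disables the gate; note that
        accelerations perpendicular to gravity barely change the
        magnitude, so the gate is a coarse filter at best.

    Returns
    -------
    QuaternionSeries
        One unit-norm orientation per input sample.  The orientation at
        ``t[0]`` is ``q0`` itself.

    Notes
    -----
    A zero-norm accelerometer sample cannot define a gravity direction;
    for such samples the correction step is skipped and the update is
    gyro-only.  Per-sample ``dt`` is taken from the time vector, so
    irregular timestamps are handled exactly.
    """
    n = len(stream)
    if n == 0:
        raise ValueError("empty stream")
    beta_arr = np.broadcast_to(np.asarray(beta, dtype=float), (n,))
    if beta_arr.min() < 0:
        raise ValueError("beta must be nonnegative")
    if q0 is None:
        q0 = np.array([1.0, 0.0, 0.0, 0.0])
    q = quat_normalize(_check_finite(q0))

    t = stream.t
    gyro = stream.gyro
    accel = stream.accel
    out = np.empty((n, 4))
    out[0] = q
    w, x, y, z = (float(v) for v in q)
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        gx, gy, gz = gyro[i]
        # exact gyro propagation: q ⊗ exp(dt/2 · ω)
        gn = math.sqrt(gx * gx + gy * gy + gz * gz)
        if gn > 0.0:
            half = 0.5 * dt * gn
            c, s = math.cos(half), math.sin(half) / gn
            ew, ex, ey, ez = c, s * gx, s * gy, s * gz
            w, x, y, z = (
                w * ew - x * ex - y * ey - z * ez,
                w * ex + x * ew + y * ez - z * ey,
                w * ey - x * ez + y * ew + z * ex,
                w * ez + x * ey - y * ex + z * ew,
            )

        b = beta_arr[i]
        ax, ay, az = accel[i]
        anorm = math.sqrt(ax * ax + ay * ay + az * az)
        trusted = anorm > 0.0 and (
            accel_trust_band is None
            or abs(anorm - GRAVITY) <= accel_trust_band * GRAVITY)
        if b > 0.0 and trusted:
            ax, ay, az = ax / anorm, ay / anorm, az / anorm
            # objective: predicted gravity direction minus measured one
            f1 = 2.0 * (x * z - w * y) - ax
            f2 = 2.0 * (w * x + y * z) - ay
            f3 = 2.0 * (0.5 - x * x - y * y) - az
            # gradient = J^T f for the gravity objective, projected onto
            # the tangent space of the unit sphere: the radial component
            # is a parameterization artifact, and removing it makes the
            # update exactly equivariant under constant sensor re-mounting
            s0 = -2.0 * y * f1 + 2.0 * x * f2
            s1 = 2.0 * z * f1 + 2.0 * w * f2 - 4.0 * x * f3
            s2 = -2.0 * w * f1 + 2.0 * z * f2 - 4.0 * y * f3
            s3 = 2.0 * x * f1 + 2.0 * y * f2
            radial = s0 * w + s1 * x + s2 * y + s3 * z
            s0 -= radial * w
            s1 -= radial * x
            s2 -= radial * y
            s3 -= radial * z
            snorm = math.sqrt(s0 * s0 + s1 * s1 + s2 * s2 + s3 * s3)
            if snorm > 0.0:
                # normalized step of size beta*dt, regularized so that it
                # shrinks proportionally once the gradient is small —
                # a fixed-size step would limit-cycle around the optimum
                step = b * dt / max(snorm, _GRAD_FLOOR)
                w -= step * s0
                x -= step * s1
                y -= step * s2
                z -= step * s3

        qn = math.sqrt(w * w + x * x + y * y + z * z)
        w, x, y, z = w / qn, x / qn, y / qn, z / qn
        out[i, 0] = w
        out[i, 1] = x
        out[i, 2] = y
        out[i, 3] = z
    return QuaternionSeries(t, out)


def static_attitude_init(stream: SensorStream, gyro_rms_threshold: float = 0.1,
                         min_duration: float = 1.0) -> np.ndarray:
    """Initial attitude (roll/pitch) from the mean accelerometer reading
    of a motionless window; heading is set to zero.

    The returned quaternion is the shortest-arc rotation that carries the
    sensor-frame mean specific-force direction onto the world up axis, so
    it contains no rotation about the gravity axis ("zero yaw").

    Raises
    ------
    CalibrationError
        If the window is shorter than ``min_duration`` seconds or the
        gyro RMS exceeds ``gyro_rms_threshold`` rad/s (motion detected).
    """
    if len(stream) < 2 or stream.t[-1] - stream.t[0] < min_duration:
        raise CalibrationError("static window shorter than %.1f s" % min_duration)
    rms = float(np.sqrt(np.mean(np.sum(stream.gyro ** 2, axis=1))))
    if rms > gyro_rms_threshold:
        raise CalibrationError(
            "motion during static window (gyro RMS %.3f rad/s > %.3f)"
            % (rms, gyro_rms_threshold))
    a = stream.accel.mean(axis=0)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise CalibrationError("zero mean accelerometer during static window")
    v = a / norm                       # measured up direction, sensor frame
    u = np.array([0.0, 0.0, 1.0])      # world up
    # shortest-arc quaternion rotating v (sensor) onto u (world)
    c = float(np.dot(v, u))
    if c < -1.0 + 1e-12:               # antiparallel: 180° about any ⟂ axis
        return np.array([0.0, 1.0, 0.0, 0.0])
    axis = np.cross(v, u)
    q = np.concatenate([[1.0 + c], axis])
    return quat_normalize(q)
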