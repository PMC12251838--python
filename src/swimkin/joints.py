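"""Common-frame alignment, sensor-to-segment calibration, joint angles.

All sensors are first expressed in a shared *body-fixed* Earth frame in
which the x-axis points downward (along gravity), the y-axis forward and
the z-axis to the swimmer's right.  Because 6-axis fusion cannot observe
absolute heading, the heading of the shared frame is pinned to the right
thigh sensor: during the static standing window every sensor's heading
is rotated to match the reference sensor's.  The residual common heading
offset (the reference sensor's own mounting yaw) conjugates all joint
rotations equally; for realistic mounting yaws (≲ 10–15°) the induced
flexion/extension error is below ~2° and is accepted as the intrinsic
heading indeterminacy of magnetometer-free tracking.

Mounting offsets (sensor tilted on the segment by strapping and body
curvature) are removed by a sensor-to-segment calibration: during the
static window every joint is assumed to be in its neutral (0°) posture,
so the constant rotation that maps each sensor's static orientation to
identity is the sensor-to-segment offset.  After calibration the joint
angle is the Euler decomposition of the relative rotation between the
proximal and distal segment frames,

    R_rel(t) = R_prox(t)^T  R_dist(t),

decomposed in intrinsic Z–Y–X order: the z-angle (dominant rotation) is
flexion/extension — dorsi/plantarflexion at the ankle — and the y-angle
is abduction/adduction.  A fully extended knee reads 0°, flexion is
positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .fusion import CalibrationError, Placement, QuaternionSeries

__all__ = [
    "BODY_FRAME_FROM_WORLD",
    "SegmentFrame",
    "JointSpec",
    "JointAngleSeries",
    "JOINTS",
    "align_common_frame",
    "sensor_to_segment_offset",
    "relative_rotation",
    "joint_angles",
    "mean_rotation",
]

# Fixed change of convention from the fusion world frame (z up, arbitrary
# heading) to the body-fixed frame (x down, y forward, z right): a -90°
# rotation about y, which maps world up (+z) onto -x and keeps y forward.
BODY_FRAME_FROM_WORLD = np.array([
    [0.0, 0.0, -1.0],
    [0.0, 1.0, 0.0],
    [1.0, 0.0, 0.0],
])


@dataclass
class SegmentFrame:
    """Orientation series of one body segment.

    ``R`` holds sensor-to-body-frame rotations (n, 3, 3); ``offset`` is
    the constant sensor-to-segment rotation found during calibration.
    ``segment_rotations()`` returns the calibrated segment orientation
    ``R(t) @ offset``.
    """

    placement: Placement
    t: np.ndarray
    R: np.ndarray
    offset: np.ndarray | None = None

    def segment_rotations(self) -> np.ndarray:
        if self.offset is None:
            return self.R
        return self.R @ self.offset


@dataclass(frozen=True)
class JointSpec:
    name: str
    proximal: Placement
    distal: Placement
    planes: tuple[str, ...]


#: Joint definitions. The lower-back sensor serves as the pelvis segment
#: for the hip; knee and ankle expose only the sagittal plane.
JOINTS: dict[str, JointSpec] = {
    "hip_L": JointSpec("hip_L", Placement.BACK_LOWER, Placement.THIGH_L,
                       ("flex_ext", "abd_add")),
    "hip_R": JointSpec("hip_R", Placement.BACK_LOWER, Placement.THIGH_R,
                       ("flex_ext", "abd_add")),
    "knee_L": JointSpec("knee_L", Placement.THIGH_L, Placement.SHANK_L,
                        ("flex_ext",)),
    "knee_R": JointSpec("knee_R", Placement.THIGH_R, Placement.SHANK_R,
                        ("flex_ext",)),
    "ankle_L": JointSpec("ankle_L", Placement.SHANK_L, Placement.FOOT_L,
                         ("flex_ext",)),
    "ankle_R": JointSpec("ankle_R", Placement.SHANK_R, Placement.FOOT_R,
                         ("flex_ext",)),
}


@dataclass
class JointAngleSeries:
    """One joint angle in one movement plane over time (degrees, unwrapped)."""

    joint: str
    plane: str
    t: np.ndarray
    angle: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.t.shape != self.angle.shape:
            raise ValueError("t and angle must have the same shape")


def mean_rotation(R: np.ndarray) -> np.ndarray:
    """Chordal mean of a rotation series: SVD projection of the element
    average back onto SO(3)."""
    M = np.asarray(R).mean(axis=0)
    U, _, Vt = np.linalg.svd(M)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def _heading(R: np.ndarray) -> float:
    """Rotation of ``R`` about the body-frame vertical (x) axis, rad."""
    return Rotation.from_matrix(R).as_euler("XYZ")[0]


def _heading_rotation(angle: float) -> np.ndarray:
    return Rotation.from_euler("X", angle).as_matrix()


def align_common_frame(series: dict[Placement, QuaternionSeries],
                       static_window: tuple[float, float],
                       reference: Placement = Placement.THIGH_R,
                       ) -> dict[Placement, SegmentFrame]:
    """Express every sensor in the shared body-fixed frame and match all
    headings to the reference sensor over the static window.

    Parameters
    ----------
    series
        Fusion output per placement (world frame, z up).
    static_window
        ``(t0, t1)`` of the motionless standing phase, seconds.
    reference
        Placement whose heading defines "forward" (right thigh).

    Returns
    -------
    dict mapping each placement to a :class:`SegmentFrame` whose ``R``
    is the heading-aligned sensor-to-body-frame rotation series (no
    segment offset yet).
    """
    if reference not in series:
        raise CalibrationError("reference sensor %s missing" % reference.value)
    t0, t1 = static_window

    def _static_mean(qs: QuaternionSeries, Rs: np.ndarray) -> np.ndarray:
        m = (qs.t >= t0) & (qs.t <= t1)
        if not m.any():
            raise CalibrationError("no samples in static window")
        return mean_rotation(Rs[m])

    body = {}
    for plc, qs in series.items():
        Rw = Rotation.from_quat(qs.q, scalar_first=True).as_matrix()
        body[plc] = BODY_FRAME_FROM_WORLD @ Rw

    ref_heading = _heading(_static_mean(series[reference], body[reference]))
    out = {}
    for plc, qs in series.items():
        h = _heading(_static_mean(qs, body[plc]))
        C = _heading_rotation(ref_heading - h)
        out[plc] = SegmentFrame(plc, qs.t, C @ body[plc])
    return out


def sensor_to_segment_offset(frame: SegmentFrame,
                             static_window: tuple[float, float],
                             min_duration: float = 1.0) -> np.ndarray:
    """Constant sensor-to-segment rotation from the static standing pose.

    During the window every joint is assumed neutral (0°), i.e. every
    segment frame coincides with the body-fixed frame; the offset is
    therefore the inverse of the sensor's mean static orientation, so
    that ``R(t) @ offset`` averages to identity over the window.
    """
    t0, t1 = static_window
    if t1 - t0 < min_duration:
        raise CalibrationError("calibration window shorter than %.1f s"
                               % min_duration)
    m = (frame.t >= t0) & (frame.t <= t1)
    if m.sum() < 2:
        raise CalibrationError("calibration window contains too few samples")
    return mean_rotation(frame.R[m]).T


def relative_rotation(R1: np.ndarray, R2: np.ndarray) -> np.ndarray:
    """Rotation of frame 2 relative to frame 1: ``R1(t)^T @ R2(t)``."""
    R1 = np.asarray(R1)
    R2 = np.asarray(R2)
    if R1.shape != R2.shape:
        raise ValueError("rotation series length mismatch")
    return np.einsum("nji,njk->nik", R1, R2)


def joint_angles(proximal: SegmentFrame, distal: SegmentFrame,
                 spec: JointSpec, gimbal_margin: float = 1.0,
                 ) -> dict[str, JointAngleSeries]:
    """Euler joint angles of ``distal`` relative to ``proximal``.

    The relative rotation is decomposed in intrinsic Z–Y–X order.  The
    z-angle is flexion/extension, the y-angle abduction/adduction; only
    the planes listed in ``spec.planes`` are returned.  Samples whose
    middle Euler angle lies within ``gimbal_margin`` degrees of ±90°
    (gimbal proximity) are flagged and linearly interpolated over.
    Angles are unwrapped to remove ±180° jumps.
    """
    if proximal.t.shape != distal.t.shape or not np.allclose(
            proximal.t, distal.t, atol=1e-9):
        raise ValueError("proximal and distal frames are not on the same time base")
    Rrel = relative_rotation(proximal.segment_rotations(),
                             distal.segment_rotations())
    eul = Rotation.from_matrix(Rrel).as_euler("ZYX", degrees=True)
    flex = eul[:, 0]
    abd = eul[:, 1]

    bad = np.abs(np.abs(abd) - 90.0) < gimbal_margin
    if bad.any() and not bad.all():
        idx = np.arange(len(flex))
        flex = flex.copy()
        abd = abd.copy()
        flex[bad] = np.interp(idx[bad], idx[~bad], flex[~bad])
        abd[bad] = np.interp(idx[bad], idx[~bad], abd[~bad])
    elif bad.all():
        warnings.warn("joint %s: gimbal proximity on every sample" % spec.name)

    flex = np.unwrap(flex, period=360.0)
    abd = np.unwrap(abd, period=360.0)
    out = {}
    if "flex_ext" in spec.planes:
        out["flex_ext"] = JointAngleSeries(spec.name, "flex_ext", proximal.t, flex)
    if "abd_add" in spec.planes:
        out["abd_add"] = JointAngleSeries(spec.name, "abd_add", proximal.t, abd)
    return out
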