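"""Stroke-cycle detection and 100-point time normalization.

A breaststroke cycle runs glide → recovery → propulsion and is bounded
by consecutive instants of maximum knee extension, i.e. minima of the
sagittal knee flexion angle (fully extended = 0°).  Events are detected
per leg on a low-pass-filtered knee angle; the first and last partial
cycles are implicitly discarded because cycles are only formed between
consecutive events.  Each raw cycle is linearly resampled onto a uniform
grid of exactly 100 cycle-percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .joints import JointAngleSeries

__all__ = [
    "NoStrokesError",
    "StrokeEvent",
    "RawCycle",
    "NormalizedCycle",
    "lowpass",
    "detect_stroke_events",
    "segment_cycles",
    "normalize_cycle",
    "extract_cycles",
    "CYCLE_POINTS",
]

#: Number of points on the normalized cycle grid.
CYCLE_POINTS = 100


class NoStrokesError(ValueError):
    """Raised when fewer than two stroke events are found."""


@dataclass(frozen=True)
class StrokeEvent:
    t: float
    index: int
    leg: str  # "L" or "R"


@dataclass
class RawCycle:
    """Samples of one joint-angle series between two consecutive events,
    half-open ``[t_start, t_end)`` for membership; the closing boundary
    sample is retained for interpolation so endpoints are preserved."""

    joint: str
    plane: str
    leg: str
    t: np.ndarray
    angle: np.ndarray
    t_start: float
    t_end: float


@dataclass
class NormalizedCycle:
    """One stroke cycle resampled to exactly 100 points on 0–100%."""

    joint: str
    plane: str
    leg: str
    points: np.ndarray
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (CYCLE_POINTS,):
            raise ValueError("normalized cycle must have exactly %d points"
                             % CYCLE_POINTS)
        if not np.isfinite(self.points).all():
            raise ValueError("non-finite angle in normalized cycle")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def lowpass(angle: np.ndarray, fs: float, cutoff: float = 6.0,
            order: int = 4) -> np.ndarray:
    """Zero-lag Butterworth low-pass (applied forward and backward)."""
    b, a = butter(order, cutoff, fs=fs)
    return filtfilt(b, a, angle)


def detect_stroke_events(knee: JointAngleSeries, leg: str,
                         min_prominence: float = 10.0,
                         min_period: float = 1.0,
                         smooth: bool = True) -> list[StrokeEvent]:
    """Detect cycle-start events at minima of the sagittal knee angle.

    Parameters
    ----------
    knee
        Sagittal-plane knee angle series of one leg.
    leg
        "L" or "R"; attached to the returned events.
    min_prominence
        Minimum prominence of a knee-flexion peak-to-minimum excursion in
        degrees; rejects tremor and noise minima.
    min_period
        Minimum spacing between events in seconds.
    smooth
        Low-pass filter (6 Hz, zero-lag) before detection.  Event indices
        refer to the original series either way.

    Raises
    ------
    NoStrokesError
        If fewer than two qualifying minima are found (e.g. insufficient
        knee flexion for stroke detection).
    """
    t = knee.t
    if len(t) < 8:
        raise NoStrokesError("series too short for stroke detection")
    fs = 1.0 / np.median(np.diff(t))
    y = lowpass(knee.angle, fs) if smooth else np.asarray(knee.angle, float)
    distance = max(1, int(round(min_period * fs)))
    idx, _ = find_peaks(-y, prominence=min_prominence, distance=distance)
    if idx.size < 2:
        raise NoStrokesError(
            "no strokes detected on %s leg: %d qualifying knee-extension "
            "minima (need >= 2)" % (leg, idx.size))
    return [StrokeEvent(float(t[i]), int(i), leg) for i in idx]


def segment_cycles(angles: JointAngleSeries, events: list[StrokeEvent],
                   leg: str | None = None) -> list[RawCycle]:
    """Cut a joint-angle series into raw cycles between consecutive events.

    ``n_events`` events yield ``n_events - 1`` cycles; cycle k spans
    ``[event_k, event_{k+1})``.
    """
    if len(events) < 2:
        raise NoStrokesError("need at least 2 events to form a cycle")
    leg = leg or events[0].leg
    out = []
    for e0, e1 in zip(events[:-1], events[1:]):
        m = (angles.t >= e0.t) & (angles.t <= e1.t)
        out.append(RawCycle(angles.joint, angles.plane, leg,
                            angles.t[m], angles.angle[m], e0.t, e1.t))
    return out


def normalize_cycle(cycle: RawCycle) -> NormalizedCycle | None:
    """Linearly resample one raw cycle onto the uniform 100-point grid.

    Linear interpolation is monotone and cannot overshoot near the sharp
    propulsion peak.  Cycles with fewer than 4 samples are dropped with
    a warning (returns None).
    """
    if cycle.t.size < 4:
        warnings.warn("dropping too-short cycle at t=%.2f s (%d samples)"
                      % (cycle.t_start, cycle.t.size))
        return None
    grid = np.linspace(cycle.t[0], cycle.t[-1], CYCLE_POINTS)
    pts = np.interp(grid, cycle.t, cycle.angle)
    return NormalizedCycle(cycle.joint, cycle.plane, cycle.leg, pts,
                           cycle.t_start, cycle.t_end)


def extract_cycles(angles: JointAngleSeries, events: list[StrokeEvent],
                   leg: str | None = None) -> list[NormalizedCycle]:
    """Segment and normalize in one step, silently dropping short cycles."""
    out = []
    for raw in segment_cycles(angles, events, leg):
        norm = normalize_cycle(raw)
        if norm is not None:
            out.append(norm)
    return out
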