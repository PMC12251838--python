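"""Swimming parameters: temporal, RoM, cyclograms, ACC, SSD, phase shift,
asymmetry, ankle displacement and z-scored profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swimkin.cycles import CYCLE_POINTS, NormalizedCycle, StrokeEvent
from swimkin.fusion import GRAVITY, Placement, SensorStream
from swimkin.joints import SegmentFrame
from swimkin.params import (Cyclogram, acc, ankle_displacement, asymmetry_pct,
                            asymmetry_ssd, build_cyclogram, center_cyclogram,
                            mean_cyclogram, phase_shift, range_of_motion,
                            reference_stats, ssd, temporal_params,
                            zscore_profile)


def events(times, leg="L"):
    return [StrokeEvent(float(t), int(t * 200), leg) for t in times]


def cycle(points, leg="L", joint="knee_L", t0=0.0, t1=2.0):
    return NormalizedCycle(joint, "flex_ext", leg, np.asarray(points, float),
                           t0, t1)


def cyclogram_from(points, centered=False):
    return Cyclogram("ankle_knee", "L", np.asarray(points, float), centered)


class TestTemporalParams:
    def test_arithmetic_example(self):
        # events every 2 s over 50 s, 25 m covered
        ev = {"L": events(np.arange(0, 50.1, 2.0))}
        out = temporal_params(ev, lap_length=5.0, n_laps=5)
        assert out["stroke_duration_mean"] == pytest.approx(2.0)
        assert out["stroke_duration_sd"] == pytest.approx(0.0)
        assert out["stroke_rate"] == pytest.approx(30.0)
        assert out["velocity"] == pytest.approx(0.5)
        assert out["distance_per_stroke"] == pytest.approx(1.0)

    def test_missing_lap_metadata_degrades_gracefully(self):
        out = temporal_params({"L": events([0, 2, 4])})
        assert out["velocity"] is None
        assert out["distance_per_stroke"] is None
        assert out["stroke_duration_mean"] == pytest.approx(2.0)


class TestRangeOfMotion:
    def test_known_span(self):
        pts = np.linspace(10, 80, CYCLE_POINTS)
        assert range_of_motion([cycle(pts)])["rom"] == pytest.approx(70.0)

    def test_constant_cycle_zero(self):
        assert range_of_motion([cycle(np.full(CYCLE_POINTS, 30.0))])["rom"] == 0.0

    def test_mean_over_cycles(self):
        c1 = cycle(np.linspace(0, 60, CYCLE_POINTS))
        c2 = cycle(np.linspace(0, 80, CYCLE_POINTS))
        assert range_of_motion([c1, c2])["rom"] == pytest.approx(70.0)


class TestCyclograms:
    def test_build_requires_matching_grid(self):
        a = cycle(np.zeros(CYCLE_POINTS), t1=2.0)
        b = cycle(np.zeros(CYCLE_POINTS), t1=2.5)
        with pytest.raises(ValueError, match="grid"):
            build_cyclogram(a, b, "ankle_knee")

    def test_centering_idempotent_and_translation_invariant(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-30, 30, (CYCLE_POINTS, 2))
        c = cyclogram_from(pts)
        c1 = center_cyclogram(c)
        c2 = center_cyclogram(c1)
        assert np.allclose(c1.points, c2.points, atol=1e-12)
        shifted = center_cyclogram(cyclogram_from(pts + [17.0, -4.0]))
        assert np.allclose(c1.points, shifted.points, atol=1e-9)

    def test_offset_circle_centers_to_origin(self):
        th = np.linspace(0, 2 * np.pi, CYCLE_POINTS)
        pts = np.column_stack([20 * np.cos(th) + 35, 20 * np.sin(th) - 10])
        c = center_cyclogram(cyclogram_from(pts))
        assert np.allclose(c.points.mean(axis=0), 0, atol=1e-9)


class TestSSD:
    def _rand_centered(self, seed):
        rng = np.random.default_rng(seed)
        return center_cyclogram(
            cyclogram_from(rng.uniform(-40, 40, (CYCLE_POINTS, 2))))

    def test_identical_zero(self):
        c = self._rand_centered(1)
        assert ssd(c, c) == 0.0

    def test_scaling_oracle(self):
        # c2 = 2·c1 ⇒ SSD = Σ‖c1‖²
        c1 = self._rand_centered(2)
        c2 = Cyclogram(c1.pair, c1.leg, 2.0 * c1.points, centered=True)
        assert ssd(c1, c2) == pytest.approx(np.sum(c1.points ** 2))

    @settings(max_examples=25, deadline=None)
    @given(s1=st.integers(0, 1000), s2=st.integers(0, 1000))
    def test_symmetry_and_nonnegativity(self, s1, s2):
        a, b = self._rand_centered(s1), self._rand_centered(s2)
        v = ssd(a, b)
        assert v >= 0
        assert v == pytest.approx(ssd(b, a))
        if s1 == s2:
            assert v == 0.0

    def test_uncentered_rejected(self):
        a = cyclogram_from(np.ones((CYCLE_POINTS, 2)))
        with pytest.raises(ValueError, match="centered"):
            ssd(a, a)

    def test_asymmetry_ssd_definitional(self):
        L = [self._rand_centered(i) for i in range(3)]
        R = [self._rand_centered(i + 10) for i in range(3)]
        assert asymmetry_ssd(L, R) == pytest.approx(
            ssd(mean_cyclogram(L), mean_cyclogram(R)))
        assert asymmetry_ssd(L, [Cyclogram("ankle_knee", "R", c.points, True)
                                 for c in L]) == pytest.approx(0.0)


def brute_force_acc(cyclograms):
    """Independent scalar-loop circular-statistics implementation."""
    n = len(cyclograms)
    vals = []
    for i in range(CYCLE_POINTS - 1):
        cos_sum = sin_sum = count = 0
        for c in cyclograms:
            dx = c.points[i + 1, 0] - c.points[i, 0]
            dy = c.points[i + 1, 1] - c.points[i, 1]
            if dx == 0 and dy == 0:
                continue
            th = math.atan2(dy, dx)
            cos_sum += math.cos(th)
            sin_sum += math.sin(th)
            count += 1
        if count:
            vals.append(math.sqrt((cos_sum / count) ** 2
                                  + (sin_sum / count) ** 2))
    return sum(vals) / len(vals)


class TestACC:
    def _random_cycles(self, n, seed):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            steps = rng.standard_normal((CYCLE_POINTS - 1, 2))
            pts = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            out.append(cyclogram_from(pts))
        return out

    def test_identical_cycles_give_one(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.standard_normal((CYCLE_POINTS, 2)), axis=0)
        cycles = [cyclogram_from(pts.copy()) for _ in range(20)]
        assert acc(cycles) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        cycles = self._random_cycles(5, seed=4)
        assert acc(cycles) == pytest.approx(brute_force_acc(cycles),
                                            abs=1e-12)

    def test_uniform_directions_drive_acc_to_zero(self):
        cycles = self._random_cycles(200, seed=5)
        assert acc(cycles) <= 0.15

    def test_bounds(self):
        for seed in range(5):
            v = acc(self._random_cycles(4, seed))
            assert 0.0 <= v <= 1.0

    def test_zero_length_segments_excluded(self):
        base = np.cumsum(np.ones((CYCLE_POINTS, 2)), axis=0)
        frozen = base.copy()
        frozen[10] = frozen[9]          # one zero-length step
        v = acc([cyclogram_from(base), cyclogram_from(frozen)])
        assert 0.0 <= v <= 1.0 and np.isfinite(v)


class TestPhaseShift:
    def test_synchronized_is_zero(self):
        ev = np.arange(0, 20, 2.0)
        out = phase_shift(events(ev, "L"), events(ev, "R"))
        assert out["phase_shift_mean"] == 0.0

    def test_fixed_delay(self):
        evL = np.arange(0, 20, 2.0)
        out = phase_shift(events(evL, "L"), events(evL + 0.2, "R"))
        assert out["phase_shift_mean"] == pytest.approx(10.0)

    def test_wrap_to_half_cycle(self):
        evL = np.arange(0, 20, 2.0)
        # 1.8 s delay on a 2 s cycle is a -10% shift, not +90%
        out = phase_shift(events(evL, "L"), events(evL + 1.8, "R"))
        assert out["phase_shift_mean"] == pytest.approx(10.0)

    def test_non_overlapping_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            phase_shift(events([0, 2, 4], "L"), events([50, 52], "R"))


class TestAsymmetry:
    def test_equal_is_zero(self):
        assert asymmetry_pct(70.0, 70.0) == 0.0

    def test_arithmetic(self):
        assert asymmetry_pct(90.0, 110.0) == pytest.approx(20.0)

    def test_leg_swap_invariant(self):
        assert asymmetry_pct(55.0, 80.0) == asymmetry_pct(80.0, 55.0)

    def test_both_zero_defined(self):
        assert asymmetry_pct(0.0, 0.0) == 0.0


class TestAnkleDisplacement:
    def _stream_and_frame(self, accel_body, rate=200.0):
        n = accel_body.shape[0]
        t = np.arange(n) / rate
        R = np.broadcast_to(np.eye(3), (n, 3, 3))
        # sensor specific force = R^T (a - g), g = +9.81 x (down)
        f = accel_body - np.array([GRAVITY, 0, 0])
        stream = SensorStream(Placement.SHANK_L, t, np.zeros((n, 3)), f)
        return stream, SegmentFrame(Placement.SHANK_L, t, R)

    def test_zero_acceleration_zero_displacement(self):
        stream, frame = self._stream_and_frame(np.zeros((400, 3)))
        d = ankle_displacement(stream, frame, [(0.0, 1.9)])
        assert all(abs(v) < 1e-9 for v in d.values())

    def test_sinusoidal_lateral_motion_recovered(self):
        # lateral (z) sinusoid, amplitude 0.15 m, period 1 s
        rate, T, A, f = 200.0, 2.0, 0.15, 1.0
        n = int(T * rate) + 1
        t = np.arange(n) / rate
        a = np.zeros((n, 3))
        a[:, 2] = -A * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t)
        stream, frame = self._stream_and_frame(a)
        # window between velocity zeros (position extrema): t = 0.25..0.75
        d = ankle_displacement(stream, frame, [(0.25, 0.75)])
        assert d["lateral"] == pytest.approx(2 * A, rel=0.10)
        assert abs(d["vertical"]) < 0.02 and abs(d["horizontal"]) < 0.02

    def test_rotation_only_gravity_leakage_small(self):
        # sensor rotating under gravity with zero translation
        from scipy.spatial.transform import Rotation
        rate, T = 200.0, 2.0
        n = int(T * rate)
        t = np.arange(n) / rate
        ang = 30 * np.sin(2 * np.pi * t / T)
        R = Rotation.from_euler("z", ang[:, None], degrees=True).as_matrix()
        f = np.einsum("nji,j->ni", R, np.array([-GRAVITY, 0.0, 0.0]))
        stream = SensorStream(Placement.SHANK_L, t, np.zeros((n, 3)), f)
        frame = SegmentFrame(Placement.SHANK_L, t, R)
        d = ankle_displacement(stream, frame, [(0.0, T - 0.01)])
        assert all(abs(v) < 0.02 for v in d.values())

    def test_short_windows_skipped(self):
        stream, frame = self._stream_and_frame(np.zeros((400, 3)))
        with pytest.raises(ValueError, match="windows"):
            ankle_displacement(stream, frame, [(0.0, 0.1)])


class TestZScoreProfile:
    def test_mean_maps_to_zero_and_sd_to_one(self):
        mu, sigma = {"rom_knee_L": 90.0}, {"rom_knee_L": 10.0}
        assert zscore_profile({"rom_knee_L": 90.0}, mu, sigma).z["rom_knee_L"] == 0.0
        assert zscore_profile({"rom_knee_L": 100.0}, mu, sigma).z["rom_knee_L"] == 1.0

    def test_zero_sigma_names_parameter(self):
        with pytest.raises(ValueError, match="rom_knee_L"):
            zscore_profile({"rom_knee_L": 1.0}, {"rom_knee_L": 0.0},
                           {"rom_knee_L": 0.0})

    def test_cohort_self_normalization(self):
        rng = np.random.default_rng(8)
        names = ["a", "b"]
        cohort = [{"a": float(x), "b": float(y)}
                  for x, y in rng.normal([5, -2], [2, 0.5], (30, 2))]
        mu, sigma = reference_stats(cohort, names)
        zs = np.array([[zscore_profile(c, mu, sigma).z[n] for n in names]
                       for c in cohort])
        assert np.allclose(zs.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(zs.std(axis=0, ddof=1), 1, atol=1e-12)
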