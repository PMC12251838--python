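"""Shared fixtures: small synthetic trials generated at test time."""

import numpy as np
import pytest

from swimkin.fusion import GRAVITY, Placement, SensorStream
from swimkin.simulate import (SensorModel, default_template,
                              generate_kinematics, kinematics_to_imu)


@pytest.fixture(scope="session")
def template():
    return default_template(duration_cv=0.05, cycle_jitter=0.03,
                            phase_lag=5.0)


@pytest.fixture(scope="session")
def kinematics(template):
    """Ten-stroke ground-truth trial with mild variability."""
    return generate_kinematics(template, 10, seed=1)


@pytest.fixture(scope="session")
def clean_streams(kinematics):
    """Noiseless, perfectly mounted sensor streams."""
    model = SensorModel(gyro_noise_sd=0.0, accel_noise_sd=0.0,
                        gyro_bias_sd=0.0, mounting_tilt_max=0.0,
                        mounting_yaw_max=0.0)
    return kinematics_to_imu(kinematics, sensor_model=model, seed=2)


@pytest.fixture(scope="session")
def noisy_streams(kinematics):
    """Default noise and random mounting offsets."""
    return kinematics_to_imu(kinematics, seed=3)


def make_static_stream(attitude=None, duration=5.0, rate=200.0,
                       gyro_sd=0.0, accel_sd=0.0, seed=0,
                       placement=Placement.THIGH_R):
    """A motionless stream at a given sensor-to-world attitude."""
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    t = np.arange(n) / rate
    up_world = np.array([0.0, 0.0, GRAVITY])
    R = np.eye(3) if attitude is None else np.asarray(attitude)
    accel = np.tile(R.T @ up_world, (n, 1))
    gyro = gyro_sd * rng.standard_normal((n, 3))
    accel = accel + accel_sd * rng.standard_normal((n, 3))
    return SensorStream(placement, t, gyro, accel, rate)
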