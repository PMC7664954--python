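import numpy as np
import pytest

from imutrack.synthetic import (
    ImuErrorSpec,
    TrajectorySpec,
    corrupt_to_imu,
    make_dataset,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def clean_trajectory():
    spec = TrajectorySpec(n_segments=9, seed=3)
    return simulate_trajectory(spec)


@pytest.fixture(scope="session")
def clean_trial(clean_trajectory):
    """Noise-free IMU trial: finite-difference accel, zero gyro."""
    track, labels = clean_trajectory
    return corrupt_to_imu(track, labels, ImuErrorSpec()), track, labels


@pytest.fixture(scope="session")
def detect_dataset():
    """Near-clean trials with gyro motion signal for SHOE/ARED tests."""
    data = []
    for s in range(4):
        track, labels = simulate_trajectory(TrajectorySpec(n_segments=9, seed=s))
        err = ImuErrorSpec(
            accel_noise_sd=1e-5,
            gyro_noise_sd=1e-5,
            gyro_motion_scale=0.5,
            seed=s,
        )
        data.append((corrupt_to_imu(track, labels, err), track, labels))
    return data


@pytest.fixture(scope="session")
def noisy_dataset():
    """5 subjects x 1 trial with realistic sensor errors."""
    spec = TrajectorySpec(n_segments=9)
    err = ImuErrorSpec(
        accel_noise_sd=0.05,
        gyro_noise_sd=0.02,
        gyro_motion_scale=0.5,
        accel_bias_rw_sd=0.005,
        gravity_leak_amplitude=0.02,
    )
    return make_dataset(5, ["rsho"], 1, spec, err, master_seed=1)


@pytest.fixture(scope="session")
def segment_dataset():
    """Short-segment noisy dataset for regressor training tests."""
    spec = TrajectorySpec(
        n_segments=7,
        dwell_duration_range=(0.3, 0.6),
        move_duration_range=(0.6, 1.2),
    )
    err = ImuErrorSpec(
        accel_noise_sd=0.02,
        gyro_noise_sd=0.01,
        gyro_motion_scale=0.5,
        accel_bias_rw_sd=0.02,
    )
    return make_dataset(4, ["rsho"], 1, spec, err, master_seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
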