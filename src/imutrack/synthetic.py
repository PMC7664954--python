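"""Synthetic human-motion IMU simulator.

Trials alternate stationary dwells with bounded point-to-point movements.
Each movement follows a minimum-jerk displacement profile per axis (the
standard model for human sub-movements), which guarantees zero velocity and
acceleration at segment boundaries — exactly the structure zero-velocity
detectors rely on.  Trajectories are then differentiated and corrupted with
configurable sensor errors (white noise, bias random walk, and a slow
sinusoidal "gravity leak" term emulating imperfect orientation-based
gravity removal) to produce six-channel inertial streams.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .signal_model import ImuTrial, LabelSequence, PositionTrack

__all__ = [
    "TrajectorySpec",
    "ImuErrorSpec",
    "minimum_jerk_profile",
    "simulate_trajectory",
    "corrupt_to_imu",
    "make_dataset",
    "trial_seed",
]

DistRange = tuple[float, float]


@dataclass
class TrajectorySpec:
    """Parameters of one simulated trial's ground-truth trajectory.

    ``move_distance_range`` is either a single (low, high) pair applied to
    every axis or a 3-tuple of per-axis pairs.  ``random_sign`` flips each
    per-axis displacement with probability 1/2.
    """

    sample_rate: float = 120.0
    n_segments: int = 7
    dwell_duration_range: DistRange = (0.5, 1.5)
    move_duration_range: DistRange = (0.8, 2.0)
    move_distance_range: DistRange | tuple[DistRange, DistRange, DistRange] = (0.1, 0.5)
    motion_profile: str = "minimum_jerk"
    random_sign: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.motion_profile != "minimum_jerk":
            raise ValueError(f"unknown motion profile {self.motion_profile!r}")
        for lo, hi in (self.dwell_duration_range, self.move_duration_range):
            if lo <= 0 or hi < lo:
                raise ValueError("duration ranges must be positive and ordered")

    def axis_ranges(self) -> list[DistRange]:
        r = self.move_distance_range
        if isinstance(r[0], (tuple, list)):
            return [tuple(map(float, ax)) for ax in r]  # type: ignore[arg-type]
        return [tuple(map(float, r))] * 3  # type: ignore[list-item]


@dataclass
class ImuErrorSpec:
    """Sensor-error model applied when converting a trajectory to IMU data.

    All magnitudes are non-negative; an all-zero spec yields noise-free
    finite-difference acceleration and identically-zero gyro output.
    """

    accel_noise_sd: float = 0.0  # m/s^2 white noise
    gyro_noise_sd: float = 0.0  # rad/s OU scale while stopped
    accel_bias_rw_sd: float = 0.0  # m/s^2 per sqrt(s) bias random walk
    gravity_leak_amplitude: float = 0.0  # m/s^2 slow sinusoidal additive bias
    gravity_leak_period: float = 60.0  # s
    gyro_motion_scale: float = 0.0  # rad/s OU scale while moving
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "accel_noise_sd",
            "gyro_noise_sd",
            "accel_bias_rw_sd",
            "gravity_leak_amplitude",
            "gravity_leak_period",
            "gyro_motion_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement s(tau), tau in [0, 1].

    s(0)=0, s(1)=1 with zero velocity and acceleration at both endpoints;
    peak acceleration of the scaled profile d*s((t-t0)/T) is 10*d/(sqrt(3)*T^2).
    """
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_trajectory(spec: TrajectorySpec) -> tuple[PositionTrack, LabelSequence]:
    """Generate an origin-anchored position track and its exact labels.

    Segments alternate dwell (stopped, label 1) and move (label 0), starting
    with a dwell; ``spec.n_segments`` counts all segments.
    """
    rng = np.random.default_rng(spec.seed)
    rate = spec.sample_rate
    ranges = spec.axis_ranges()

    pieces: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    pos = np.zeros(3)
    for seg in range(spec.n_segments):
        if seg % 2 == 0:  # dwell
            dur = rng.uniform(*spec.dwell_duration_range)
            n = max(1, int(round(dur * rate)))
            pieces.append(np.tile(pos, (n, 1)))
            labels.append(np.ones(n, dtype=int))
        else:  # move
            dur = rng.uniform(*spec.move_duration_range)
            n = max(2, int(round(dur * rate)))
            d = np.array([rng.uniform(lo, hi) for lo, hi in ranges])
            if spec.random_sign:
                d *= rng.choice([-1.0, 1.0], size=3)
            tau = np.arange(1, n + 1) / n
            s = minimum_jerk_profile(tau)
            pieces.append(pos + s[:, None] * d[None, :])
            labels.append(np.zeros(n, dtype=int))
            pos = pos + d
    positions = np.concatenate(pieces, axis=0)
    lab = np.concatenate(labels)
    return (
        PositionTrack(positions, sample_rate=rate, origin_anchored=True),
        LabelSequence(lab),
    )


def _ou_process(rng: np.random.Generator, n: int, dt: float, theta: float = 20.0) -> np.ndarray:
    """Unit-stationary-variance Ornstein–Uhlenbeck path, shape (n, 3)."""
    x = np.zeros((n, 3))
    sigma = np.sqrt(2 * theta)  # stationary sd 1
    noise = rng.standard_normal((n, 3))
    for k in range(1, n):
        x[k] = x[k - 1] - theta * x[k - 1] * dt + sigma * np.sqrt(dt) * noise[k]
    return x


def corrupt_to_imu(
    track: PositionTrack,
    labels: LabelSequence,
    err: ImuErrorSpec,
    subject_id: str = "sim",
    placement: str = "sim",
) -> ImuTrial:
    """Convert a trajectory into an error-corrupted six-channel IMU trial.

    Acceleration is the second central finite difference of position times
    rate^2, plus white noise, a bias random walk and the gravity-leak
    sinusoid.  Gyro output is an OU process whose scale switches between
    ``gyro_motion_scale`` (moving frames) and ``gyro_noise_sd`` (stopped).
    Deterministic for a fixed ``err.seed``.
    """
    n = len(track)
    if n < 3:
        raise ValueError("track must have at least 3 samples")
    rng = np.random.default_rng(err.seed)
    rate = track.sample_rate
    dt = track.dt
    p = track.positions

    accel = np.zeros((n, 3))
    accel[1:-1] = (p[2:] - 2 * p[1:-1] + p[:-2]) * rate**2
    # endpoints: trials start/end at rest, second difference is zero there

    accel = accel + err.accel_noise_sd * rng.standard_normal((n, 3))
    if err.accel_bias_rw_sd > 0:
        steps = err.accel_bias_rw_sd * np.sqrt(dt) * rng.standard_normal((n, 3))
        accel = accel + np.cumsum(steps, axis=0)
    if err.gravity_leak_amplitude > 0:
        t = track.times
        phase = rng.uniform(0, 2 * np.pi, size=3)
        leak = err.gravity_leak_amplitude * np.sin(
            2 * np.pi * t[:, None] / err.gravity_leak_period + phase[None, :]
        )
        accel = accel + leak

    full = labels.labels.astype(float)
    scale = np.where(full == 0, err.gyro_motion_scale, err.gyro_noise_sd)
    if np.any(scale > 0):
        gyro = _ou_process(rng, n, dt) * scale[:, None]
    else:
        gyro = np.zeros((n, 3))

    return ImuTrial(
        subject_id=subject_id,
        placement=placement,
        sample_rate=rate,
        accel=accel,
        gyro=gyro,
    )


def trial_seed(master_seed: int, subject: str, placement: str, index: int) -> int:
    """Stable per-trial seed derived from a master seed and trial identity."""
    key = f"{master_seed}|{subject}|{placement}|{index}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big")


def make_dataset(
    n_subjects: int,
    placements: list[str],
    trials_per_subject: int,
    spec: TrajectorySpec,
    err: ImuErrorSpec,
    master_seed: int = 0,
) -> list[tuple[ImuTrial, PositionTrack, LabelSequence]]:
    """Simulate ``n_subjects x placements x trials_per_subject`` trials.

    Per-trial seeds are derived deterministically from ``master_seed`` so
    the collection is reproducible and subject-wise splits are leak-free.
    """
    if n_subjects < 1 or trials_per_subject < 1 or not placements:
        raise ValueError("counts must be >= 1 and placements non-empty")
    out = []
    for s in range(n_subjects):
        subject = f"S{s:02d}"
        for placement in placements:
            for k in range(trials_per_subject):
                seed = trial_seed(master_seed, subject, placement, k)
                tspec = TrajectorySpec(**{**spec.__dict__, "seed": seed})
                espec = ImuErrorSpec(**{**err.__dict__, "seed": seed + 1})
                track, labels = simulate_trajectory(tspec)
                trial = corrupt_to_imu(
                    track, labels, espec, subject_id=subject, placement=placement
                )
                out.append((trial, track, labels))
    return out
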