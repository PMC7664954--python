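"""Core domain types shared by every pipeline stage.

An :class:`ImuTrial` carries one trial's six-channel inertial stream
(gravity-removed linear acceleration in m/s^2 and angular velocity in
rad/s), a :class:`PositionTrack` the matching 3D position in metres, and a
:class:`LabelSequence` the per-timestep binary zero-velocity state
(1 = stopped, 0 = moving).  Windowing conventions used by the labeler and
all detectors live in :class:`WindowSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ImuTrial",
    "PositionTrack",
    "LabelSequence",
    "WindowSpec",
    "InputTooShortError",
    "validate_trial",
    "sliding_windows",
    "fill_boundary_labels",
    "read_trial_csv",
    "write_trial_csv",
    "read_label_csv",
    "write_label_csv",
    "write_track_csv",
]


class InputTooShortError(ValueError):
    """Raised when a signal is shorter than the requested window."""


@dataclass
class ImuTrial:
    """One trial's inertial stream with its subject/placement identity."""

    subject_id: str
    placement: str
    sample_rate: float
    accel: np.ndarray  # (n, 3) m/s^2, gravity removed
    gyro: np.ndarray  # (n, 3) rad/s

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass
class PositionTrack:
    """3D positions in metres, one row per timestep."""

    positions: np.ndarray  # (n, 3) m
    sample_rate: float
    origin_anchored: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt


@dataclass
class LabelSequence:
    """Binary zero-velocity state per timestep; 1 = stopped (positive class).

    ``valid_range`` is the inclusive index span actually labeled; window
    half-width margins outside it are filled by the nearest labeled value
    when a full-length sequence is required.
    """

    labels: np.ndarray  # (n,) int, 0/1 inside valid_range
    valid_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.valid_range is None:
            self.valid_range = (0, len(self.labels) - 1)

    def __len__(self) -> int:
        return len(self.labels)

    def valid_slice(self) -> slice:
        first, last = self.valid_range
        return slice(first, last + 1)


@dataclass
class WindowSpec:
    """Sliding-window convention: length ``N``, ``stride`` between window
    starts and the in-window index that receives the label (default the
    centre, ``floor(N/2)``)."""

    N: int = 30
    stride: int = 1
    label_index: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"window length N must be >= 2, got {self.N}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if self.label_index is None:
            self.label_index = self.N // 2
        if not 0 <= self.label_index < self.N:
            raise ValueError(
                f"label_index {self.label_index} outside window of length {self.N}"
            )


def validate_trial(trial: ImuTrial, track: PositionTrack | None = None) -> list[str]:
    """Check the trial (and optional track) invariants.

    Violations are returned as human-readable strings; an empty list means
    everything holds.  Never raises.
    """
    violations: list[str] = []
    if trial.sample_rate <= 0:
        violations.append(f"sample_rate must be > 0, got {trial.sample_rate}")
    if trial.accel.ndim != 2 or trial.accel.shape[1] != 3:
        violations.append(f"accel must have shape (n, 3), got {trial.accel.shape}")
    if trial.gyro.ndim != 2 or trial.gyro.shape[1] != 3:
        violations.append(f"gyro must have shape (n, 3), got {trial.gyro.shape}")
    if trial.accel.shape[0] != trial.gyro.shape[0]:
        violations.append(
            "accel/gyro length mismatch: "
            f"{trial.accel.shape[0]} vs {trial.gyro.shape[0]}"
        )
    if trial.accel.shape[0] < 1:
        violations.append("trial must contain at least one sample")
    if not np.all(np.isfinite(trial.accel)):
        violations.append("accel contains non-finite values")
    if not np.all(np.isfinite(trial.gyro)):
        violations.append("gyro contains non-finite values")
    if track is not None:
        if len(track) != trial.n_samples:
            violations.append(
                f"track length {len(track)} != trial length {trial.n_samples}"
            )
        if not np.all(np.isfinite(track.positions)):
            violations.append("track contains non-finite values")
        if track.origin_anchored and len(track) and not np.allclose(
            track.positions[0], 0.0
        ):
            violations.append("origin-anchored track does not start at [0,0,0]")
    return violations


def sliding_windows(length: int, spec: WindowSpec) -> list[tuple[int, int, int]]:
    """Enumerate ``(start, end, labeled_frame)`` triples, ``end`` exclusive.

    Windows are ordered, in bounds, and number ``floor((length - N)/stride) + 1``.
    """
    if length < spec.N:
        raise InputTooShortError(
            f"signal of length {length} shorter than window N={spec.N}"
        )
    starts = range(0, length - spec.N + 1, spec.stride)
    return [(s, s + spec.N, s + spec.label_index) for s in starts]


def fill_boundary_labels(labels: LabelSequence) -> np.ndarray:
    """Full-length label array with margins filled by the nearest labeled value."""
    first, last = labels.valid_range
    out = labels.labels.copy()
    out[:first] = out[first]
    out[last + 1 :] = out[last]
    return out


# ---------------------------------------------------------------------------
# Plain-text trial I/O.  One CSV per (subject, placement, trial) with header
# t,ax,ay,az,gx,gy,gz and optional px,py,pz columns.

_TRIAL_COLS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
_POS_COLS = ["px", "py", "pz"]


def write_trial_csv(
    path: str | Path,
    trial: ImuTrial,
    track: PositionTrack | None = None,
) -> None:
    data = {
        "t": trial.times,
        "ax": trial.accel[:, 0],
        "ay": trial.accel[:, 1],
        "az": trial.accel[:, 2],
        "gx": trial.gyro[:, 0],
        "gy": trial.gyro[:, 1],
        "gz": trial.gyro[:, 2],
    }
    if track is not None:
        data["px"] = track.positions[:, 0]
        data["py"] = track.positions[:, 1]
        data["pz"] = track.positions[:, 2]
    pd.DataFrame(data).to_csv(path, index=False)


def read_trial_csv(
    path: str | Path,
    subject_id: str = "unknown",
    placement: str = "unknown",
) -> tuple[ImuTrial, PositionTrack | None]:
    df = pd.read_csv(path)
    missing = [c for c in _TRIAL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["t"].to_numpy()
    if len(t) < 2:
        rate = 120.0
    else:
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: sample period is not constant")
        rate = 1.0 / dts[0]
    trial = ImuTrial(
        subject_id=subject_id,
        placement=placement,
        sample_rate=rate,
        accel=df[["ax", "ay", "az"]].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
    )
    track = None
    if all(c in df.columns for c in _POS_COLS):
        track = PositionTrack(df[_POS_COLS].to_numpy(), sample_rate=rate)
    return trial, track


def write_label_csv(path: str | Path, labels: LabelSequence, sample_rate: float) -> None:
    t = np.arange(len(labels)) / sample_rate
    pd.DataFrame({"t": t, "label": fill_boundary_labels(labels)}).to_csv(
        path, index=False
    )


def read_label_csv(path: str | Path) -> LabelSequence:
    df = pd.read_csv(path)
    return LabelSequence(df["label"].to_numpy().astype(int))


def write_track_csv(
    path: str | Path,
    track: PositionTrack,
    velocity: np.ndarray | None = None,
) -> None:
    data = {
        "t": track.times,
        "px": track.positions[:, 0],
        "py": track.positions[:, 1],
        "pz": track.positions[:, 2],
    }
    if velocity is not None:
        data["vx"] = velocity[:, 0]
        data["vy"] = velocity[:, 1]
        data["vz"] = velocity[:, 2]
    pd.DataFrame(data).to_csv(path, index=False)
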