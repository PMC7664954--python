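"""Inertial dead reckoning.

Euler integration (out_t = out_{t-1} + in_t * dt) applied twice turns
acceleration into position.  Zero-velocity gating resets the velocity to
zero during stopped frames and freezes the position; per-moving-segment
linear drift removal subtracts the linearly accumulated velocity error
measured between segment entry and exit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import ImuTrial, LabelSequence, PositionTrack, fill_boundary_labels

__all__ = [
    "MovingSegment",
    "integrate",
    "find_moving_segments",
    "remove_linear_drift",
    "naive_dead_reckoning",
    "gated_dead_reckoning",
]


@dataclass
class MovingSegment:
    """Maximal run of moving frames; b and e are inclusive sample indices."""

    b: int
    e: int

    def __post_init__(self) -> None:
        if self.b > self.e:
            raise ValueError("segment start after end")

    @property
    def length(self) -> int:
        return self.e - self.b + 1


def integrate(
    series: np.ndarray, dt: float, initial: np.ndarray | float = 0.0
) -> np.ndarray:
    """Euler (rectangular) integration: out_t = out_{t-1} + in_t * dt."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    series = np.asarray(series, dtype=float)
    return np.asarray(initial, dtype=float) + np.cumsum(series, axis=0) * dt


def find_moving_segments(labels: LabelSequence) -> list[MovingSegment]:
    """Maximal runs of moving (label 0) frames, ordered and non-overlapping."""
    full = fill_boundary_labels(labels)
    moving = full == 0
    edges = np.diff(moving.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0])
    if moving[0]:
        starts.insert(0, 0)
    if moving[-1]:
        ends.append(len(full) - 1)
    return [MovingSegment(b, e) for b, e in zip(starts, ends)]


def remove_linear_drift(velocity: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Subtract the linearly accumulated velocity drift over one segment.

    drift_rate = (v_e - v_b) / (t_e - t_b) per axis, and
    corrected v(t_i) = v(t_i) - drift_rate * (t_i - t_b), so the corrected
    end velocity equals the start velocity.  Length-1 segments are returned
    unchanged.
    """
    velocity = np.asarray(velocity, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(velocity) != len(t):
        raise ValueError("velocity/time length mismatch")
    if len(velocity) < 2 or t[-1] == t[0]:
        return velocity.copy()
    drift_rate = (velocity[-1] - velocity[0]) / (t[-1] - t[0])
    return velocity - np.outer(t - t[0], np.atleast_1d(drift_rate))


def naive_dead_reckoning(trial: ImuTrial) -> tuple[PositionTrack, np.ndarray]:
    """Plain double integration of the whole trial from rest at the origin."""
    v = integrate(trial.accel, trial.dt, np.zeros(3))
    p = integrate(v, trial.dt, np.zeros(3))
    return PositionTrack(p, trial.sample_rate, origin_anchored=False), v


def gated_dead_reckoning(
    trial: ImuTrial,
    labels: LabelSequence,
    drift_correction: bool = True,
) -> tuple[PositionTrack, np.ndarray]:
    """Zero-velocity-gated double integration.

    During stopped frames velocity is zero and position is frozen.  Each
    moving segment integrates acceleration with v_b = 0, optionally removes
    linear drift, and integrates the (corrected) velocity onward from the
    segment's entry position.  Position starts at [0,0,0] and is continuous
    across segment boundaries.
    """
    if len(labels) != trial.n_samples:
        raise ValueError(
            f"label length {len(labels)} != trial length {trial.n_samples}"
        )
    n = trial.n_samples
    dt = trial.dt
    velocity = np.zeros((n, 3))
    position = np.zeros((n, 3))
    t = trial.times

    pos = np.zeros(3)
    last_end = -1
    for seg in find_moving_segments(labels):
        position[last_end + 1 : seg.b] = pos  # stopped frames before this segment
        v = integrate(trial.accel[seg.b : seg.e + 1], dt, np.zeros(3))
        if drift_correction:
            v = remove_linear_drift(v, t[seg.b : seg.e + 1])
        p = integrate(v, dt, pos)
        velocity[seg.b : seg.e + 1] = v
        position[seg.b : seg.e + 1] = p
        pos = p[-1]
        last_end = seg.e
    position[last_end + 1 :] = pos
    return PositionTrack(position, trial.sample_rate, origin_anchored=True), velocity
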