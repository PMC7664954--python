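"""Fixed-threshold zero-velocity detectors.

SHOE compares a variance-normalized windowed energy of acceleration plus
angular rate to a threshold gamma; ARED uses the windowed squared norm of
angular velocity only.  In both, a statistic strictly below the threshold
means "stopped" (label 1).  Thresholds are calibrated on labeled training
trials by maximizing pooled frame accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal_model import (
    ImuTrial,
    InputTooShortError,
    LabelSequence,
    WindowSpec,
    fill_boundary_labels,
    sliding_windows,
)

__all__ = [
    "ShoeParams",
    "AredParams",
    "shoe_statistic",
    "shoe_statistics",
    "ared_statistics",
    "shoe_detect",
    "ared_detect",
    "estimate_noise_variances",
    "calibrate_threshold",
]


@dataclass
class ShoeParams:
    N: int = 30
    gamma: float = 1.0
    sigma_a2: float = 1.0  # (m/s^2)^2
    sigma_w2: float = 1.0  # (rad/s)^2

    def __post_init__(self) -> None:
        if self.N < 1 or self.gamma <= 0 or self.sigma_a2 <= 0 or self.sigma_w2 <= 0:
            raise ValueError("ShoeParams requires N >= 1 and positive gamma/variances")


@dataclass
class AredParams:
    N: int = 30
    gamma_w: float = 1.0  # (rad/s)^2

    def __post_init__(self) -> None:
        if self.N < 1 or self.gamma_w <= 0:
            raise ValueError("AredParams requires N >= 1 and gamma_w > 0")


def _windowed_mean(x: np.ndarray, N: int) -> np.ndarray:
    """Mean of x over windows [k, k+N), for every valid start k."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[N:] - c[:-N]) / N


def shoe_statistics(trial: ImuTrial, params: ShoeParams) -> np.ndarray:
    """SHOE statistic for every window start; length n_samples - N + 1."""
    if trial.n_samples < params.N:
        raise InputTooShortError("trial shorter than SHOE window")
    per_sample = (
        np.sum(trial.accel**2, axis=1) / params.sigma_a2
        + np.sum(trial.gyro**2, axis=1) / params.sigma_w2
    )
    return _windowed_mean(per_sample, params.N)


def shoe_statistic(trial: ImuTrial, k: int, params: ShoeParams) -> float:
    """SHOE statistic for the window starting at sample k."""
    if k < 0 or k + params.N > trial.n_samples:
        raise IndexError(f"window [{k}, {k + params.N}) out of range")
    a = trial.accel[k : k + params.N]
    w = trial.gyro[k : k + params.N]
    return float(
        np.mean(np.sum(a**2, axis=1) / params.sigma_a2 + np.sum(w**2, axis=1) / params.sigma_w2)
    )


def ared_statistics(trial: ImuTrial, params: AredParams) -> np.ndarray:
    """ARED statistic (windowed mean squared gyro norm) for every window start."""
    if trial.n_samples < params.N:
        raise InputTooShortError("trial shorter than ARED window")
    return _windowed_mean(np.sum(trial.gyro**2, axis=1), params.N)


def _labels_from_statistics(stats: np.ndarray, threshold: float, N: int, n: int) -> LabelSequence:
    spec = WindowSpec(N=N, stride=1)
    labels = np.ones(n, dtype=int)
    first = spec.label_index
    last = first + len(stats) - 1
    labels[first : last + 1] = (stats < threshold).astype(int)
    seq = LabelSequence(labels, valid_range=(first, last))
    seq.labels = fill_boundary_labels(seq)
    return seq


def shoe_detect(trial: ImuTrial, params: ShoeParams) -> LabelSequence:
    """Label frames stopped (1) where the SHOE statistic is strictly below gamma."""
    stats = shoe_statistics(trial, params)
    return _labels_from_statistics(stats, params.gamma, params.N, trial.n_samples)


def ared_detect(trial: ImuTrial, params: AredParams) -> LabelSequence:
    """Label frames stopped (1) where the ARED statistic is strictly below gamma_w."""
    stats = ared_statistics(trial, params)
    return _labels_from_statistics(stats, params.gamma_w, params.N, trial.n_samples)


def estimate_noise_variances(
    trials: list[ImuTrial],
    truths: list[LabelSequence],
    floor: float = 1e-12,
) -> tuple[float, float]:
    """Per-channel-pooled accel/gyro variances over stationary training frames."""
    acc, gyr = [], []
    for trial, truth in zip(trials, truths):
        mask = fill_boundary_labels(truth) == 1
        if mask.any():
            acc.append(trial.accel[mask])
            gyr.append(trial.gyro[mask])
    if not acc:
        raise ValueError("no stationary frames available to estimate variances")
    sigma_a2 = float(np.var(np.concatenate(acc)))
    sigma_w2 = float(np.var(np.concatenate(gyr)))
    return max(sigma_a2, floor), max(sigma_w2, floor)


def _default_candidates(all_stats: np.ndarray, n: int = 200) -> np.ndarray:
    pos = all_stats[all_stats > 0]
    if pos.size == 0:
        return np.array([1.0])
    lo, hi = pos.min(), all_stats.max()
    if hi <= lo:
        return np.array([lo * 1.0000001])
    return np.geomspace(lo, hi * 1.0000001, n)


def calibrate_threshold(
    detector_kind: str,
    trials: list[ImuTrial],
    truths: list[LabelSequence],
    candidates: np.ndarray | None = None,
    N: int = 30,
    sigma_a2: float | None = None,
    sigma_w2: float | None = None,
) -> ShoeParams | AredParams:
    """Select the threshold maximizing pooled frame accuracy on training trials.

    Ties break toward the smallest threshold.  When SHOE variances are not
    supplied they are estimated from the stationary training frames.  The
    default candidate grid is log-spaced between the extremes of the
    observed windowed statistics.
    """
    if detector_kind not in ("shoe", "ared"):
        raise ValueError(f"unknown detector kind {detector_kind!r}")
    if not trials or len(trials) != len(truths):
        raise ValueError("need >= 1 labeled trial")

    if detector_kind == "shoe":
        if sigma_a2 is None or sigma_w2 is None:
            sigma_a2, sigma_w2 = estimate_noise_variances(trials, truths)
        base = ShoeParams(N=N, gamma=1.0, sigma_a2=sigma_a2, sigma_w2=sigma_w2)
        stat_fn = lambda tr: shoe_statistics(tr, base)  # noqa: E731
    else:
        base = AredParams(N=N, gamma_w=1.0)
        stat_fn = lambda tr: ared_statistics(tr, base)  # noqa: E731

    per_trial = [stat_fn(tr) for tr in trials]
    center = WindowSpec(N=N).label_index
    truth_windows = [
        fill_boundary_labels(tt)[center : center + len(st)]
        for st, tt in zip(per_trial, truths)
    ]
    stats = np.concatenate(per_trial)
    truth = np.concatenate(truth_windows)
    if candidates is None:
        candidates = _default_candidates(stats)
    candidates = np.sort(np.asarray(candidates, dtype=float))

    best_gamma, best_acc = None, -1.0
    for g in candidates:
        acc = float(np.mean((stats < g).astype(int) == truth))
        if acc > best_acc:  # ties keep the earlier (smaller) candidate
            best_acc, best_gamma = acc, g
    assert best_gamma is not None
    if detector_kind == "shoe":
        return replace(base, gamma=float(best_gamma))
    return replace(base, gamma_w=float(best_gamma))
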