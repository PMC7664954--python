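"""Zero-velocity ground-truth labeling from a position track.

A sliding window of ``N`` samples is scanned over the 3D position signal;
the window's movement measure is compared against a displacement threshold
and the label (1 = stopped) is written at the window's centre frame.  A
hysteresis multiplier ``T`` elevates the threshold when the previous state
was stopped, suppressing label chatter near the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import (
    InputTooShortError,
    LabelSequence,
    PositionTrack,
    WindowSpec,
    sliding_windows,
)

__all__ = [
    "LabelingParams",
    "ClassificationReport",
    "label_from_position",
    "compare_labels",
    "fit_labeling_params",
]


@dataclass
class LabelingParams:
    thresh: float = 0.01  # m, displacement threshold
    T: float = 3.0  # hysteresis multiplier
    N: int = 30  # window size, samples

    def __post_init__(self) -> None:
        if self.thresh <= 0:
            raise ValueError("thresh must be > 0")
        if self.T < 1:
            raise ValueError("hysteresis term T must be >= 1")
        if self.N < 2:
            raise ValueError("window size N must be >= 2")


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")


def _window_movement(window: np.ndarray, measure: str) -> float:
    if measure == "max_deviation":
        return float(np.max(np.linalg.norm(window - window[0], axis=1)))
    if measure == "path_length":
        return float(np.sum(np.linalg.norm(np.diff(window, axis=0), axis=1)))
    raise ValueError(f"unknown movement measure {measure!r}")


def label_from_position(
    track: PositionTrack,
    params: LabelingParams | None = None,
    window: WindowSpec | None = None,
    movement_measure: str = "max_deviation",
) -> LabelSequence:
    """Label each centre frame stopped/moving from windowed displacement.

    The movement measure defaults to the maximum Euclidean deviation from
    the window's first sample (``path_length`` available as alternative).
    A window is moving iff the measure strictly exceeds the effective
    threshold: ``thresh`` when the previous state was moving, ``T*thresh``
    when it was stopped.  The initial state is stopped (trials begin at
    rest).  Margins outside the labeled span carry the nearest label.
    """
    params = params or LabelingParams()
    spec = window or WindowSpec(N=params.N, stride=1)
    n = len(track)
    if n < spec.N:
        raise InputTooShortError(f"track length {n} < window N={spec.N}")
    p = track.positions
    labels = np.ones(n, dtype=int)
    state_stopped = True
    first_frame = last_frame = None
    for start, end, frame in sliding_windows(n, spec):
        m = _window_movement(p[start:end], movement_measure)
        eff = params.T * params.thresh if state_stopped else params.thresh
        moving = m > eff
        labels[frame] = 0 if moving else 1
        state_stopped = not moving
        if first_frame is None:
            first_frame = frame
        last_frame = frame
    labels[:first_frame] = labels[first_frame]
    labels[last_frame + 1 :] = labels[last_frame]
    return LabelSequence(labels, valid_range=(first_frame, last_frame))


def compare_labels(pred: LabelSequence, truth: LabelSequence) -> ClassificationReport:
    """Confusion counts over the intersection of valid ranges; positive = stopped."""
    lo = max(pred.valid_range[0], truth.valid_range[0])
    hi = min(pred.valid_range[1], truth.valid_range[1])
    if lo > hi:
        raise ValueError("label sequences have disjoint valid ranges")
    p = pred.labels[lo : hi + 1]
    t = truth.labels[lo : hi + 1]
    tp = int(np.sum((p == 1) & (t == 1)))
    fp = int(np.sum((p == 1) & (t == 0)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    return ClassificationReport(tp=tp, fp=fp, tn=tn, fn=fn)


def fit_labeling_params(
    tracks: list[PositionTrack],
    manual_labels: list[LabelSequence],
    candidates: list[LabelingParams],
) -> LabelingParams:
    """Pick the candidate maximizing mean accuracy against manual labels.

    Ties are broken by smallest ``thresh``, then smallest ``T``.
    """
    if not tracks or len(tracks) != len(manual_labels):
        raise ValueError("need >= 1 track with matching manual labels")
    if not candidates:
        raise ValueError("candidate grid is empty")
    best: tuple[float, float, float] | None = None
    best_params: LabelingParams | None = None
    for cand in candidates:
        accs = []
        for track, truth in zip(tracks, manual_labels):
            pred = label_from_position(track, cand)
            accs.append(compare_labels(pred, truth).accuracy)
        key = (-float(np.mean(accs)), cand.thresh, cand.T)
        if best is None or key < best:
            best = key
            best_params = cand
    assert best_params is not None
    return best_params
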