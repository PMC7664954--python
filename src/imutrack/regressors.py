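"""LSTM displacement regressors for moving segments.

Three warm-start strategies for a two-layer recurrent integrator:

* **Integrative weights** — the LSTM gate weights are drawn tiny, gate
  biases saturate the sigmoids at ~1, cell activations are linear, and the
  candidate weight on the input equals the sampling period ``dt``.  The
  untrained network then computes ``c_t = c_{t-1} + a_t*dt`` per layer,
  i.e. exact Euler double integration, and training only has to learn the
  error corrections.
* **Pre-trained weights** — a one-layer LSTM + linear head is first
  trained to mimic single integration (plain, or drift-corrected targets);
  its weights seed both layers of the two-layer displacement model.
* **No customized initialization** — standard random init, with input
  combinations of acceleration, gyro, and INS-estimated position.

A stacked network performs zero-velocity classification and whole-trial
displacement regression jointly, trained with a convex combination of
binary cross-entropy and MSE controlled by ``alpha``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .integration import find_moving_segments, integrate, remove_linear_drift
from .nn import LSTM, Adam, Dense, Dropout, TrainingProtocol
from .nn.layers import sigmoid
from .nn.train import _EarlyStopper, bce_loss, train_sequence_regressor
from .signal_model import ImuTrial, LabelSequence, PositionTrack, fill_boundary_labels

__all__ = [
    "IntegrativeWeightSpec",
    "SequenceRegressor",
    "build_integrative_model",
    "build_no_init_model",
    "pretrain_single_integrator",
    "assemble_warm_start_model",
    "train_displacement_regressor",
    "trial_axis_integration_pairs",
    "segment_axis_integration_pairs",
    "segment_axis_displacement_pairs",
    "segment_3d_displacement_pairs",
    "split_pairs_by_subject",
    "StackedModel",
    "build_stacked_model",
    "joint_loss",
    "train_stacked",
]

EPS = 1e-7
DEFAULT_UNITS = 30


@dataclass
class IntegrativeWeightSpec:
    """Analytic initialization constants for the integrative warm start.

    Gate weights are drawn uniformly from (-eps, eps) (symmetry breaking);
    gate biases sit at ``gate_bias`` so every gate sigmoid is saturated at
    ~1 (sigmoid(20) = 1 - 2e-9, which keeps the compounded per-step decay
    below 1e-6 over realistic segment lengths).  The candidate weight on
    the driving input is exactly ``dt``.  ``eps`` defaults to 1e-9: large
    enough to break symmetry, small enough that the candidate bias drift it
    injects (~eps * T per layer) stays orders of magnitude below the
    integration output over hundreds of steps.
    """

    dt: float
    gate_bias: float = 20.0
    eps: float = 1e-9

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if sigmoid(np.array([self.gate_bias]))[0] < 0.9999:
            raise ValueError("gate bias must saturate the sigmoid to >= 0.9999")


class SequenceRegressor:
    """A chain of LSTM/Dense/Dropout blocks applied over full sequences."""

    def __init__(self, blocks: list):
        self.blocks = blocks
        self.layers = blocks  # optimizer interface

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        for blk in self.blocks:
            if isinstance(blk, (LSTM, Dropout)):
                x = blk.forward(x, training=training, rng=rng)
            else:
                x = blk.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for blk in reversed(self.blocks):
            dy = blk.backward(dy)
        return dy

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass on a single (T, D) series."""
        return self.forward(np.asarray(x, dtype=float)[None])[0]


def _integrative_lstm(
    input_size: int,
    hidden: int,
    drive_row: int,
    spec: IntegrativeWeightSpec,
    rng: np.random.Generator,
) -> LSTM:
    """Linear-cell LSTM whose unit 0 Euler-integrates input channel
    ``drive_row``; every other weight is a tiny symmetry-breaking value."""
    lstm = LSTM(input_size, hidden, rng, cell_activation="linear")
    H = hidden
    u = lambda shape: rng.uniform(-spec.eps, spec.eps, size=shape)  # noqa: E731
    Wx = u((input_size, 4 * H))
    Wh = u((H, 4 * H))
    b = np.concatenate([
        spec.gate_bias + u(H),  # input gate
        spec.gate_bias + u(H),  # forget gate
        u(H),  # candidate bias b_c
        spec.gate_bias + u(H),  # output gate
    ])
    Wx[:, 2 * H : 3 * H] = u((input_size, H))  # candidate weights ~ 0 ...
    Wx[drive_row, 2 * H] = spec.dt  # ... except dt on the driving channel
    lstm.params["Wx"][...] = Wx
    lstm.params["Wh"][...] = Wh
    lstm.params["b"][...] = b
    return lstm


def build_integrative_model(
    dt: float,
    hidden: int = DEFAULT_UNITS,
    seed: int = 0,
    spec: IntegrativeWeightSpec | None = None,
) -> SequenceRegressor:
    """Two linear-cell LSTM layers + linear head that, untrained, perform
    Euler double integration of a single-axis acceleration series.

    Layer 1 accumulates velocity in cell unit 0, layer 2 accumulates
    position from that unit, and the head reads unit 0 with weight 1.
    """
    spec = spec or IntegrativeWeightSpec(dt=dt)
    rng = np.random.default_rng(seed)
    l1 = _integrative_lstm(1, hidden, drive_row=0, spec=spec, rng=rng)
    l2 = _integrative_lstm(hidden, hidden, drive_row=0, spec=spec, rng=rng)
    head = Dense(hidden, 1, rng)
    head.params["W"][...] = rng.uniform(-spec.eps, spec.eps, size=(hidden, 1))
    head.params["W"][0, 0] = 1.0
    head.params["b"][...] = 0.0
    return SequenceRegressor([l1, l2, head])


def build_no_init_model(
    input_channels: int,
    hidden: int = DEFAULT_UNITS,
    seed: int = 0,
) -> SequenceRegressor:
    """Two-layer LSTM + 3D head with default random initialization."""
    if input_channels not in (3, 6, 9):
        raise ValueError(
            f"input_channels must be 3, 6 or 9, got {input_channels}"
        )
    rng = np.random.default_rng(seed)
    return SequenceRegressor(
        [
            LSTM(input_channels, hidden, rng),
            LSTM(hidden, hidden, rng),
            Dense(hidden, 3, rng),
        ]
    )


def _build_single_integrator(hidden: int, seed: int) -> SequenceRegressor:
    rng = np.random.default_rng(seed)
    return SequenceRegressor([LSTM(1, hidden, rng), Dense(hidden, 1, rng)])


def pretrain_single_integrator(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    protocol: TrainingProtocol | None = None,
    hidden: int = DEFAULT_UNITS,
    seed: int = 0,
    val_fraction: float = 0.3,
) -> tuple[SequenceRegressor, dict]:
    """Train a one-layer LSTM + linear head to mimic single integration.

    ``pairs`` are (single-axis acceleration (T,1), target velocity (T,1))
    series — plain Euler-integrated or drift-corrected targets, axes
    pooled as independent samples.  Batch size is forced to 1.
    """
    protocol = protocol or TrainingProtocol(batch_size=1)
    if len(pairs) < 2:
        raise ValueError("need >= 2 pairs to hold out validation data")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(val_fraction * len(pairs))))
    val = [pairs[i] for i in order[:n_val]]
    train = [pairs[i] for i in order[n_val:]]
    model = _build_single_integrator(hidden, seed)
    history = train_sequence_regressor(model, train, val, protocol, seed=seed)
    return model, {"history": history}


def assemble_warm_start_model(
    first: SequenceRegressor, second: SequenceRegressor
) -> SequenceRegressor:
    """Stack two pre-trained (LSTM + linear head) integrators.

    The plain variant passes the same model twice; the drift variant passes
    the drift-corrected integrator first and the plain one second.
    """
    for m in (first, second):
        if len(m.blocks) != 2 or not isinstance(m.blocks[0], LSTM):
            raise ValueError("expected one-layer LSTM + dense integrators")
    if first.blocks[1].params["W"].shape[1] != second.blocks[0].input_size:
        raise ValueError("incompatible layer shapes")
    return SequenceRegressor(
        [copy.deepcopy(b) for b in first.blocks]
        + [copy.deepcopy(b) for b in second.blocks]
    )


def train_displacement_regressor(
    model: SequenceRegressor,
    train_pairs: list[tuple[np.ndarray, np.ndarray]],
    val_pairs: list[tuple[np.ndarray, np.ndarray]],
    protocol: TrainingProtocol | None = None,
    seed: int = 0,
) -> dict:
    """Fine-tune a displacement regressor with MSE at batch size 1.

    Targets are per-segment displacements since the segment's first frame,
    so every target series starts at (approximately) zero.
    """
    protocol = protocol or TrainingProtocol(batch_size=1)
    return train_sequence_regressor(model, train_pairs, val_pairs, protocol, seed=seed)


# ---------------------------------------------------------------------------
# Segment dataset builders.

Sample = tuple[np.ndarray, np.ndarray]


def _segments(labels: LabelSequence):
    return find_moving_segments(labels)


def trial_axis_integration_pairs(
    dataset: list[tuple[ImuTrial, PositionTrack, LabelSequence]],
) -> list[Sample]:
    """Whole-trial (accel axis series, Euler-integrated velocity) pairs.

    Preferred pretraining data for the plain integrator: the dwell spans
    teach the quiet-input -> hold-velocity fixed point that per-segment
    pairs never exhibit.
    """
    pairs: list[Sample] = []
    for trial, _track, _labels in dataset:
        v = integrate(trial.accel, trial.dt, np.zeros(3))
        for ax in range(3):
            pairs.append((trial.accel[:, ax : ax + 1], v[:, ax : ax + 1]))
    return pairs


def segment_axis_integration_pairs(
    dataset: list[tuple[ImuTrial, PositionTrack, LabelSequence]],
    drift_corrected: bool = False,
) -> list[Sample]:
    """(accel axis series, velocity target) pairs pooled over axes/segments."""
    pairs: list[Sample] = []
    for trial, _track, labels in dataset:
        t = trial.times
        for seg in _segments(labels):
            a = trial.accel[seg.b : seg.e + 1]
            v = integrate(a, trial.dt, np.zeros(3))
            if drift_corrected:
                v = remove_linear_drift(v, t[seg.b : seg.e + 1])
            for ax in range(3):
                pairs.append((a[:, ax : ax + 1], v[:, ax : ax + 1]))
    return pairs


def segment_axis_displacement_pairs(
    dataset: list[tuple[ImuTrial, PositionTrack, LabelSequence]],
) -> list[Sample]:
    """(accel axis series, displacement-since-segment-start) pairs."""
    pairs: list[Sample] = []
    for trial, track, labels in dataset:
        for seg in _segments(labels):
            a = trial.accel[seg.b : seg.e + 1]
            p = track.positions[seg.b : seg.e + 1]
            d = p - track.positions[max(seg.b - 1, 0)]
            for ax in range(3):
                pairs.append((a[:, ax : ax + 1], d[:, ax : ax + 1]))
    return pairs


def segment_3d_displacement_pairs(
    dataset: list[tuple[ImuTrial, PositionTrack, LabelSequence]],
    input_channels: int = 3,
) -> list[Sample]:
    """3D (input series, displacement) pairs for the no-init variant.

    Channels 3/6/9 select accel; accel+gyro; accel+gyro+INS position (the
    position obtained by naive double integration within the segment).
    """
    if input_channels not in (3, 6, 9):
        raise ValueError("input_channels must be 3, 6 or 9")
    pairs: list[Sample] = []
    for trial, track, labels in dataset:
        for seg in _segments(labels):
            sl = slice(seg.b, seg.e + 1)
            a = trial.accel[sl]
            feats = [a]
            if input_channels >= 6:
                feats.append(trial.gyro[sl])
            if input_channels == 9:
                v = integrate(a, trial.dt, np.zeros(3))
                feats.append(integrate(v, trial.dt, np.zeros(3)))
            x = np.hstack(feats)
            d = track.positions[sl] - track.positions[max(seg.b - 1, 0)]
            pairs.append((x, d))
    return pairs


def split_pairs_by_subject(
    dataset: list[tuple[ImuTrial, PositionTrack, LabelSequence]],
    builder,
    train_fraction: float = 0.7,
    seed: int = 0,
    **kwargs,
) -> tuple[list[Sample], list[Sample]]:
    """Build pairs separately for a subject-wise 7/3 train/validation split."""
    from .ml_detectors import split_subjects

    subjects = [t.subject_id for t, _, _ in dataset]
    train_subj, val_subj = split_subjects(subjects, train_fraction, seed)
    train = builder([d for d in dataset if d[0].subject_id in train_subj], **kwargs)
    val = builder([d for d in dataset if d[0].subject_id in val_subj], **kwargs)
    return train, val


# ---------------------------------------------------------------------------
# Stacked joint detection + regression network.


class StackedModel:
    """LSTM(30) -> sigmoid label head, concatenated back onto the input,
    then two LSTM(30) layers, dropout 0.25 and a 3D linear head.

    ``forward`` maps a whole-trial six-channel stream (1, T, 6) to the
    per-timestep stopped probability (1, T, 1) and the displacement since
    trial start (1, T, 3).
    """

    def __init__(self, input_size: int = 6, hidden: int = DEFAULT_UNITS, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.lstm_cls = LSTM(input_size, hidden, rng)
        self.dense_cls = Dense(hidden, 1, rng)
        self.lstm_r1 = LSTM(input_size + 1, hidden, rng)
        self.lstm_r2 = LSTM(hidden, hidden, rng)
        self.drop = Dropout(0.25)
        self.dense_out = Dense(hidden, 3, rng)
        self.layers = [
            self.lstm_cls,
            self.dense_cls,
            self.lstm_r1,
            self.lstm_r2,
            self.drop,
            self.dense_out,
        ]
        self.norm_mean = np.zeros(input_size)
        self.norm_sd = np.ones(input_size)

    def forward(
        self, x: np.ndarray, training: bool = False, rng=None
    ) -> tuple[np.ndarray, np.ndarray]:
        h1 = self.lstm_cls.forward(x, training=training, rng=rng)
        z = self.dense_cls.forward(h1)
        p = sigmoid(z)
        self._p = p
        x2 = np.concatenate([x, p], axis=2)
        h2 = self.lstm_r1.forward(x2, training=training, rng=rng)
        h3 = self.lstm_r2.forward(h2, training=training, rng=rng)
        hd = self.drop.forward(h3, training=training, rng=rng)
        y = self.dense_out.forward(hd)
        return p, y

    def backward(self, dz_cls: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Backprop given d(loss)/d(classifier logit) and d(loss)/d(output)."""
        dhd = self.dense_out.backward(dy)
        dh3 = self.drop.backward(dhd)
        dh2 = self.lstm_r2.backward(dh3)
        dx2 = self.lstm_r1.backward(dh2)
        dx_reg = dx2[:, :, :-1]
        # gradient reaching the probability through the concatenation
        dz = dz_cls + dx2[:, :, -1:] * self._p * (1 - self._p)
        dh1 = self.dense_cls.backward(dz)
        dx_cls = self.lstm_cls.backward(dh1)
        return dx_reg + dx_cls

    def predict_trial(self, trial: ImuTrial) -> tuple[np.ndarray, PositionTrack]:
        x = (np.hstack([trial.accel, trial.gyro]) - self.norm_mean) / self.norm_sd
        p, y = self.forward(x[None])
        return p[0, :, 0], PositionTrack(y[0], trial.sample_rate, origin_anchored=False)


def build_stacked_model(
    input_size: int = 6, hidden: int = DEFAULT_UNITS, seed: int = 0
) -> StackedModel:
    return StackedModel(input_size=input_size, hidden=hidden, seed=seed)


def joint_loss(
    y_cl: np.ndarray,
    p_cl: np.ndarray,
    y_reg: np.ndarray,
    yhat_reg: np.ndarray,
    alpha: float,
) -> float:
    """(1 - alpha) * BCE(labels, probabilities) + alpha * MSE(displacements).

    Both terms are means over the N timesteps; the MSE additionally
    averages over the three axes.  alpha = 1 reduces to plain MSE, alpha =
    0 to plain BCE.  Probabilities are clipped to [eps, 1 - eps].
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    y_cl = np.asarray(y_cl, dtype=float).reshape(-1)
    p_cl = np.asarray(p_cl, dtype=float).reshape(-1)
    if len(y_cl) != len(p_cl):
        raise ValueError("classification target/prediction length mismatch")
    lb = bce_loss(y_cl, p_cl)
    lm = float(np.mean((np.asarray(y_reg) - np.asarray(yhat_reg)) ** 2))
    return (1 - alpha) * lb + alpha * lm


def train_stacked(
    model: StackedModel,
    train_trials: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    val_trials: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    alpha: float,
    protocol: TrainingProtocol | None = None,
    seed: int = 0,
) -> dict:
    """Train the stacked network with the joint loss at batch size 1.

    Each trial is ``(x (T,6) standardized stream, y_cl (T,) truth labels,
    y_reg (T,3) displacement since trial start)``.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if not val_trials:
        raise ValueError("validation split is empty")
    protocol = protocol or TrainingProtocol(batch_size=1)
    rng = np.random.default_rng(seed)
    opt = Adam(
        model.layers,
        lr=protocol.learning_rate,
        weight_decay=protocol.weight_decay,
        clip_norm=protocol.gradient_clip,
    )
    stopper = _EarlyStopper(protocol.early_stop_patience)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    def val_loss_now() -> float:
        total = 0.0
        for x, y_cl, y_reg in val_trials:
            p, yhat = model.forward(x[None])
            total += joint_loss(y_cl, p[0, :, 0], y_reg, yhat[0], alpha)
        return total / len(val_trials)

    stopper.update(val_loss_now(), model.layers)
    for _ in range(protocol.max_epochs):
        order = rng.permutation(len(train_trials))
        epoch_loss = 0.0
        for idx in order:
            x, y_cl, y_reg = train_trials[idx]
            n = len(y_cl)
            opt.zero_grad()
            p, yhat = model.forward(x[None], training=True, rng=rng)
            loss = joint_loss(y_cl, p[0, :, 0], y_reg, yhat[0], alpha)
            epoch_loss += loss
            pc = np.clip(p[0, :, 0], EPS, 1 - EPS)
            dz_cls = ((1 - alpha) * (pc - y_cl) / n)[None, :, None]
            dy = (alpha * 2 * (yhat[0] - y_reg) / y_reg.size)[None]
            model.backward(dz_cls, dy)
            opt.step()
        history["train_loss"].append(epoch_loss / len(train_trials))
        val_loss = val_loss_now()
        history["val_loss"].append(val_loss)
        if stopper.update(val_loss, model.layers):
            break
    stopper.restore_best(model.layers)
    return history
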