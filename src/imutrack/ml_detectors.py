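"""Learned zero-velocity classifiers.

Two families: windowed time-domain features (11 statistics x 6 channels)
feeding scikit-learn LR/SVM/RF models tuned by group-3-fold cross
validation, and sequence models (single LSTM(30) with recurrent dropout,
or six stacked LSTM(80) layers) consuming raw standardized six-channel
windows.  A binary median filter is available as post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, ParameterSampler, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .nn import LSTM, Dense, Dropout, TrainingProtocol, train_window_classifier
from .nn.layers import sigmoid
from .signal_model import (
    ImuTrial,
    LabelSequence,
    WindowSpec,
    fill_boundary_labels,
    sliding_windows,
)

__all__ = [
    "FeatureTable",
    "TrainingProtocol",
    "FEATURE_NAMES",
    "CHANNEL_NAMES",
    "extract_window_features",
    "build_feature_table",
    "prune_correlated",
    "standardize",
    "fit_window_classifier",
    "SequenceClassifier",
    "fit_sequence_classifier",
    "median_filter_labels",
    "split_subjects",
]

FEATURE_NAMES = (
    "mean",
    "max",
    "min",
    "sum",
    "sd",
    "q25",
    "q75",
    "median",
    "var",
    "energy",
    "maxdiff",
)
CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")


def extract_window_features(window: np.ndarray, absolute_maxdiff: bool = False) -> dict[str, float]:
    """The 11 time-domain statistics of one single-channel window.

    Variance and sd are population-style (divide by N); ``maxdiff`` is the
    signed maximum of first differences unless ``absolute_maxdiff``.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("window must be 1-D with length >= 2")
    d = np.diff(x)
    return {
        "mean": float(np.mean(x)),
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "sum": float(np.sum(x)),
        "sd": float(np.std(x)),
        "q25": float(np.quantile(x, 0.25)),
        "q75": float(np.quantile(x, 0.75)),
        "median": float(np.median(x)),
        "var": float(np.var(x)),
        "energy": float(np.sum(x**2)),
        "maxdiff": float(np.max(np.abs(d)) if absolute_maxdiff else np.max(d)),
    }


@dataclass
class FeatureTable:
    """Windows x named-features matrix with per-row subject group and label."""

    features: pd.DataFrame
    labels: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(set(self.features.columns)) != len(self.features.columns):
            raise ValueError("feature column names must be unique")


def build_feature_table(
    trials: list[ImuTrial],
    truths: list[LabelSequence],
    window: WindowSpec | None = None,
) -> FeatureTable:
    """Extract 66 features per window across all trials (stride from spec)."""
    spec = window or WindowSpec()
    rows, labels, groups = [], [], []
    for trial, truth in zip(trials, truths):
        data = np.hstack([trial.accel, trial.gyro])
        full = fill_boundary_labels(truth)
        for start, end, frame in sliding_windows(trial.n_samples, spec):
            row = {}
            for ci, ch in enumerate(CHANNEL_NAMES):
                feats = extract_window_features(data[start:end, ci])
                row.update({f"{name}_{ch}": v for name, v in feats.items()})
            rows.append(row)
            labels.append(full[frame])
            groups.append(trial.subject_id)
    cols = [f"{name}_{ch}" for ch in CHANNEL_NAMES for name in FEATURE_NAMES]
    df = pd.DataFrame(rows, columns=cols)
    return FeatureTable(df, np.array(labels), np.array(groups))


def prune_correlated(
    table: pd.DataFrame, r_threshold: float = 0.9
) -> tuple[list[str], list[str]]:
    """Greedy keep-first correlation pruning on the training table.

    Columns are scanned in order; a column is dropped when its |Pearson r|
    with any already-kept column exceeds ``r_threshold``.  Zero-variance
    columns correlate with nothing (r treated as 0) and are kept.  The
    dropped list is meant to be applied verbatim to any other table.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 rows to compute correlations")
    values = table.to_numpy(dtype=float)
    sds = values.std(axis=0)
    kept_idx: list[int] = []
    dropped: list[str] = []
    for j, col in enumerate(table.columns):
        drop = False
        if sds[j] > 0:
            for k in kept_idx:
                if sds[k] == 0:
                    continue
                r = np.corrcoef(values[:, j], values[:, k])[0, 1]
                if abs(r) > r_threshold:
                    drop = True
                    break
        if drop:
            dropped.append(col)
        else:
            kept_idx.append(j)
    return [table.columns[k] for k in kept_idx], dropped


def standardize(
    table: pd.DataFrame, params: tuple[pd.Series, pd.Series] | None = None
) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Centre/scale columns; fit on the given table unless params supplied.

    Zero-variance columns are centred only (sd treated as 1).
    """
    if params is None:
        mean = table.mean()
        sd = table.std(ddof=0).replace(0.0, 1.0)
        params = (mean, sd)
    mean, sd = params
    return (table - mean) / sd, params


_DEFAULT_SPACES = {
    "lr": {"clf__C": np.geomspace(1e-3, 100, 40)},
    "svm": {"clf__C": np.geomspace(0.1, 100, 20), "clf__gamma": np.geomspace(1e-3, 10, 20)},
    "rf": {
        "clf__n_estimators": [25, 50, 100, 200],
        "clf__max_depth": [3, 5, 8, 12, None],
    },
}


def fit_window_classifier(
    kind: str,
    table: FeatureTable,
    n_iter: int = 8,
    seed: int = 0,
    search_space: dict | None = None,
):
    """Tune and fit an LR/SVM/RF window classifier.

    Hyperparameters are selected by group-3-fold cross-validation accuracy
    using a seeded random search (the search backend is pluggable through
    ``search_space``/``n_iter``); the winning configuration is refit on all
    rows.  LR/SVM pipelines standardize per fold; the tree model does not.
    Returns ``(fitted_pipeline, cv_report)``.
    """
    if kind not in ("lr", "svm", "rf"):
        raise ValueError(f"unknown classifier kind {kind!r}")
    groups = table.groups
    if len(np.unique(groups)) < 3:
        raise ValueError("group-3-fold CV needs >= 3 distinct subjects")

    if kind == "lr":
        base = LogisticRegression(max_iter=2000, random_state=seed)
    elif kind == "svm":
        base = SVC(kernel="rbf", random_state=seed)
    else:
        base = RandomForestClassifier(random_state=seed)
    steps = [] if kind == "rf" else [("scale", StandardScaler())]
    pipe = Pipeline(steps + [("clf", base)])

    space = search_space or _DEFAULT_SPACES[kind]
    cv = GroupKFold(n_splits=3)
    X, y = table.features.to_numpy(), table.labels
    best_params, best_score = None, -np.inf
    cv_report = []
    for params in ParameterSampler(space, n_iter=n_iter, random_state=seed):
        pipe.set_params(**params)
        scores = cross_val_score(pipe, X, y, groups=groups, cv=cv, scoring="accuracy")
        cv_report.append({"params": params, "cv_accuracy": float(scores.mean())})
        if scores.mean() > best_score:
            best_score, best_params = float(scores.mean()), params
    pipe.set_params(**best_params)
    pipe.fit(X, y)
    return pipe, {"best_params": best_params, "best_cv_accuracy": best_score,
                  "trials": cv_report}


class SequenceClassifier:
    """LSTM window classifier: stacked LSTMs -> (dropout) -> Dense(1) logit
    at the window's final timestep; ``predict_proba`` applies the sigmoid."""

    ARCHS = {
        "lstm30": {"layers": [(30, 0.2)], "head_dropout": 0.0},
        "lstm6x80": {"layers": [(80, 0.0)] * 6, "head_dropout": 0.2},
    }

    def __init__(self, arch: str, input_size: int = 6, seed: int = 0):
        if arch not in self.ARCHS:
            raise ValueError(f"unknown architecture {arch!r}")
        rng = np.random.default_rng(seed)
        cfg = self.ARCHS[arch]
        self.arch = arch
        self.lstms: list[LSTM] = []
        size = input_size
        for hidden, rdrop in cfg["layers"]:
            self.lstms.append(LSTM(size, hidden, rng, recurrent_dropout=rdrop))
            size = hidden
        self.head_dropout = Dropout(cfg["head_dropout"])
        self.head = Dense(size, 1, rng)
        self.layers = [*self.lstms, self.head_dropout, self.head]
        # train-set standardization parameters (set by the fitting routine)
        self.norm_mean = np.zeros(input_size)
        self.norm_sd = np.ones(input_size)

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        h = x
        for lstm in self.lstms:
            h = lstm.forward(h, training=training, rng=rng)
        last = h[:, -1]
        last = self.head_dropout.forward(last, training=training, rng=rng)
        self._seq_shape = h.shape
        return self.head.forward(last)[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        dlast = self.head.backward(dlogit[:, None])
        dlast = self.head_dropout.backward(dlast)
        dh = np.zeros(self._seq_shape)
        dh[:, -1] = dlast
        for lstm in reversed(self.lstms):
            dh = lstm.backward(dh)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [
            sigmoid(self.forward(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out) if out else np.zeros(0)

    def predict_trial(self, trial: ImuTrial, window: WindowSpec | None = None) -> LabelSequence:
        """Per-frame labels for a whole trial (margins nearest-filled)."""
        spec = window or WindowSpec()
        data = (np.hstack([trial.accel, trial.gyro]) - self.norm_mean) / self.norm_sd
        wins = sliding_windows(trial.n_samples, spec)
        x = np.stack([data[s:e] for s, e, _ in wins])
        p = self.predict_proba(x)
        labels = np.ones(trial.n_samples, dtype=int)
        first, last = wins[0][2], wins[-1][2]
        frames = np.array([f for _, _, f in wins])
        labels[frames] = (p >= 0.5).astype(int)
        seq = LabelSequence(labels, valid_range=(first, last))
        seq.labels = fill_boundary_labels(seq)
        return seq


def split_subjects(
    subjects: list[str], train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic subject-wise train/validation split (paper ratio 7/3)."""
    uniq = sorted(set(subjects))
    if len(uniq) < 2:
        raise ValueError("need >= 2 subjects to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(uniq))
    n_train = max(1, min(len(uniq) - 1, int(round(train_fraction * len(uniq)))))
    return sorted(order[:n_train]), sorted(order[n_train:])


def _windows_for_trials(
    trials: list[ImuTrial],
    truths: list[LabelSequence],
    spec: WindowSpec,
    mean: np.ndarray,
    sd: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for trial, truth in zip(trials, truths):
        data = (np.hstack([trial.accel, trial.gyro]) - mean) / sd
        full = fill_boundary_labels(truth)
        for s, e, f in sliding_windows(trial.n_samples, spec):
            xs.append(data[s:e])
            ys.append(full[f])
    return np.stack(xs), np.array(ys, dtype=float)


def fit_sequence_classifier(
    arch: str,
    trials: list[ImuTrial],
    truths: list[LabelSequence],
    protocol: TrainingProtocol | None = None,
    window: WindowSpec | None = None,
    seed: int = 0,
) -> tuple[SequenceClassifier, dict]:
    """Train an LSTM zero-velocity classifier on raw standardized windows.

    The training subjects are split 7/3 into train/validation; the raw
    six-channel streams are standardized with train-split statistics only.
    """
    protocol = protocol or TrainingProtocol()
    spec = window or WindowSpec()
    subjects = [t.subject_id for t in trials]
    train_subj, val_subj = split_subjects(subjects, 0.7, seed)
    tr = [(t, y) for t, y in zip(trials, truths) if t.subject_id in train_subj]
    va = [(t, y) for t, y in zip(trials, truths) if t.subject_id in val_subj]
    if not va:
        raise ValueError("validation split is empty")

    raw = np.vstack([np.hstack([t.accel, t.gyro]) for t, _ in tr])
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    sd[sd == 0] = 1.0

    x_tr, y_tr = _windows_for_trials(*zip(*tr), spec, mean, sd)
    x_va, y_va = _windows_for_trials(*zip(*va), spec, mean, sd)
    model = SequenceClassifier(arch, input_size=x_tr.shape[2], seed=seed)
    model.norm_mean, model.norm_sd = mean, sd
    history = train_window_classifier(model, x_tr, y_tr, x_va, y_va, protocol, seed=seed)
    val_acc = float(np.mean((model.predict_proba(x_va) >= 0.5) == y_va))
    return model, {"history": history, "val_accuracy": val_acc,
                   "train_subjects": train_subj, "val_subjects": val_subj}


def median_filter_labels(labels: LabelSequence, kernel: int = 31) -> LabelSequence:
    """Sliding binary median with edge replication; kernel must be odd."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd positive integer")
    if kernel == 1:
        return LabelSequence(labels.labels.copy(), valid_range=labels.valid_range)
    half = kernel // 2
    x = fill_boundary_labels(labels)
    padded = np.pad(x, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, kernel)
    out = (windows.sum(axis=1) > half).astype(int)
    return LabelSequence(out, valid_range=labels.valid_range)
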