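"""End-to-end experiment pipelines.

``run_detection_experiment`` trains/calibrates each requested zero-velocity
detector on the training subjects and reports pooled test-frame accuracy
with and without median filtering.  ``run_tracking_experiment`` builds the
detector x regressor error matrix (per-axis RMSE/MAE/R^2, 3D ATE/MAE,
mean +/- sd across test trials).  Both emit a YAML manifest sufficient to
reproduce the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .integration import (
    find_moving_segments,
    gated_dead_reckoning,
    naive_dead_reckoning,
    integrate,
)
from .labeling import compare_labels
from .metrics import aggregate_reports, error_report
from .ml_detectors import (
    build_feature_table,
    fit_sequence_classifier,
    fit_window_classifier,
    median_filter_labels,
    prune_correlated,
)
from .nn import TrainingProtocol
from .regressors import (
    assemble_warm_start_model,
    build_integrative_model,
    build_no_init_model,
    build_stacked_model,
    pretrain_single_integrator,
    segment_3d_displacement_pairs,
    segment_axis_displacement_pairs,
    segment_axis_integration_pairs,
    split_pairs_by_subject,
    trial_axis_integration_pairs,
    train_displacement_regressor,
    train_stacked,
)
from .signal_model import (
    ImuTrial,
    LabelSequence,
    PositionTrack,
    WindowSpec,
    fill_boundary_labels,
    sliding_windows,
)
from .synthetic import ImuErrorSpec, TrajectorySpec, make_dataset
from .threshold_detectors import ared_detect, calibrate_threshold, shoe_detect

__all__ = [
    "ExperimentConfig",
    "split_dataset",
    "run_detection_experiment",
    "run_tracking_experiment",
    "regressor_track",
]

Dataset = list[tuple[ImuTrial, PositionTrack, LabelSequence]]


@dataclass
class ExperimentConfig:
    n_subjects: int = 8
    placements: tuple[str, ...] = ("rsho",)
    trials_per_subject: int = 1
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    errors: ImuErrorSpec = field(default_factory=ImuErrorSpec)
    test_subjects: tuple[str, ...] | None = None  # default: ~23% of subjects
    detectors: tuple[str, ...] = ("shoe", "ared")
    regressors: tuple[str, ...] = ("double", "double+drift")
    alphas: tuple[float, ...] = ()
    median_kernel: int = 31
    window: WindowSpec = field(default_factory=WindowSpec)
    protocol: TrainingProtocol = field(default_factory=lambda: TrainingProtocol(max_epochs=10))
    seed: int = 0
    output_dir: str | None = None


def _subject_ids(config: ExperimentConfig) -> list[str]:
    return [f"S{s:02d}" for s in range(config.n_subjects)]


def resolve_test_subjects(config: ExperimentConfig) -> list[str]:
    subjects = _subject_ids(config)
    if config.test_subjects is not None:
        test = list(config.test_subjects)
        unknown = set(test) - set(subjects)
        if unknown:
            raise ValueError(f"unknown test subjects {sorted(unknown)}")
    else:
        rng = np.random.default_rng(config.seed)
        n_test = max(1, int(round(len(subjects) * 3 / 13)))
        test = sorted(rng.permutation(subjects)[:n_test])
    if len(test) >= len(subjects):
        raise ValueError("test split leaves no training subjects")
    return test


def split_dataset(dataset: Dataset, test_subjects: list[str]) -> tuple[Dataset, Dataset]:
    """Subject-wise split; raises if any subject would land in both sets."""
    train = [d for d in dataset if d[0].subject_id not in test_subjects]
    test = [d for d in dataset if d[0].subject_id in test_subjects]
    overlap = {t.subject_id for t, _, _ in train} & {t.subject_id for t, _, _ in test}
    if overlap:
        raise ValueError(f"train/test subject overlap: {sorted(overlap)}")
    return train, test


def _simulate(config: ExperimentConfig) -> Dataset:
    return make_dataset(
        config.n_subjects,
        list(config.placements),
        config.trials_per_subject,
        config.trajectory,
        config.errors,
        master_seed=config.seed,
    )


def _write_manifest(config: ExperimentConfig, results: dict, name: str) -> None:
    if config.output_dir is None:
        return
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": _config_dict(config),
        "results": results,
    }
    with open(out / f"{name}.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, default_flow_style=False)


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["window"] = {"N": config.window.N, "stride": config.window.stride,
                   "label_index": config.window.label_index}
    return d


# ---------------------------------------------------------------------------
# Detection experiment.


def _frame_accuracy(pred: LabelSequence, truth: LabelSequence) -> float:
    return compare_labels(pred, truth).accuracy


def _make_window_predictor(pipe, dropped: list[str], window: WindowSpec):
    def predict(trial: ImuTrial) -> LabelSequence:
        table = build_feature_table(
            [trial], [LabelSequence(np.ones(trial.n_samples, dtype=int))], window
        )
        X = table.features.drop(columns=dropped).to_numpy()
        y = pipe.predict(X).astype(int)
        wins = sliding_windows(trial.n_samples, window)
        labels = np.ones(trial.n_samples, dtype=int)
        labels[[f for _, _, f in wins]] = y
        seq = LabelSequence(labels, valid_range=(wins[0][2], wins[-1][2]))
        seq.labels = fill_boundary_labels(seq)
        return seq

    return predict


def train_detector(
    name: str,
    train: Dataset,
    config: ExperimentConfig,
):
    """Fit/calibrate one detector; returns ``(trial, truth) -> LabelSequence``.

    The ``truth`` argument is only consulted by the oracle detector
    ``"truth"``; every real detector ignores it.
    """
    trials = [t for t, _, _ in train]
    truths = [y for _, _, y in train]
    N = config.window.N
    # training may subsample windows (config.window.stride); prediction is
    # always dense so every frame gets a label
    predict_window = WindowSpec(N=N, stride=1, label_index=config.window.label_index)
    if name == "truth":
        return lambda trial, truth: truth
    if name == "shoe":
        params = calibrate_threshold("shoe", trials, truths, N=N)
        return lambda trial, truth: shoe_detect(trial, params)
    if name == "ared":
        params = calibrate_threshold("ared", trials, truths, N=N)
        return lambda trial, truth: ared_detect(trial, params)
    if name in ("lr", "svm", "rf"):
        table = build_feature_table(trials, truths, config.window)
        kept, dropped = prune_correlated(table.features)
        table.features = table.features[kept]
        pipe, _report = fit_window_classifier(name, table, seed=config.seed)
        predict = _make_window_predictor(pipe, dropped, predict_window)
        return lambda trial, truth: predict(trial)
    if name in ("lstm", "lstm6"):
        arch = "lstm30" if name == "lstm" else "lstm6x80"
        model, _info = fit_sequence_classifier(
            arch, trials, truths, config.protocol, config.window, seed=config.seed
        )
        return lambda trial, truth: model.predict_trial(trial, predict_window)
    raise ValueError(f"unknown detector {name!r}")


def run_detection_experiment(config: ExperimentConfig) -> dict:
    """Per-detector pooled test accuracy with and without median filtering."""
    dataset = _simulate(config)
    train, test = split_dataset(dataset, resolve_test_subjects(config))
    results: dict[str, dict] = {}
    for name in config.detectors:
        try:
            predictor = train_detector(name, train, config)
            accs, accs_med = [], []
            for trial, _track, truth in test:
                pred = predictor(trial, truth)
                accs.append(_frame_accuracy(pred, truth))
                filtered = median_filter_labels(pred, config.median_kernel)
                accs_med.append(_frame_accuracy(filtered, truth))
            results[name] = {
                "accuracy": float(np.mean(accs)),
                "accuracy_median_filtered": float(np.mean(accs_med)),
                "n_test_trials": len(test),
            }
        except Exception as exc:  # keep other cells alive
            results[name] = {"error": f"{type(exc).__name__}: {exc}"}
    _write_manifest(config, results, "detection")
    return results


# ---------------------------------------------------------------------------
# Tracking experiment.


def regressor_track(
    trial: ImuTrial,
    labels: LabelSequence,
    model,
    mode: str,
) -> PositionTrack:
    """Dead reckoning where each moving segment's displacement comes from a
    trained regressor; stopped frames hold position.

    ``mode``: "axis" runs a single-axis model per axis; "3d{3,6,9}" feeds
    the matching channel combination to a 3D model.
    """
    n = trial.n_samples
    position = np.zeros((n, 3))
    pos = np.zeros(3)
    last_end = -1
    for seg in find_moving_segments(labels):
        sl = slice(seg.b, seg.e + 1)
        position[last_end + 1 : seg.b] = pos
        if mode == "axis":
            d = np.column_stack(
                [model.predict(trial.accel[sl, ax : ax + 1])[:, 0] for ax in range(3)]
            )
        elif mode in ("3d3", "3d6", "3d9"):
            feats = [trial.accel[sl]]
            if mode in ("3d6", "3d9"):
                feats.append(trial.gyro[sl])
            if mode == "3d9":
                v = integrate(trial.accel[sl], trial.dt, np.zeros(3))
                feats.append(integrate(v, trial.dt, np.zeros(3)))
            d = model.predict(np.hstack(feats))
        else:
            raise ValueError(f"unknown regressor mode {mode!r}")
        position[sl] = pos + d
        pos = position[seg.e]
        last_end = seg.e
    position[last_end + 1 :] = pos
    return PositionTrack(position, trial.sample_rate, origin_anchored=True)


def train_regressor_variant(
    name: str, train: Dataset, protocol: TrainingProtocol, seed: int = 0
) -> tuple[object, str]:
    """Train one displacement-regressor variant; returns (model, mode)."""
    dt = train[0][0].dt
    reg_protocol = TrainingProtocol(
        learning_rate=protocol.learning_rate,
        weight_decay=protocol.weight_decay,
        batch_size=1,
        early_stop_patience=protocol.early_stop_patience,
        max_epochs=protocol.max_epochs,
        gradient_clip=protocol.gradient_clip,
    )
    if name == "integrative":
        model = build_integrative_model(dt, seed=seed)
        tr, va = split_pairs_by_subject(train, segment_axis_displacement_pairs, seed=seed)
        train_displacement_regressor(model, tr, va, reg_protocol, seed=seed)
        return model, "axis"
    if name in ("pretrained", "pretrained+drift"):
        plain_pairs = trial_axis_integration_pairs(train)
        plain, _ = pretrain_single_integrator(plain_pairs, reg_protocol, seed=seed)
        if name == "pretrained+drift":
            drift_pairs = segment_axis_integration_pairs(train, drift_corrected=True)
            drift, _ = pretrain_single_integrator(drift_pairs, reg_protocol, seed=seed)
            model = assemble_warm_start_model(drift, plain)
        else:
            model = assemble_warm_start_model(plain, plain)
        tr, va = split_pairs_by_subject(train, segment_axis_displacement_pairs, seed=seed)
        train_displacement_regressor(model, tr, va, reg_protocol, seed=seed)
        return model, "axis"
    if name in ("noinit3", "noinit6", "noinit9"):
        channels = int(name[-1])
        model = build_no_init_model(channels, seed=seed)
        tr, va = split_pairs_by_subject(
            train, segment_3d_displacement_pairs, seed=seed, input_channels=channels
        )
        train_displacement_regressor(model, tr, va, reg_protocol, seed=seed)
        return model, f"3d{channels}"
    raise ValueError(f"unknown regressor variant {name!r}")


def _train_stacked_for_config(
    train: Dataset, alpha: float, protocol: TrainingProtocol, seed: int
):
    from .ml_detectors import split_subjects

    raw = np.vstack([np.hstack([t.accel, t.gyro]) for t, _, _ in train])
    mean, sd = raw.mean(axis=0), raw.std(axis=0)
    sd[sd == 0] = 1.0

    def to_sample(item):
        trial, track, labels = item
        x = (np.hstack([trial.accel, trial.gyro]) - mean) / sd
        y_reg = track.positions - track.positions[0]
        return x, fill_boundary_labels(labels).astype(float), y_reg

    subjects = [t.subject_id for t, _, _ in train]
    tr_subj, va_subj = split_subjects(subjects, 0.7, seed)
    tr = [to_sample(d) for d in train if d[0].subject_id in tr_subj]
    va = [to_sample(d) for d in train if d[0].subject_id in va_subj]
    model = build_stacked_model(seed=seed)
    model.norm_mean, model.norm_sd = mean, sd
    train_stacked(model, tr, va, alpha, protocol, seed=seed)
    return model


def run_tracking_experiment(config: ExperimentConfig) -> dict:
    """Detector x regressor error matrix, mean +/- sd across test trials."""
    dataset = _simulate(config)
    train, test = split_dataset(dataset, resolve_test_subjects(config))
    results: dict[str, dict] = {}

    def evaluate(estimator) -> dict:
        reports = [
            error_report(track, estimator(trial, truth))
            for trial, track, truth in test
        ]
        return {k: {"mean": v[0], "sd": v[1]} for k, v in aggregate_reports(reports).items()}

    # Baseline: no detector, naive double integration.
    results["none/double"] = evaluate(lambda trial, truth: naive_dead_reckoning(trial)[0])

    for det_name in config.detectors:
        try:
            predictor = train_detector(det_name, train, config)
        except Exception as exc:
            for reg_name in config.regressors:
                results[f"{det_name}/{reg_name}"] = {
                    "error": f"{type(exc).__name__}: {exc}"
                }
            continue
        for reg_name in config.regressors:
            key = f"{det_name}/{reg_name}"
            try:
                if reg_name == "double":
                    results[key] = evaluate(
                        lambda trial, truth: gated_dead_reckoning(
                            trial, predictor(trial, truth), drift_correction=False
                        )[0]
                    )
                elif reg_name == "double+drift":
                    results[key] = evaluate(
                        lambda trial, truth: gated_dead_reckoning(
                            trial, predictor(trial, truth), drift_correction=True
                        )[0]
                    )
                else:
                    model, mode = train_regressor_variant(
                        reg_name, train, config.protocol, seed=config.seed
                    )
                    results[key] = evaluate(
                        lambda trial, truth: regressor_track(
                            trial, predictor(trial, truth), model, mode
                        )
                    )
            except Exception as exc:
                results[key] = {"error": f"{type(exc).__name__}: {exc}"}

    for alpha in config.alphas:
        key = f"stacked/alpha={alpha}"
        try:
            model = _train_stacked_for_config(train, alpha, config.protocol, config.seed)
            results[key] = evaluate(
                lambda trial, truth: model.predict_trial(trial)[1]
            )
        except Exception as exc:
            results[key] = {"error": f"{type(exc).__name__}: {exc}"}

    _write_manifest(config, results, "tracking")
    return results
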