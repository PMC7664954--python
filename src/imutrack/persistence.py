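"""Save/load trained models: weights as .npz next to a YAML manifest
recording architecture, seeds and input standardization parameters."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .ml_detectors import SequenceClassifier
from .nn import LSTM, Dense, Dropout
from .regressors import SequenceRegressor, StackedModel, build_stacked_model

__all__ = ["save_model", "load_model"]


def _block_descriptor(blk) -> dict:
    if isinstance(blk, LSTM):
        return {
            "type": "lstm",
            "input_size": blk.input_size,
            "hidden_size": blk.hidden_size,
            "cell_activation": blk.cell_activation,
            "recurrent_dropout": blk.recurrent_dropout,
        }
    if isinstance(blk, Dense):
        W = blk.params["W"]
        return {"type": "dense", "in_size": W.shape[0], "out_size": W.shape[1]}
    if isinstance(blk, Dropout):
        return {"type": "dropout", "rate": blk.rate}
    raise TypeError(f"cannot serialize block {type(blk).__name__}")


def _build_block(desc: dict):
    rng = np.random.default_rng(0)
    if desc["type"] == "lstm":
        return LSTM(
            desc["input_size"],
            desc["hidden_size"],
            rng,
            cell_activation=desc["cell_activation"],
            recurrent_dropout=desc["recurrent_dropout"],
        )
    if desc["type"] == "dense":
        return Dense(desc["in_size"], desc["out_size"], rng)
    if desc["type"] == "dropout":
        return Dropout(desc["rate"])
    raise ValueError(f"unknown block type {desc['type']!r}")


def save_model(path: str | Path, model, meta: dict | None = None) -> None:
    """Write ``<path>.npz`` (weights) and ``<path>.yaml`` (manifest)."""
    path = Path(path)
    manifest: dict = dict(meta or {})
    if isinstance(model, SequenceClassifier):
        manifest["model"] = {"kind": "sequence_classifier", "arch": model.arch,
                             "input_size": model.lstms[0].input_size}
        manifest["norm_mean"] = model.norm_mean.tolist()
        manifest["norm_sd"] = model.norm_sd.tolist()
    elif isinstance(model, StackedModel):
        manifest["model"] = {
            "kind": "stacked",
            "input_size": model.lstm_cls.input_size,
            "hidden": model.lstm_cls.hidden_size,
        }
        manifest["norm_mean"] = model.norm_mean.tolist()
        manifest["norm_sd"] = model.norm_sd.tolist()
    elif isinstance(model, SequenceRegressor):
        manifest["model"] = {
            "kind": "sequence_regressor",
            "blocks": [_block_descriptor(b) for b in model.blocks],
        }
    else:
        raise TypeError(f"cannot serialize model {type(model).__name__}")
    arrays = {
        f"layer{i}__{k}": v
        for i, layer in enumerate(model.layers)
        for k, v in layer.params.items()
    }
    np.savez(path.with_suffix(".npz"), **arrays)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)


def load_model(path: str | Path):
    """Rebuild a model saved by :func:`save_model`; returns (model, manifest)."""
    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        manifest = yaml.safe_load(fh)
    info = manifest["model"]
    if info["kind"] == "sequence_classifier":
        model = SequenceClassifier(info["arch"], input_size=info["input_size"])
        model.norm_mean = np.asarray(manifest["norm_mean"], dtype=float)
        model.norm_sd = np.asarray(manifest["norm_sd"], dtype=float)
    elif info["kind"] == "stacked":
        model = build_stacked_model(info["input_size"], info["hidden"])
        model.norm_mean = np.asarray(manifest["norm_mean"], dtype=float)
        model.norm_sd = np.asarray(manifest["norm_sd"], dtype=float)
    elif info["kind"] == "sequence_regressor":
        model = SequenceRegressor([_build_block(d) for d in info["blocks"]])
    else:
        raise ValueError(f"unknown model kind {info['kind']!r}")
    with np.load(path.with_suffix(".npz")) as data:
        for i, layer in enumerate(model.layers):
            for k in layer.params:
                layer.params[k][...] = data[f"layer{i}__{k}"]
    return model, manifest
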