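"""Trial-level tracking error metrics.

Per-axis RMSE/MAE/R^2 plus 3D absolute trajectory error (ATE, the RMSE of
per-timestep Euclidean position errors) and 3D MAE.  R^2 is the squared
Pearson correlation between truth and estimate, which is bounded in [0, 1]
and equals 1 for a perfect prediction.  Reports are aggregated across test
trials as mean +/- sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import PositionTrack

__all__ = [
    "ErrorReport",
    "axis_errors",
    "trajectory_errors",
    "r_squared",
    "error_report",
    "aggregate_reports",
]

AXES = ("x", "y", "z")


@dataclass
class ErrorReport:
    rmse: tuple[float, float, float]  # per axis, m
    mae: tuple[float, float, float]  # per axis, m
    r2: tuple[float, float, float]  # per axis; nan when undefined
    ate: float  # m
    mae3d: float  # m
    n_samples: int

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for i, ax in enumerate(AXES):
            out[f"rmse_{ax}"] = self.rmse[i]
            out[f"mae_{ax}"] = self.mae[i]
            out[f"r2_{ax}"] = self.r2[i]
        out["ate"] = self.ate
        out["mae3d"] = self.mae3d
        return out


def _residuals(truth: PositionTrack, est: PositionTrack) -> np.ndarray:
    if len(truth) != len(est) or len(truth) == 0:
        raise ValueError("tracks must have equal nonzero length")
    return truth.positions - est.positions


def axis_errors(
    truth: PositionTrack, est: PositionTrack
) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis (rmse, mae), each an array of 3 values in metres."""
    r = _residuals(truth, est)
    return np.sqrt(np.mean(r**2, axis=0)), np.mean(np.abs(r), axis=0)


def trajectory_errors(truth: PositionTrack, est: PositionTrack) -> tuple[float, float]:
    """(ATE, 3D MAE): RMS and mean of per-timestep Euclidean errors."""
    norms = np.linalg.norm(_residuals(truth, est), axis=1)
    return float(np.sqrt(np.mean(norms**2))), float(np.mean(norms))


def r_squared(truth: np.ndarray, est: np.ndarray) -> float:
    """Squared Pearson correlation; nan when either series is constant."""
    truth = np.asarray(truth, dtype=float)
    est = np.asarray(est, dtype=float)
    if truth.std() == 0 or est.std() == 0:
        return float("nan")
    r = np.corrcoef(truth, est)[0, 1]
    return float(r**2)


def r_squared_variance_ratio(truth: np.ndarray, est: np.ndarray) -> float:
    """Alternative Var(est)/Var(truth) form; unbounded, kept behind a flag."""
    truth = np.asarray(truth, dtype=float)
    est = np.asarray(est, dtype=float)
    if truth.var() == 0:
        return float("nan")
    return float(est.var() / truth.var())


def error_report(truth: PositionTrack, est: PositionTrack) -> ErrorReport:
    rmse, mae = axis_errors(truth, est)
    ate, mae3d = trajectory_errors(truth, est)
    r2 = tuple(
        r_squared(truth.positions[:, i], est.positions[:, i]) for i in range(3)
    )
    return ErrorReport(
        rmse=tuple(rmse),
        mae=tuple(mae),
        r2=r2,  # type: ignore[arg-type]
        ate=ate,
        mae3d=mae3d,
        n_samples=len(truth),
    )


def aggregate_reports(reports: list[ErrorReport]) -> dict[str, tuple[float, float]]:
    """Mean +/- sample sd per metric across trials (sd 0 for a single trial)."""
    if not reports:
        raise ValueError("need >= 1 report")
    keys = reports[0].as_dict().keys()
    out = {}
    for key in keys:
        vals = np.array([r.as_dict()[key] for r in reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            out[key] = (float("nan"), float("nan"))
        elif vals.size == 1:
            out[key] = (float(vals[0]), 0.0)
        else:
            out[key] = (float(np.mean(vals)), float(np.std(vals, ddof=1)))
    return out
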