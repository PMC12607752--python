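"""Regression metrics and per-sugar-level error profiles.

R² = 1 − SS_res/SS_tot, RMSE and MAE in % sugar; per-class MAE restricts the
error to the records of each sugar level (the per-class profile shows where
on the 25–75% range a model struggles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConstantTargetError(ValueError):
    """R² is undefined when the true targets are constant."""


@dataclass
class MetricsReport:
    r2: float
    rmse: float
    mae: float
    n_test: int
    per_class_mae: dict[float, float] = field(default_factory=dict)
    n_runs: int = 1
    per_run: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rmse + 1e-12 < self.mae:
            raise ValueError("rmse must be >= mae")


def regression_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float]:
    """(R², RMSE, MAE) of predictions against truth."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ConstantTargetError(
            f"R^2 undefined for constant y_true (rmse={rmse:.6g}, mae={mae:.6g})"
        )
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return r2, rmse, mae


def per_class_mae(
    y_true: np.ndarray, y_pred: np.ndarray, levels: list[float] | None = None
) -> dict[float, float]:
    """MAE restricted to the records of each sugar level.

    Levels with no records are omitted from the result.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if levels is None:
        levels = sorted(np.unique(y_true))
    out: dict[float, float] = {}
    for level in levels:
        sel = y_true == float(level)
        if sel.any():
            out[float(level)] = float(np.mean(np.abs(y_true[sel] - y_pred[sel])))
    return out


def metrics_report(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    levels: list[float] | None = None,
) -> MetricsReport:
    r2, rmse, mae = regression_metrics(y_true, y_pred)
    return MetricsReport(
        r2=r2,
        rmse=rmse,
        mae=mae,
        n_test=len(np.asarray(y_true)),
        per_class_mae=per_class_mae(y_true, y_pred, levels),
    )
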