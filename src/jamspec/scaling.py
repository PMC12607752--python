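"""MinMax scaling of features and targets, fitted on the training fold only.

The scaler records which fold it was fitted on (`provenance`) so the
pipeline can assert at training time that no validation/test information
leaked into the normalisation.  Validation/test values falling outside the
training range map outside [0, 1] and are deliberately not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateScaleError(ValueError):
    """A scaled column is constant on the training fold."""


@dataclass(frozen=True)
class ScalerParams:
    feature_min: np.ndarray
    feature_max: np.ndarray
    target_min: float
    target_max: float
    provenance: str = "train"

    def __post_init__(self) -> None:
        if np.any(self.feature_max < self.feature_min):
            raise ValueError("feature_max must be >= feature_min")
        if self.target_max < self.target_min:
            raise ValueError("target_max must be >= target_min")


def fit_scaler(
    X_train: np.ndarray, y_train: np.ndarray, provenance: str = "train"
) -> ScalerParams:
    """Column-wise feature and target min/max from the training records."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    fmin, fmax = X_train.min(axis=0), X_train.max(axis=0)
    constant = np.flatnonzero(fmax - fmin == 0)
    if constant.size:
        raise DegenerateScaleError(
            f"constant feature column(s) on the training fold: {constant.tolist()}"
        )
    if y_train.max() == y_train.min():
        raise DegenerateScaleError("constant target on the training fold")
    return ScalerParams(
        feature_min=fmin,
        feature_max=fmax,
        target_min=float(y_train.min()),
        target_max=float(y_train.max()),
        provenance=provenance,
    )


def apply_scaler(params: ScalerParams, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params.feature_min) / (
        params.feature_max - params.feature_min
    )


def apply_target(params: ScalerParams, y: np.ndarray) -> np.ndarray:
    return (np.asarray(y, dtype=float) - params.target_min) / (
        params.target_max - params.target_min
    )


def invert_target(params: ScalerParams, y_scaled: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`apply_target` (round-trips to ~1e-12)."""
    return np.asarray(y_scaled, dtype=float) * (
        params.target_max - params.target_min
    ) + params.target_min


def assert_train_provenance(params: ScalerParams) -> None:
    if params.provenance != "train":
        raise ValueError(
            f"scaler was fitted on {params.provenance!r}; models require a "
            "train-fold scaler (leakage guard)"
        )
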