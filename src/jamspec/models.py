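"""Regression models over spectral feature tables: SVM, XGBoost, 1D ResNet.

All three share one contract: ``train_*`` takes a record table and a fold
assignment, fits the MinMax scaler on the training fold only, trains on
scaled features, and returns a fitted regressor whose ``predict`` gives
sugar content in % w/w.  Targets are MinMax-rescaled (and inverted after
prediction) for the residual network only; the SVM and the boosted trees
regress the raw percentages — their printed epsilon/objective settings are
stated in target units.

Published configurations: SVM with an RBF kernel at C = 110, epsilon = 0.1,
gamma = 0.01; XGBoost with learning rate 0.10, depth 5, column subsampling
0.95, up to 400 rounds with 40-round early stopping on validation RMSE; the
residual network per :mod:`jamspec.nn.resnet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.svm import SVR

from .dataset import SplitAssignment, band_columns
from .nn import ResNet1DConfig, TrainingHistory, predict_resnet, train_resnet
from .scaling import (
    ScalerParams,
    apply_scaler,
    apply_target,
    assert_train_provenance,
    fit_scaler,
    invert_target,
)


@dataclass(frozen=True)
class SVMConfig:
    C: float = 110.0
    epsilon: float = 0.1
    gamma: float = 0.01

    def __post_init__(self) -> None:
        if min(self.C, self.epsilon, self.gamma) < 0 or self.C == 0 or self.gamma == 0:
            raise ValueError("SVM hyperparameters must be positive")


@dataclass(frozen=True)
class XGBConfig:
    learning_rate: float = 0.10
    max_depth: int = 5
    colsample: float = 0.95
    max_rounds: int = 400
    early_stop_rounds: int = 40

    def __post_init__(self) -> None:
        if self.max_rounds < self.early_stop_rounds:
            raise ValueError("max_rounds must be >= early_stop_rounds")


@dataclass
class FittedRegressor:
    """A trained model plus the train-fold scaler that feeds it."""

    kind: str
    model: Any
    scaler: ScalerParams
    feature_names: list[str]
    history: TrainingHistory | None = None
    extra: dict = field(default_factory=dict)

    def predict(self, records: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predict sugar content in % w/w."""
        X = (
            records[self.feature_names].to_numpy()
            if isinstance(records, pd.DataFrame)
            else np.asarray(records)
        )
        Xs = apply_scaler(self.scaler, X)
        if self.kind == "svm":
            return self.model.predict(Xs)
        if self.kind == "xgb":
            return self.model.predict(
                xgb.DMatrix(Xs),
                iteration_range=(0, self.extra["best_iteration"] + 1),
            )
        if self.kind == "resnet":
            return invert_target(self.scaler, predict_resnet(self.model, Xs))
        raise ValueError(f"unknown model kind {self.kind!r}")  # pragma: no cover


def _fold_matrices(
    table: pd.DataFrame, folds: SplitAssignment, fold: str
) -> tuple[np.ndarray, np.ndarray]:
    sel = folds.folds == fold
    if not sel.any():
        raise ValueError(f"empty {fold!r} fold")
    sub = table.loc[sel]
    return sub[band_columns(table)].to_numpy(), sub["sugar_pct"].to_numpy(float)


def prepare_folds(
    table: pd.DataFrame,
    folds: SplitAssignment,
    scale_targets: bool = False,
) -> tuple[ScalerParams, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Scale every fold with the train-fold scaler; returns (X, y) per fold.

    Features are always MinMax-scaled; targets only when ``scale_targets``
    (the residual network's protocol).
    """
    out = {}
    X_tr, y_tr = _fold_matrices(table, folds, "train")
    scaler = fit_scaler(X_tr, y_tr)
    assert_train_provenance(scaler)
    for fold in ("train", "val", "test"):
        if (folds.folds == fold).any():
            X, y = _fold_matrices(table, folds, fold)
            ys = apply_target(scaler, y) if scale_targets else y
            out[fold] = (apply_scaler(scaler, X), ys)
    return scaler, out


def train_svm(
    table: pd.DataFrame,
    folds: SplitAssignment,
    config: SVMConfig | None = None,
) -> FittedRegressor:
    """Epsilon-SVR with RBF kernel on scaled features; deterministic."""
    config = config or SVMConfig()
    scaler, mats = prepare_folds(table, folds)
    Xs, ys = mats["train"]
    model = SVR(kernel="rbf", C=config.C, epsilon=config.epsilon, gamma=config.gamma)
    model.fit(Xs, ys)
    return FittedRegressor(
        kind="svm", model=model, scaler=scaler, feature_names=band_columns(table)
    )


def train_xgb(
    table: pd.DataFrame,
    folds: SplitAssignment,
    config: XGBConfig | None = None,
    seed: int = 0,
) -> FittedRegressor:
    """Gradient-boosted trees with early stopping on validation RMSE."""
    config = config or XGBConfig()
    if not (folds.folds == "val").any():
        raise ValueError("XGBoost early stopping requires a validation fold")
    scaler, mats = prepare_folds(table, folds)
    dtrain = xgb.DMatrix(*mats["train"])
    dval = xgb.DMatrix(*mats["val"])
    params = {
        "objective": "reg:squarederror",
        "eta": config.learning_rate,
        "max_depth": config.max_depth,
        "colsample_bytree": config.colsample,
        "eval_metric": "rmse",
        "seed": seed,
        "nthread": 1,
    }
    booster = xgb.train(
        params,
        dtrain,
        num_boost_round=config.max_rounds,
        evals=[(dval, "val")],
        early_stopping_rounds=config.early_stop_rounds,
        verbose_eval=False,
    )
    best = getattr(booster, "best_iteration", config.max_rounds - 1)
    return FittedRegressor(
        kind="xgb",
        model=booster,
        scaler=scaler,
        feature_names=band_columns(table),
        extra={"best_iteration": int(best)},
    )


def train_resnet_model(
    table: pd.DataFrame,
    folds: SplitAssignment,
    config: ResNet1DConfig | None = None,
    seed: int = 0,
) -> FittedRegressor:
    """1D residual network trained on scaled features and targets."""
    config = config or ResNet1DConfig()
    if not (folds.folds == "val").any():
        raise ValueError("ResNet early stopping requires a validation fold")
    scaler, mats = prepare_folds(table, folds, scale_targets=True)
    model, history = train_resnet(
        *mats["train"], *mats["val"], config=config, seed=seed
    )
    return FittedRegressor(
        kind="resnet",
        model=model,
        scaler=scaler,
        feature_names=band_columns(table),
        history=history,
    )


TRAINERS = {
    "svm": train_svm,
    "xgb": train_xgb,
    "resnet": train_resnet_model,
}


def train_model(
    kind: str,
    table: pd.DataFrame,
    folds: SplitAssignment,
    seed: int = 0,
    **kwargs,
) -> FittedRegressor:
    """Uniform entry point over the three model families."""
    if kind not in TRAINERS:
        raise ValueError(f"unknown model kind {kind!r} (choose from {sorted(TRAINERS)})")
    if kind == "svm":
        return train_svm(table, folds, **kwargs)
    return TRAINERS[kind](table, folds, seed=seed, **kwargs)
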