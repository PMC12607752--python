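"""Training loop for the spectral residual network.

Minimises mean absolute error on MinMax-scaled targets with Adam, shuffling
each epoch, and early-stops when the validation MAE fails to improve (strict
decrease by at least ``min_improvement``) for ``patience`` consecutive
epochs; the best-validation weights are restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optim import Adam
from .resnet import ResNet1DConfig, SpectralResNet, build_resnet1d


class NonFiniteLossError(RuntimeError):
    """Training diverged to NaN/inf; carries the offending epoch."""


@dataclass
class TrainingHistory:
    train_mae: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def _batched_forward(model: SpectralResNet, X: np.ndarray, batch: int = 512) -> np.ndarray:
    out = np.empty(X.shape[0], dtype=np.float64)
    for start in range(0, X.shape[0], batch):
        out[start : start + batch] = model.forward(X[start : start + batch], train=False)
    return out


def train_resnet(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ResNet1DConfig | None = None,
    seed: int = 0,
) -> tuple[SpectralResNet, TrainingHistory]:
    """Train on scaled features/targets; returns the best model + history.

    ``y`` must already be on the scaled [0, 1] target scale; prediction back
    to % sugar is the caller's (scaler's) job.
    """
    config = config or ResNet1DConfig()
    n = X_train.shape[0]
    if config.batch_size > n:
        raise ValueError(
            f"batch size {config.batch_size} exceeds training set size {n}"
        )
    ss = np.random.SeedSequence(seed)
    init_seed, shuffle_seed = ss.spawn(2)
    model = build_resnet1d(config, n_bands=X_train.shape[1],
                           seed=int(init_seed.generate_state(1)[0] % 2**31))
    shuffle_rng = np.random.default_rng(shuffle_seed)
    opt = Adam(
        model.parameters(),
        model.gradients(),
        lr=config.lr,
        weight_decay=config.weight_decay,
    )

    X_train = np.ascontiguousarray(X_train, dtype=config.dtype)
    y_train = np.asarray(y_train, dtype=np.float64)
    history = TrainingHistory()
    best_val = np.inf
    best_state = model.state()
    bad_epochs = 0

    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_abs = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            pred = model.forward(xb, train=True)
            resid = pred - yb
            loss = np.abs(resid).mean()
            if not np.isfinite(loss):
                raise NonFiniteLossError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch starting {start}"
                )
            epoch_abs += np.abs(resid).sum()
            model.backward(np.sign(resid).astype(config.dtype) / len(idx))
            opt.step()
        history.train_mae.append(epoch_abs / n)
        val_pred = _batched_forward(model, np.asarray(X_val, dtype=config.dtype))
        val_mae = float(np.abs(val_pred - y_val).mean())
        history.val_mae.append(val_mae)

        if val_mae < best_val - config.min_improvement:
            best_val = val_mae
            best_state = model.state()
            history.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                history.stopped_epoch = epoch
                break
    else:
        history.stopped_epoch = config.max_epochs - 1

    model.load_state(best_state)
    return model, history


def predict_resnet(model: SpectralResNet, X: np.ndarray) -> np.ndarray:
    """Scaled-target predictions for a feature matrix."""
    return _batched_forward(model, np.asarray(X, dtype=model.config.dtype))
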