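"""NumPy layer primitives with explicit forward/backward passes.

Activations flow channels-last as (batch, length, channels) arrays, which
keeps the channel axis contiguous so each convolution tap is a single fast
BLAS matmul.  Every layer caches what its backward pass needs during
``forward`` and accumulates parameter gradients into ``.grads`` (aligned
with ``.params``).
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def custom_pad(kernel_size: int) -> tuple[int, int]:
    """Asymmetric 'same' padding: floor(k/2) left, k-1-floor(k/2) right.

    Preserves length exactly for stride-1 convolutions of any kernel size,
    including even ones (where symmetric padding cannot).
    """
    left = kernel_size // 2
    return left, kernel_size - 1 - left


def conv_out_len(length: int, kernel_size: int, stride: int) -> int:
    left, right = custom_pad(kernel_size)
    return (length + left + right - kernel_size) // stride + 1


class Conv1d(Layer):
    """1-D convolution with custom 'same' padding; no bias (BatchNorm follows)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.stride = stride
        self.kernel_size = kernel_size
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel_size))
        self.weight = w.astype(dtype)
        self.params = [self.weight]
        self.grads = [np.zeros_like(self.weight)]

    def _weight_cols(self) -> np.ndarray:
        # (k*c, o) layout matching the im2col column order
        return self.weight.transpose(2, 1, 0).reshape(-1, self.weight.shape[0])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        left, right = custom_pad(self.kernel_size)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))  # (n, lp, c)
        n, lp, c = xp.shape
        l_out = (lp - self.kernel_size) // self.stride + 1
        # im2col: one (n*l_out, k*c) matrix, then a single GEMM
        cols = np.concatenate(
            [
                xp[:, k : k + self.stride * l_out : self.stride, :]
                for k in range(self.kernel_size)
            ],
            axis=2,
        ).reshape(n * l_out, self.kernel_size * c)
        out = cols @ self._weight_cols()
        self._cache = (cols, (n, lp, c), l_out)
        return out.reshape(n, l_out, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, (n, lp, c), l_out = self._cache
        g2 = grad.reshape(n * l_out, -1)
        # dW via one GEMM, then back to (o, c, k)
        dw_cols = cols.T @ g2  # (k*c, o)
        self.grads[0][:] = dw_cols.reshape(self.kernel_size, c, -1).transpose(2, 1, 0)
        dcols = (g2 @ self._weight_cols().T).reshape(
            n, l_out, self.kernel_size, c
        )
        dxp = np.zeros((n, lp, c), dtype=grad.dtype)
        for k in range(self.kernel_size):
            idx = slice(k, k + self.stride * l_out, self.stride)
            dxp[:, idx, :] += dcols[:, :, k, :]
        left, _ = custom_pad(self.kernel_size)
        length = lp - sum(custom_pad(self.kernel_size))
        return dxp[:, left : left + length, :]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over the batch and length axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        self.grads[0][:] = (grad * xhat).sum(axis=(0, 1))
        self.grads[1][:] = grad.sum(axis=(0, 1))
        dxhat = grad * self.gamma
        if not train:
            return dxhat * inv
        m = shape[0] * shape[1]
        return (
            inv
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * (dxhat * xhat).sum(axis=(0, 1))
            )
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class GlobalAvgPool(Layer):
    """(batch, length, channels) -> (batch, channels) mean over length."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, None, :], self._length, axis=1) / self._length


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = rng.uniform(-bound, bound, (in_features, out_features)).astype(dtype)
        self.bias = np.zeros(out_features, dtype=dtype)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][:] = self._x.T @ grad
        self.grads[1][:] = grad.sum(axis=0)
        return grad @ self.weight.T
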