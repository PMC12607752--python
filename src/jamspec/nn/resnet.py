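"""1-D residual network for spectral regression.

Architecture: a custom-padded stem convolution, eight residual blocks with
downsampling (stride 2) at every second block and filter doubling at each
downsampling, global average pooling, and a single-unit linear head.  Each
block is conv-BN-ReLU-dropout-conv-BN plus a skip connection (identity, or a
1x1 strided projection where the shape changes), followed by a final ReLU.

With 204 input bands the four stride-2 stages shrink the length
204 -> 102 -> 51 -> 26 -> 13 before pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    BatchNorm1d,
    Conv1d,
    Dropout,
    GlobalAvgPool,
    Layer,
    Linear,
    ReLU,
    conv_out_len,
)


@dataclass(frozen=True)
class ResNet1DConfig:
    """Hyperparameters of the spectral residual network."""

    n_blocks: int = 8
    base_filters: int = 32
    stem_kernel: int = 7
    block_kernel: int = 3
    downsample_every: int = 2
    dropout_p: float = 0.1
    lr: float = 1e-3
    weight_decay: float = 1e-4
    max_epochs: int = 30
    patience: int = 5
    min_improvement: float = 1e-6
    batch_size: int = 64
    dtype: type = np.float32

    def block_plan(self) -> list[tuple[int, int, int]]:
        """(in_channels, out_channels, stride) per block."""
        plan = []
        channels = self.base_filters
        for i in range(1, self.n_blocks + 1):
            downsample = self.downsample_every > 0 and i % self.downsample_every == 0
            out = channels * 2 if downsample else channels
            plan.append((channels, out, 2 if downsample else 1))
            channels = out
        return plan

    @property
    def n_downsamplings(self) -> int:
        return sum(1 for _, _, s in self.block_plan() if s == 2)

    def min_bands(self) -> int:
        return 2 ** self.n_downsamplings


class ResidualBlock(Layer):
    def __init__(self, cin: int, cout: int, stride: int, cfg: ResNet1DConfig,
                 rng: np.random.Generator) -> None:
        super().__init__()
        k, dt = cfg.block_kernel, cfg.dtype
        self.conv1 = Conv1d(cin, cout, k, stride=stride, rng=rng, dtype=dt)
        self.bn1 = BatchNorm1d(cout, dtype=dt)
        self.relu1 = ReLU()
        self.drop = Dropout(cfg.dropout_p, rng)
        self.conv2 = Conv1d(cout, cout, k, stride=1, rng=rng, dtype=dt)
        self.bn2 = BatchNorm1d(cout, dtype=dt)
        self.relu_out = ReLU()
        if stride != 1 or cin != cout:
            self.proj_conv = Conv1d(cin, cout, 1, stride=stride, rng=rng, dtype=dt)
            self.proj_bn = BatchNorm1d(cout, dtype=dt)
        else:
            self.proj_conv = None
            self.proj_bn = None
        self._sublayers = [
            l
            for l in (self.conv1, self.bn1, self.conv2, self.bn2,
                      self.proj_conv, self.proj_bn)
            if l is not None
        ]
        for l in self._sublayers:
            self.params.extend(l.params)
            self.grads.extend(l.grads)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.drop.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        if self.proj_conv is not None:
            s = self.proj_bn.forward(self.proj_conv.forward(x, train), train)
        else:
            s = x
        return self.relu_out.forward(h + s, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        gh, gs = g, g
        gh = self.bn2.backward(gh)
        gh = self.conv2.backward(gh)
        gh = self.drop.backward(gh)
        gh = self.relu1.backward(gh)
        gh = self.bn1.backward(gh)
        gh = self.conv1.backward(gh)
        if self.proj_conv is not None:
            gs = self.proj_conv.backward(self.proj_bn.backward(gs))
        return gh + gs


class SpectralResNet:
    """The assembled network: (batch, bands) spectra -> (batch,) scalars."""

    def __init__(self, config: ResNet1DConfig, n_bands: int, seed: int = 0) -> None:
        if n_bands < config.min_bands():
            raise ValueError(
                f"need at least {config.min_bands()} bands for "
                f"{config.n_downsamplings} downsamplings, got {n_bands}"
            )
        self.config = config
        self.n_bands = n_bands
        rng = np.random.default_rng(seed)
        dt = config.dtype
        self.stem = Conv1d(1, config.base_filters, config.stem_kernel, rng=rng, dtype=dt)
        self.stem_bn = BatchNorm1d(config.base_filters, dtype=dt)
        self.stem_relu = ReLU()
        self.blocks = [
            ResidualBlock(cin, cout, stride, config, rng)
            for cin, cout, stride in config.block_plan()
        ]
        self.gap = GlobalAvgPool()
        final_channels = config.block_plan()[-1][1]
        self.head = Linear(final_channels, 1, rng=rng, dtype=dt)
        self._layers: list[Layer] = [self.stem, self.stem_bn, *self.blocks, self.head]

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for l in self._layers for p in l.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for l in self._layers for g in l.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state(self) -> list[np.ndarray]:
        extras = []
        for l in self._iter_bn():
            extras.extend([l.running_mean, l.running_var])
        return [p.copy() for p in self.parameters() + extras]

    def load_state(self, state: list[np.ndarray]) -> None:
        extras = []
        for l in self._iter_bn():
            extras.extend([l.running_mean, l.running_var])
        for dst, src in zip(self.parameters() + extras, state, strict=True):
            dst[:] = src

    def _iter_bn(self):
        yield self.stem_bn
        for b in self.blocks:
            yield b.bn1
            yield b.bn2
            if b.proj_bn is not None:
                yield b.proj_bn

    # -- computation --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (batch, bands) -> (batch,) predictions."""
        h = np.ascontiguousarray(x, dtype=self.config.dtype)[:, :, None]
        h = self.stem.forward(h, train)
        h = self.stem_bn.forward(h, train)
        h = self.stem_relu.forward(h, train)
        for block in self.blocks:
            h = block.forward(h, train)
        h = self.gap.forward(h, train)
        return self.head.forward(h, train)[:, 0]

    def backward(self, grad_out: np.ndarray) -> None:
        g = self.head.backward(grad_out[:, None])
        g = self.gap.backward(g)
        for block in reversed(self.blocks):
            g = block.backward(g)
        g = self.stem_relu.backward(g)
        g = self.stem_bn.backward(g)
        self.stem.backward(g)

    def output_length(self) -> int:
        """Temporal length reaching the pooling layer."""
        length = conv_out_len(self.n_bands, self.config.stem_kernel, 1)
        for _, _, stride in self.config.block_plan():
            length = conv_out_len(length, self.config.block_kernel, stride)
        return length


def build_resnet1d(
    config: ResNet1DConfig | None = None, n_bands: int = 204, seed: int = 0
) -> SpectralResNet:
    return SpectralResNet(config or ResNet1DConfig(), n_bands, seed=seed)
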