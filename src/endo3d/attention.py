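"""Convolutional Block Attention Module (CBAM).

Sequential refinement of a feature map F: channel attention first,

    Mc(F) = sigmoid( MLP(AvgPool(F)) + MLP(MaxPool(F)) ),   F' = Mc x F,

with a shared two-layer bottleneck MLP (reduction ratio r, ReLU after the
first layer), then spatial attention,

    Ms(F') = sigmoid( conv7x7([mean_c F'; max_c F']) ),     F'' = Ms x F',

a 7x7 convolution over the channel-pooled mean/max maps.  Both gates lie
strictly in (0, 1), so refined features never exceed the input in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .nn import Conv2d, Linear, Module


@dataclass(frozen=True)
class CBAMConfig:
    reduction_ratio: int = 16
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.reduction_ratio < 1:
            raise ValueError("reduction ratio must be >= 1")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial kernel must be odd")


class ChannelAttention(Module):
    def __init__(self, channels: int, cfg: CBAMConfig = CBAMConfig(),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // min(cfg.reduction_ratio, channels))
        self.fc1 = Linear(channels, hidden, rng=rng, bias=False)
        self.fc2 = Linear(hidden, channels, rng=rng, bias=False)

    def forward(self, f: Tensor) -> Tensor:
        """Per-channel gate Mc of shape (N, C, 1, 1)."""
        n, c = f.shape[:2]
        flat = f.reshape(n, c, -1)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        logits = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return logits.sigmoid().reshape(n, c, 1, 1)


class SpatialAttention(Module):
    def __init__(self, cfg: CBAMConfig = CBAMConfig(),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        k = cfg.spatial_kernel
        self.conv = Conv2d(2, 1, k, padding=k // 2, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        """Per-pixel gate Ms of shape (N, 1, H, W)."""
        avg = f.mean(axis=1, keepdims=True)
        mx = f.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()


class CBAM(Module):
    """F'' = Ms(Mc(F) x F) x (Mc(F) x F); ``force_value`` is a test hook
    replacing both gates by a constant."""

    def __init__(self, channels: int, cfg: CBAMConfig = CBAMConfig(),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.channel = ChannelAttention(channels, cfg, rng)
        self.spatial = SpatialAttention(cfg, rng)
        self.force_value: float | None = None

    def forward(self, f: Tensor) -> Tensor:
        if self.force_value is not None:
            return f * self.force_value * self.force_value
        f1 = f * self.channel(f)
        return f1 * self.spatial(f1)


def channel_attention(f: Tensor, module: ChannelAttention) -> Tensor:
    return module(f)


def spatial_attention(f: Tensor, module: SpatialAttention) -> Tensor:
    return module(f)


def cbam(f: Tensor, module: CBAM) -> Tensor:
    return module(f)
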