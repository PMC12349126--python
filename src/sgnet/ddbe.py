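"""Dual-Domain Boundary Enhancer.

Each pyramid level is projected to 96 channels (1x1 conv + batch norm +
GELU), split evenly into a spatial branch (3x3 conv on the first 48
channels) and a frequency branch (learnable complex-valued filter applied to
the 2D Fourier transform of the last 48 channels), refused by a grouped-conv
fusion block, and residually added back to the unified feature:

    X_out = Fuse(concat(X_spatial, X_freq)) + X_init

The frequency filter is per-channel and per-level (spatial dims differ
across levels) and is initialised to 1 + 0i so that branch starts as an
exact identity.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn.autograd import concat
from .nn.fourier import frequency_filter

UNIFIED_CHANNELS = 96
BRANCH_CHANNELS = 48


class FrequencyFilter(nn.Module):
    """Learnable complex half-spectrum weight map W_f(u, v) for 48 channels."""

    def __init__(self, channels: int, height: int, width: int):
        super().__init__()
        wh = width // 2 + 1
        self.weight_real = nn.Parameter(
            np.ones((channels, height, wh), dtype=np.float32))
        self.weight_imag = nn.Parameter(
            np.zeros((channels, height, wh), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return frequency_filter(x, self.weight_real, self.weight_imag)


class ChannelUnify(nn.Module):
    """1x1 conv -> batch norm -> GELU mapping any pyramid width to 96."""

    def __init__(self, in_channels: int):
        super().__init__()
        if in_channels not in (96, 192, 384, 768):
            raise ValueError(
                f"unexpected pyramid channel count {in_channels}; expected "
                f"one of (96, 192, 384, 768)")
        self.proj = nn.Conv2d(in_channels, UNIFIED_CHANNELS, 1)
        self.norm = nn.BatchNorm2d(UNIFIED_CHANNELS)

    def forward(self, x: Tensor) -> Tensor:
        return nn.gelu(self.norm(self.proj(x)))


class DDBE(nn.Module):
    """Boundary enhancer for one pyramid level of known spatial size."""

    def __init__(self, in_channels: int, height: int, width: int,
                 groups: int = 4):
        super().__init__()
        self.height, self.width = height, width
        self.unify = ChannelUnify(in_channels)
        self.spatial = nn.Sequential(
            nn.Conv2d(BRANCH_CHANNELS, BRANCH_CHANNELS, 3, padding=1),
            nn.BatchNorm2d(BRANCH_CHANNELS), nn.GELU())
        self.freq_filter = FrequencyFilter(BRANCH_CHANNELS, height, width)
        self.fuse = nn.Sequential(
            nn.Conv2d(UNIFIED_CHANNELS, UNIFIED_CHANNELS, 3, padding=1,
                      groups=groups),
            nn.BatchNorm2d(UNIFIED_CHANNELS), nn.GELU(),
            nn.Conv2d(UNIFIED_CHANNELS, UNIFIED_CHANNELS, 1))

    def frequency_branch(self, x_f: Tensor) -> Tensor:
        """RFFT -> learnable complex modulation -> inverse transform."""
        _, _, h, w = x_f.shape
        if (h, w) != (self.height, self.width):
            raise ValueError(
                f"frequency branch built for {(self.height, self.width)} "
                f"inputs, got {(h, w)}; rebuild the model for this size")
        return self.freq_filter(x_f)

    def forward(self, level_feature: Tensor) -> Tensor:
        x_init = self.unify(level_feature)
        x_spatial = self.spatial(x_init[:, :BRANCH_CHANNELS])
        x_freq = self.frequency_branch(x_init[:, BRANCH_CHANNELS:])
        fused = self.fuse(concat([x_spatial, x_freq], axis=1))
        return fused + x_init
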