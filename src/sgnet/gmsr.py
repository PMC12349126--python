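"""Guided Multi-Scale Refiner.

One refiner stage takes a fused 96-channel feature and the previous-stage
prediction map p (logits at the same or coarser resolution):

1. sigmoid(p) is resized to the feature grid and concatenated with the
   feature (97 channels); a small conv stack emits three single-channel
   sigmoid attention maps, one per kernel scale k in {1, 3, 5};
2. each attention map gates the output of the corresponding conv branch:
   F^k = attn_k * Conv_k(F);
3. the three gated features are concatenated (288 channels), globally
   average-pooled to a channel-semantic vector g, and a two-layer 1x1
   bottleneck (reduction 8) produces softmax fusion weights W in R^3:
   F_hat = sum_s W_s * F^(k_s);
4. a two-layer conv head maps F_hat to a single-channel stage map; the next
   guidance is the residual update p_next = head(F_hat) + resize(p).

Stages run coarse-to-fine (deepest feature first, guided by the coarse map),
and each stage map doubles as a deep-supervision output.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn.autograd import concat
from .nn.functional import global_avg_pool
from .nn.interpolate import resize_bilinear

C = 96
KERNELS = (1, 3, 5)
REDUCTION = 8


class ScaleAttention(nn.Module):
    """Prediction-guided extraction of the three per-scale gates."""

    def __init__(self):
        super().__init__()
        self.conv1 = nn.Conv2d(C + 1, 48, 3, padding=1)
        self.conv2 = nn.Conv2d(48, len(KERNELS), 3, padding=1)
        for i, k in enumerate(KERNELS):
            setattr(self, f"branch{i}",
                    nn.Conv2d(C, C, k, padding=k // 2))

    def forward(self, feature: Tensor, p: Tensor) -> tuple[Tensor, ...]:
        _, _, h, w = feature.shape
        if p.shape[2:] != (h, w):
            raise ValueError(f"guidance map at {tuple(p.shape[2:])} does not "
                             f"match feature grid {(h, w)}")
        gates = nn.sigmoid(self.conv2(nn.relu(
            self.conv1(concat([nn.sigmoid(p), feature], axis=1)))))
        return tuple(
            gates[:, i:i + 1] * getattr(self, f"branch{i}")(feature)
            for i in range(len(KERNELS)))


class ScaleFusion(nn.Module):
    """Channel-semantic softmax weighting of the three scale branches."""

    def __init__(self):
        super().__init__()
        hidden = len(KERNELS) * C // REDUCTION
        self.fc1 = nn.Conv2d(len(KERNELS) * C, hidden, 1)
        self.fc2 = nn.Conv2d(hidden, len(KERNELS), 1)

    def fusion_weights(self, f1: Tensor, f3: Tensor, f5: Tensor) -> Tensor:
        g = global_avg_pool(concat([f1, f3, f5], axis=1))    # B,288,1,1
        return nn.softmax(self.fc2(nn.relu(self.fc1(g))), axis=1)  # B,3,1,1

    def forward(self, f1: Tensor, f3: Tensor, f5: Tensor) -> Tensor:
        w = self.fusion_weights(f1, f3, f5)
        return w[:, 0:1] * f1 + w[:, 1:2] * f3 + w[:, 2:3] * f5


class RefinerStage(nn.Module):
    def __init__(self):
        super().__init__()
        self.scale_attention = ScaleAttention()
        self.fusion = ScaleFusion()
        self.head1 = nn.Conv2d(C, 48, 3, padding=1)
        self.head_norm = nn.BatchNorm2d(48)
        self.head2 = nn.Conv2d(48, 1, 1)

    def forward(self, feature: Tensor, p_prev: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (stage_map, p_next), both logits at the feature grid."""
        _, _, h, w = feature.shape
        p = resize_bilinear(p_prev, h, w)
        branches = self.scale_attention(feature, p)
        f_hat = self.fusion(*branches)
        stage_map = self.head2(nn.relu(self.head_norm(self.head1(f_hat))))
        return stage_map, stage_map + p


class GMSR(nn.Module):
    """Three chained refiner stages, deepest feature first."""

    def __init__(self):
        super().__init__()
        self.stage3 = RefinerStage()   # acts on F_out3 (stride 32)
        self.stage2 = RefinerStage()   # acts on F_out2 (stride 16)
        self.stage1 = RefinerStage()   # acts on F_out1 (stride 8)

    def forward(self, fout1: Tensor, fout2: Tensor, fout3: Tensor,
                coarse: Tensor) -> tuple[list, Tensor]:
        """Returns ([map3, map2, map1] coarse-to-fine, final guidance)."""
        m3, p = self.stage3(fout3, coarse)
        m2, p = self.stage2(fout2, p)
        m1, p = self.stage1(fout1, p)
        return [m3, m2, m1], p
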