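"""Semantic-Texture Fusion Unit.

Fuses an adjacent (shallow, deep) pair of boundary-enhanced features:

1. *align*: the shallow feature is 2x2 average-pooled to the deep
   resolution; both are passed through phi = 1x1 conv + batch norm + ReLU.
2. *triplet attention* on the concatenated pair (reduced back to 96
   channels): three branches capture (C,H), (C,W) and (H,W) interactions by
   axis rotation, Z-pooling (max + mean over the rotated leading axis), a
   7x7 gating convolution and a sigmoid gate; branch outputs are averaged.
3. *CoupleConv*: K grouped-conv branches with distinct kernel sizes, summed
   with softmax-normalised learnable weights alpha_k.
4. weighted residual aggregation with softmax weights (omega_1, omega_2):

   F_out = F_multi + omega_1 * X_i' + omega_2 * X_{i+1}'

The softmax constraints (sum alpha = 1, omega_1 + omega_2 = 1) hold by
construction at every forward pass because the raw parameters are
unconstrained logits.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn.autograd import concat

C = 96


class TripletAttention(nn.Module):
    """Rotate-to-axis-pair attention with Z-pool gates (kernel size 7)."""

    def __init__(self, kernel_size: int = 7):
        super().__init__()
        p = kernel_size // 2
        self.conv_cw = nn.Conv2d(2, 1, kernel_size, padding=p)
        self.conv_ch = nn.Conv2d(2, 1, kernel_size, padding=p)
        self.conv_hw = nn.Conv2d(2, 1, kernel_size, padding=p)

    @staticmethod
    def _gate(x: Tensor, conv: nn.Conv2d) -> Tensor:
        return x * nn.sigmoid(conv(nn.zpool(x, axis=1)))

    def forward(self, x: Tensor) -> Tensor:
        # branch 1: (H, C) interaction — rotate H into the pooled axis
        xh = x.transpose(0, 2, 1, 3)
        bh = self._gate(xh, self.conv_ch).transpose(0, 2, 1, 3)
        # branch 2: (W, C) interaction
        xw = x.transpose(0, 3, 2, 1)
        bw = self._gate(xw, self.conv_cw).transpose(0, 3, 2, 1)
        # branch 3: plain spatial attention over (H, W)
        bs = self._gate(x, self.conv_hw)
        return (bh + bw + bs) * (1.0 / 3.0)


class CoupleConv(nn.Module):
    """Multi-kernel grouped-conv branches fused by softmax weights."""

    def __init__(self, channels: int = C, kernels: tuple = (1, 3, 5),
                 groups: int = 4):
        super().__init__()
        if channels % groups:
            raise ValueError(
                f"{channels} channels not divisible by groups={groups}")
        self.kernels = tuple(kernels)
        for i, k in enumerate(self.kernels):
            setattr(self, f"branch{i}",
                    nn.Conv2d(channels, channels, k, padding=k // 2,
                              groups=groups))
        self.alpha_logits = nn.Parameter(
            np.zeros(len(self.kernels), dtype=np.float32))

    def branch_weights(self) -> Tensor:
        return nn.softmax(self.alpha_logits, axis=0)

    def forward(self, f_attn: Tensor) -> Tensor:
        alpha = self.branch_weights()
        out = None
        for i in range(len(self.kernels)):
            term = alpha[i] * getattr(self, f"branch{i}")(f_attn)
            out = term if out is None else out + term
        return out


class _Phi(nn.Module):
    """1x1 conv + batch norm + ReLU alignment transform."""

    def __init__(self, channels: int = C):
        super().__init__()
        self.proj = nn.Conv2d(channels, channels, 1)
        self.norm = nn.BatchNorm2d(channels)

    def forward(self, x):
        return nn.relu(self.norm(self.proj(x)))


class STFU(nn.Module):
    def __init__(self, kernels: tuple = (1, 3, 5), groups: int = 4):
        super().__init__()
        self.phi_shallow = _Phi()
        self.phi_deep = _Phi()
        self.pair_reduce = nn.Sequential(
            nn.Conv2d(2 * C, C, 1), nn.BatchNorm2d(C), nn.ReLU())
        self.attention = TripletAttention()
        self.couple = CoupleConv(C, kernels, groups)
        self.omega_logits = nn.Parameter(np.zeros(2, dtype=np.float32))

    def residual_weights(self) -> Tensor:
        return nn.softmax(self.omega_logits, axis=0)

    def align(self, shallow: Tensor, deep: Tensor) -> tuple[Tensor, Tensor]:
        _, _, hs, ws = shallow.shape
        _, _, hd, wd = deep.shape
        if (hs, ws) != (2 * hd, 2 * wd):
            raise ValueError(
                f"shallow spatial dims {(hs, ws)} must be exactly twice the "
                f"deep dims {(hd, wd)}")
        x_i = self.phi_shallow(nn.avg_pool2d(shallow, 2))
        x_ip1 = self.phi_deep(deep)
        return x_i, x_ip1

    def forward(self, shallow: Tensor, deep: Tensor) -> Tensor:
        x_i, x_ip1 = self.align(shallow, deep)
        f_attn = self.attention(self.pair_reduce(concat([x_i, x_ip1], axis=1)))
        f_multi = self.couple(f_attn)
        omega = self.residual_weights()
        return f_multi + omega[0] * x_i + omega[1] * x_ip1
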