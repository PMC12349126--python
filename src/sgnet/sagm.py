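"""Structure-Aware Guidance Module.

Aggregates the three fused features (at strides 8/16/32) into a
full-resolution coarse segmentation map:

* per-input 3x3 conv alignment, bilinear upsampling of the two deeper
  features to the shallow (stride-8) grid;
* a boundary-attention branch on the shallow feature (cascaded 3x3 convs +
  sigmoid) multiplying it channel-broadcast: F1_enh = F1 * A_bnd;
* a global-guidance vector from the deepest feature (global average pooling
  + 1x1 conv) broadcast spatially;
* additive fusion F_fused = Up(F2) + Up(F3) + F1_enh + F_glo, convolutional
  refinement, then exactly three stride-2 transposed convolutions
  (kernel 4, padding 1; channels 96 -> 64 -> 32 -> 1) to reach the input
  resolution.  The output is a logit map.
"""

from __future__ import annotations

from . import nn
from .nn import Tensor
from .nn.functional import global_avg_pool
from .nn.interpolate import resize_bilinear

C = 96


class BoundaryAttention(nn.Module):
    """Two cascaded 3x3 convs + sigmoid producing a single-channel gate."""

    def __init__(self):
        super().__init__()
        self.conv1 = nn.Conv2d(C, 48, 3, padding=1)
        self.norm = nn.BatchNorm2d(48)
        self.conv2 = nn.Conv2d(48, 1, 3, padding=1)

    def forward(self, fout1: Tensor) -> Tensor:
        return nn.sigmoid(self.conv2(nn.relu(self.norm(self.conv1(fout1)))))


class GlobalGuidance(nn.Module):
    """Global average pooling + 1x1 projection, broadcast spatially."""

    def __init__(self):
        super().__init__()
        self.proj = nn.Conv2d(C, C, 1)

    def forward(self, fout3: Tensor, out_h: int, out_w: int) -> Tensor:
        b = fout3.shape[0]
        vec = self.proj(global_avg_pool(fout3))          # B,C,1,1
        return vec.broadcast_to((b, C, out_h, out_w))


class SAGM(nn.Module):
    def __init__(self):
        super().__init__()
        self.align1 = nn.Sequential(nn.Conv2d(C, C, 3, padding=1),
                                    nn.BatchNorm2d(C), nn.ReLU())
        self.align2 = nn.Sequential(nn.Conv2d(C, C, 3, padding=1),
                                    nn.BatchNorm2d(C), nn.ReLU())
        self.align3 = nn.Sequential(nn.Conv2d(C, C, 3, padding=1),
                                    nn.BatchNorm2d(C), nn.ReLU())
        self.boundary = BoundaryAttention()
        self.global_guidance = GlobalGuidance()
        self.refine = nn.Sequential(nn.Conv2d(C, C, 3, padding=1),
                                    nn.BatchNorm2d(C), nn.ReLU())
        self.up1 = nn.ConvTranspose2d(C, 64, 4, stride=2, padding=1)
        self.up1_norm = nn.BatchNorm2d(64)
        self.up2 = nn.ConvTranspose2d(64, 32, 4, stride=2, padding=1)
        self.up2_norm = nn.BatchNorm2d(32)
        self.up3 = nn.ConvTranspose2d(32, 1, 4, stride=2, padding=1)
        self.num_upsample_stages = 3

    def forward(self, fout1: Tensor, fout2: Tensor, fout3: Tensor) -> Tensor:
        _, _, h1, w1 = fout1.shape
        _, _, h2, w2 = fout2.shape
        _, _, h3, w3 = fout3.shape
        if (h2 * 2, w2 * 2) != (h1, w1) or (h3 * 4, w3 * 4) != (h1, w1):
            raise ValueError(
                f"fused features must arrive at strides 8/16/32; got "
                f"{(h1, w1)}, {(h2, w2)}, {(h3, w3)}")
        f1 = self.align1(fout1)
        f2 = self.align2(fout2)
        f3 = self.align3(fout3)
        a_bnd = self.boundary(f1)
        f1_enh = f1 * a_bnd
        f_glo = self.global_guidance(f3, h1, w1)
        f_fused = resize_bilinear(f2, h1, w1) + resize_bilinear(f3, h1, w1) \
            + f1_enh + f_glo
        x = self.refine(f_fused)
        x = nn.relu(self.up1_norm(self.up1(x)))
        x = nn.relu(self.up2_norm(self.up2(x)))
        return self.up3(x)
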