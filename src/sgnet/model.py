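"""Full network assembly: encoder + DDBE + STFU + SAGM + GMSR.

The model is built for a fixed input resolution (default 256, any multiple
of 32) because the DDBE frequency filters are sized per pyramid level.  All
computation is deterministic given fixed weights — there are no stochastic
layers and every kernel is a deterministic numpy routine — so repeated
forward passes are bitwise identical.

Ablation toggles mirror the module-contribution study: with a module
disabled, shape-preserving projections keep the downstream contract intact
(channel-unifying 1x1 convs in place of DDBE/STFU, a plain conv head in
place of SAGM+GMSR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import CHANNELS, EncoderConfig, build_encoder
from .ddbe import DDBE, ChannelUnify
from .gmsr import GMSR
from .nn import Tensor
from .nn.functional import bce_dice
from .nn.interpolate import resize_bilinear
from .sagm import SAGM
from .stfu import STFU


@dataclass
class AblationFlags:
    use_ddbe: bool = True
    use_stfu: bool = True
    use_gmsr_sagm: bool = True


@dataclass
class SGNetOutput:
    """All supervised prediction maps (logits)."""

    final: Tensor            # (B,1,H,W)
    coarse: Tensor           # (B,1,H,W)
    stage_maps: list         # three maps, strictly increasing resolution

    def __post_init__(self):
        if self.final.shape != self.coarse.shape:
            raise ValueError("final and coarse maps must share shape")
        res = [m.shape[2] for m in self.stage_maps]
        if len(res) != 3 or any(a >= b for a, b in zip(res, res[1:])):
            raise ValueError(
                f"stage map resolutions must strictly increase, got {res}")

    def all_maps(self) -> list:
        return [self.final, self.coarse, *self.stage_maps]


class _FallbackFuse(nn.Module):
    """Shape-preserving stand-in for STFU: non-adaptive concat-projection
    of the pooled shallow and the deep level."""

    def __init__(self):
        super().__init__()
        self.proj = nn.Conv2d(192, 96, 1)
        self.norm = nn.BatchNorm2d(96)

    def forward(self, shallow, deep):
        pooled = nn.avg_pool2d(shallow, 2)
        return nn.relu(self.norm(self.proj(
            nn.concat([pooled, deep], axis=1))))


class _PlainHead(nn.Module):
    """Minimal decoder head used when SAGM+GMSR are ablated."""

    def __init__(self):
        super().__init__()
        self.conv1 = nn.Conv2d(96, 48, 3, padding=1)
        self.norm = nn.BatchNorm2d(48)
        self.conv2 = nn.Conv2d(48, 1, 1)
        self.aux2 = nn.Conv2d(96, 1, 1)
        self.aux3 = nn.Conv2d(96, 1, 1)

    def forward(self, fout1, fout2, fout3):
        main = self.conv2(nn.relu(self.norm(self.conv1(fout1))))
        return main, self.aux2(fout2), self.aux3(fout3)


class SGNet(nn.Module):
    def __init__(self, input_size: int = 256,
                 encoder_config: EncoderConfig | None = None,
                 flags: AblationFlags | None = None,
                 couple_kernels: tuple = (1, 3, 5), ddbe_groups: int = 4):
        super().__init__()
        if input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        self.input_size = input_size
        self.encoder_config = encoder_config or EncoderConfig()
        self.flags = flags or AblationFlags()
        self.encoder = build_encoder(self.encoder_config)

        sizes = [input_size // (4 * 2 ** i) for i in range(4)]
        for i in range(4):
            enh = (DDBE(CHANNELS[i], sizes[i], sizes[i], groups=ddbe_groups)
                   if self.flags.use_ddbe else ChannelUnify(CHANNELS[i]))
            setattr(self, f"enhance{i + 1}", enh)
        for i in range(3):
            fuse = (STFU(kernels=couple_kernels)
                    if self.flags.use_stfu else _FallbackFuse())
            setattr(self, f"fuse{i + 1}", fuse)
        if self.flags.use_gmsr_sagm:
            self.sagm = SAGM()
            self.gmsr = GMSR()
        else:
            self.head = _PlainHead()

    def forward(self, image: Tensor) -> SGNetOutput:
        h = image.shape[2]
        if h != self.input_size or image.shape[3] != self.input_size:
            raise ValueError(
                f"model built for {self.input_size}x{self.input_size} input, "
                f"got {tuple(image.shape[2:])}")
        pyramid = self.encoder(image)
        enhanced = [getattr(self, f"enhance{i + 1}")(lvl)
                    for i, lvl in enumerate(pyramid.levels)]
        fouts = [getattr(self, f"fuse{i + 1}")(enhanced[i], enhanced[i + 1])
                 for i in range(3)]
        if self.flags.use_gmsr_sagm:
            coarse = self.sagm(*fouts)
            stage_maps, p = self.gmsr(*fouts, coarse)
            final = resize_bilinear(p, h, h)
        else:
            main, aux2, aux3 = self.head(*fouts)
            final = resize_bilinear(main, h, h)
            coarse = final
            stage_maps = [aux3, aux2, main]
        return SGNetOutput(final=final, coarse=coarse, stage_maps=stage_maps)


def bce_dice_loss(outputs: SGNetOutput, mask: Tensor | np.ndarray,
                  smooth: float = 1e-5) -> Tensor:
    """Deeply supervised BCE + soft-Dice loss.

    Every supervised map (final, coarse, three stage maps) is bilinearly
    upsampled to the mask resolution and compared against the binary mask
    with equal weights.
    """
    mask = nn.as_tensor(mask)
    vals = np.unique(mask.data)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError(f"mask must be binary {{0,1}}, found values {vals[:5]}")
    h, w = mask.shape[2], mask.shape[3]
    loss = None
    for m in outputs.all_maps():
        term = bce_dice(resize_bilinear(m, h, w), mask, smooth)
        loss = term if loss is None else loss + term
    return loss
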