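"""Four-level feature-pyramid encoders.

Two interchangeable variants satisfy the same contract — channels
(96, 192, 384, 768) at strides 4/8/16/32:

* ``vmamba_tiny``: a visual state-space encoder.  Patch embedding (4x4), four
  stages of VSS blocks (depths 2/2/9/2) joined by 2x2 patch-merging
  downsampling.  Each VSS block wraps an SS2D mixer: a selective state-space
  scan applied along four spatial traversal orders (row-major and
  column-major, each forward and reversed) so the 1D recurrence gains a
  non-causal 2D receptive field.
* ``test_conv``: strided convolution stages with the same pyramid contract,
  for fast training and CI.

The state-space hyperparameters the backbone's citation chain leaves open
(expansion ratio, delta-projection rank) default to expansion 2 and
dt_rank = 3C/16, a configuration consistent with the published parameter
budget of the full network; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .nn.autograd import stack
from .nn.functional import add_macs
from .nn.ssm import selective_scan

CHANNELS = (96, 192, 384, 768)


@dataclass
class EncoderConfig:
    variant: str = "vmamba_tiny"
    stage_depths: tuple[int, int, int, int] = (2, 2, 9, 2)
    state_dim: int = 16
    patch_size: int = 4
    expansion_ratio: float = 2.0

    def __post_init__(self):
        if self.variant not in ("vmamba_tiny", "test_conv"):
            raise ValueError(f"unknown encoder variant {self.variant!r}")
        if len(self.stage_depths) != 4 or any(d < 1 for d in self.stage_depths):
            raise ValueError("stage_depths must be four integers >= 1")


@dataclass
class FeaturePyramid:
    """Four feature maps at strides 4/8/16/32 with fixed channel widths."""

    levels: list
    channels: tuple = CHANNELS

    def __post_init__(self):
        if len(self.levels) != 4:
            raise ValueError(f"expected 4 pyramid levels, got {len(self.levels)}")
        prev_hw = None
        for i, (lvl, c) in enumerate(zip(self.levels, self.channels)):
            b, ci, h, w = lvl.shape
            if ci != c:
                raise ValueError(f"level {i + 1} has {ci} channels, expected {c}")
            if prev_hw is not None and (h * 2, w * 2) != prev_hw:
                raise ValueError(
                    f"level {i + 1} spatial dims {(h, w)} do not halve "
                    f"the previous level's {prev_hw}")
            if not np.isfinite(lvl.data).all():
                raise ValueError(f"level {i + 1} contains non-finite values")
            prev_hw = (h, w)


def _dt_rank(dim: int) -> int:
    return max(1, (3 * dim) // 16)


class SS2D(nn.Module):
    """2D selective-scan mixer with four-directional cross-scanning."""

    def __init__(self, dim: int, state_dim: int = 16, expand: float = 2.0,
                 dt_min: float = 1e-3, dt_max: float = 0.1):
        super().__init__()
        self.dim = dim
        self.d_inner = int(expand * dim)
        self.n = state_dim
        self.r = _dt_rank(dim)
        d_in, n, r = self.d_inner, self.n, self.r

        self.in_proj = nn.Conv2d(dim, 2 * d_in, 1, bias=False)
        self.dwconv = nn.Conv2d(d_in, d_in, 3, padding=1, groups=d_in)
        self.x_proj_weight = nn.Parameter(
            nn.init.trunc_normal((4, r + 2 * n, d_in)))
        self.dt_proj_weight = nn.Parameter(
            (nn.init.rng().uniform(-1, 1, (4, d_in, r)) * r ** -0.5)
            .astype(np.float32))
        # initialise so softplus(bias) falls in [dt_min, dt_max]
        dt = np.exp(nn.init.rng().uniform(np.log(dt_min), np.log(dt_max),
                                          (4, d_in)))
        self.dt_bias = nn.Parameter(
            (dt + np.log(-np.expm1(-dt))).astype(np.float32))
        a = np.tile(np.arange(1, n + 1, dtype=np.float32), (4, d_in, 1))
        self.A_log = nn.Parameter(np.log(a))
        self.Ds = nn.Parameter(np.ones((4, d_in), dtype=np.float32))
        self.out_norm = nn.LayerNorm2d(d_in)
        self.out_proj = nn.Conv2d(d_in, dim, 1, bias=False)

    @staticmethod
    def cross_scan(x: Tensor) -> Tensor:
        """Serialise NCHW features along the four traversal orders.

        Direction 0: row-major forward; 1: column-major forward;
        2, 3: their reversals.  Returns (B, 4, C, H*W)."""
        b, c, h, w = x.shape
        d0 = x.reshape(b, c, h * w)
        d1 = x.transpose(0, 1, 3, 2).reshape(b, c, h * w)
        return stack([d0, d1, d0.flip(2), d1.flip(2)], axis=1)

    @staticmethod
    def cross_merge(ys: Tensor, h: int, w: int) -> Tensor:
        """Invert the four scans of :meth:`cross_scan` and sum. ys: (B,4,C,L)."""
        b, _, c, l = ys.shape
        ya = (ys[:, 0] + ys[:, 2].flip(2)).reshape(b, c, h, w)
        yb = (ys[:, 1] + ys[:, 3].flip(2)).reshape(b, c, w, h) \
            .transpose(0, 1, 3, 2)
        return ya + yb

    def forward(self, x: Tensor) -> Tensor:
        b, _, h, w = x.shape
        d_in, n, r, l = self.d_inner, self.n, self.r, h * w
        xz = self.in_proj(x)
        x1, z = xz[:, :d_in], xz[:, d_in:]
        x1 = nn.silu(self.dwconv(x1))

        xs = self.cross_scan(x1)                              # B,4,D,L
        proj = self.x_proj_weight @ xs                        # B,4,R+2N,L
        add_macs(b * 4 * (r + 2 * n) * d_in * l)
        dt_raw, bc, cc = proj[:, :, :r], proj[:, :, r:r + n], proj[:, :, r + n:]
        dt = self.dt_proj_weight @ dt_raw                     # B,4,D,L
        add_macs(b * 4 * d_in * r * l)
        dt = nn.softplus(dt + self.dt_bias.reshape(1, 4, d_in, 1))

        a = -(self.A_log.exp())
        ys = selective_scan(
            xs.reshape(b * 4, d_in, l),
            dt.reshape(b * 4, d_in, l),
            a.broadcast_to((b, 4, d_in, n)).reshape(b * 4, d_in, n),
            bc.reshape(b * 4, n, l),
            cc.reshape(b * 4, n, l),
            self.Ds.broadcast_to((b, 4, d_in)).reshape(b * 4, d_in),
        ).reshape(b, 4, d_in, l)

        y = self.cross_merge(ys, h, w)
        y = self.out_norm(y) * nn.silu(z)
        return self.out_proj(y)


class VSSBlock(nn.Module):
    def __init__(self, dim: int, state_dim: int, expand: float):
        super().__init__()
        self.norm = nn.LayerNorm2d(dim)
        self.mixer = SS2D(dim, state_dim=state_dim, expand=expand)

    def forward(self, x):
        return x + self.mixer(self.norm(x))


class PatchMerging(nn.Module):
    """2x2 neighbourhood concat -> layer norm -> linear projection to 2C."""

    def __init__(self, dim: int):
        super().__init__()
        self.norm = nn.LayerNorm2d(4 * dim)
        self.reduction = nn.Conv2d(4 * dim, 2 * dim, 1, bias=False)

    def forward(self, x):
        b, c, h, w = x.shape
        x = x.reshape(b, c, h // 2, 2, w // 2, 2) \
             .transpose(0, 1, 3, 5, 2, 4) \
             .reshape(b, 4 * c, h // 2, w // 2)
        return self.reduction(self.norm(x))


class VMambaEncoder(nn.Module):
    def __init__(self, config: EncoderConfig):
        super().__init__()
        self.config = config
        ps = config.patch_size
        self.patch_embed = nn.Conv2d(3, CHANNELS[0], ps, stride=ps)
        self.patch_norm = nn.LayerNorm2d(CHANNELS[0])
        for i, depth in enumerate(config.stage_depths):
            blocks = nn.Sequential(*[
                VSSBlock(CHANNELS[i], config.state_dim, config.expansion_ratio)
                for _ in range(depth)])
            setattr(self, f"stage{i + 1}", blocks)
            if i < 3:
                setattr(self, f"merge{i + 1}", PatchMerging(CHANNELS[i]))

    def forward(self, image: Tensor) -> FeaturePyramid:
        _check_input(image)
        x = self.patch_norm(self.patch_embed(image))
        levels = []
        for i in range(4):
            x = getattr(self, f"stage{i + 1}")(x)
            levels.append(x)
            if i < 3:
                x = getattr(self, f"merge{i + 1}")(x)
        return FeaturePyramid(levels)


class TestConvEncoder(nn.Module):
    """Cheap strided-conv encoder honouring the pyramid contract."""

    def __init__(self, config: EncoderConfig | None = None):
        super().__init__()
        self.config = config or EncoderConfig(variant="test_conv")
        self.stem = nn.Sequential(
            nn.Conv2d(3, CHANNELS[0], 4, stride=4),
            nn.BatchNorm2d(CHANNELS[0]), nn.GELU(),
            nn.Conv2d(CHANNELS[0], CHANNELS[0], 3, padding=1),
            nn.BatchNorm2d(CHANNELS[0]), nn.GELU())
        for i in range(1, 4):
            setattr(self, f"down{i}", nn.Sequential(
                nn.Conv2d(CHANNELS[i - 1], CHANNELS[i], 3, stride=2, padding=1),
                nn.BatchNorm2d(CHANNELS[i]), nn.GELU(),
                nn.Conv2d(CHANNELS[i], CHANNELS[i], 3, padding=1),
                nn.BatchNorm2d(CHANNELS[i]), nn.GELU()))

    def forward(self, image: Tensor) -> FeaturePyramid:
        _check_input(image)
        x = self.stem(image)
        levels = [x]
        for i in range(1, 4):
            x = getattr(self, f"down{i}")(x)
            levels.append(x)
        return FeaturePyramid(levels)


def _check_input(image: Tensor):
    if image.ndim != 4 or image.shape[1] != 3:
        raise ValueError(f"expected NCHW input with 3 channels, got shape "
                         f"{tuple(image.shape)}")
    _, _, h, w = image.shape
    if h % 32 or w % 32:
        raise ValueError(f"input spatial dims ({h},{w}) must be divisible "
                         f"by 32")


def build_encoder(config: EncoderConfig) -> nn.Module:
    if config.variant == "vmamba_tiny":
        return VMambaEncoder(config)
    return TestConvEncoder(config)


def encode(image: Tensor, encoder) -> FeaturePyramid:
    """Run an encoder (or build one from an :class:`EncoderConfig`) on a
    batch of images, returning the validated feature pyramid."""
    if isinstance(encoder, EncoderConfig):
        encoder = build_encoder(encoder)
    return encoder(image)
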