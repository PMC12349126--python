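"""Convolution ops (im2col-based) with manual backward passes."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, make_op
from .functional import add_macs


def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B,C,Hp,Wp) -> (B,C,OH,OW,KH,KW) patch view (strided, no copy)."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2D cross-correlation on NCHW input.

    weight: (C_out, C_in/groups, KH, KW).
    """
    b, c, h, w = x.shape
    co, cg, kh, kw = weight.shape
    if c != cg * groups:
        raise ValueError(f"conv2d: input has {c} channels, weight expects "
                         f"{cg * groups} (groups={groups})")
    if co % groups:
        raise ValueError("conv2d: out_channels must be divisible by groups")
    xp = _pad2d(x.data, padding)
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (w + 2 * padding - kw) // stride + 1
    col = _im2col(xp, kh, kw, stride)                       # B,C,OH,OW,KH,KW
    colg = col.reshape(b, groups, cg, oh, ow, kh, kw)
    wg = weight.data.reshape(groups, co // groups, cg, kh, kw)
    out = np.einsum("bgchwkl,gockl->bgohw", colg, wg, optimize=True)
    out = out.reshape(b, co, oh, ow)
    add_macs(b * co * oh * ow * cg * kh * kw)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1)

    def bwd(g):
        gg = g.reshape(b, groups, co // groups, oh, ow)
        gw = np.einsum("bgchwkl,bgohw->gockl", colg, gg, optimize=True)
        gw = gw.reshape(weight.shape)
        gcol = np.einsum("gockl,bgohw->bgchwkl", wg, gg, optimize=True)
        gcol = gcol.reshape(b, c, oh, ow, kh, kw)
        gxp = np.zeros_like(xp)
        for k in range(kh):
            for l in range(kw):
                gxp[:, :, k:k + stride * oh:stride,
                    l:l + stride * ow:stride] += gcol[:, :, :, :, k, l]
        gx = gxp[:, :, padding:padding + h, padding:padding + w] if padding \
            else gxp
        gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
        return (gx, gw, gb) if bias is not None else (gx, gw)

    parents = (x, weight, bias) if bias is not None else (x, weight)
    return make_op(out, parents, bwd)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed 2D convolution (stride-s upsampling), groups=1.

    weight: (C_in, C_out, KH, KW); output H = (H-1)*stride - 2*padding + KH.
    """
    b, ci, h, w = x.shape
    ci_w, co, kh, kw = weight.shape
    if ci != ci_w:
        raise ValueError(f"conv_transpose2d: {ci} input channels but weight "
                         f"has {ci_w}")
    hp = (h - 1) * stride + kh
    wp = (w - 1) * stride + kw
    oh, ow = hp - 2 * padding, wp - 2 * padding
    out_pad = np.zeros((b, co, hp, wp), dtype=x.dtype)
    for k in range(kh):
        for l in range(kw):
            contrib = np.einsum("bchw,co->bohw", x.data, weight.data[:, :, k, l],
                                optimize=True)
            out_pad[:, :, k:k + stride * h:stride,
                    l:l + stride * w:stride] += contrib
    out = out_pad[:, :, padding:padding + oh, padding:padding + ow]
    add_macs(b * ci * co * h * w * kh * kw)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1)

    def bwd(g):
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        colg = _im2col(gp, kh, kw, stride)                  # B,Co,H,W,KH,KW
        gx = np.einsum("bohwkl,cokl->bchw", colg, weight.data, optimize=True)
        gw = np.einsum("bchw,bohwkl->cokl", x.data, colg, optimize=True)
        gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
        return (gx, gw, gb) if bias is not None else (gx, gw)

    parents = (x, weight, bias) if bias is not None else (x, weight)
    return make_op(out, parents, bwd)
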