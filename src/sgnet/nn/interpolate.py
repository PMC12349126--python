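"""Differentiable bilinear resizing for NCHW tensors.

Bilinear interpolation is separable, so a resize is two small dense matrix
contractions ``y = R_h x R_w^T``; the backward pass is the transposed
contraction.  Uses half-pixel (align_corners=False) source mapping.
"""

from __future__ import annotations

import functools

import numpy as np

from .autograd import Tensor, make_op


@functools.lru_cache(maxsize=256)
def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    rows = np.arange(n_out)
    np.add.at(m, (rows, i0), 1.0 - frac)
    np.add.at(m, (rows, i1), frac)
    return m


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    b, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    rh = _resize_matrix(h, out_h)
    rw = _resize_matrix(w, out_w)
    out = np.einsum("oh,pw,bchw->bcop", rh, rw, x.data, optimize=True)

    def bwd(g):
        return (np.einsum("oh,pw,bcop->bchw", rh, rw, g, optimize=True),)

    return make_op(out, (x,), bwd)
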