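"""Learnable frequency-domain filtering.

The op computes ``y = Re(ifft2(fft2(x) * W_full))`` per channel, where
``W_full`` is the conjugate-symmetric extension of a learnable half-spectrum
filter of shape (C, H, W//2 + 1), stored as separate real and imaginary
parameter arrays.  With a unit filter the op is an exact identity; zeroing a
bin removes that frequency component.

Backward passes are the analytic adjoints:

* ``dL/dx  = Re(fft2(ifft2(g) * W_full))``
* ``dL/dW_full = conj(fft2(x) * ifft2(g))`` summed over the batch, then folded
  back onto the half-spectrum parameters (mirrored bins receive the conjugate
  of their image).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, make_op


def _full_spectrum(wr: np.ndarray, wi: np.ndarray, w: int) -> np.ndarray:
    """Conjugate-symmetric extension of a half-spectrum (C,H,Wh) -> (C,H,W)."""
    c, h, wh = wr.shape
    wf = np.zeros((c, h, w), dtype=complex)
    wf[:, :, :wh] = wr + 1j * wi
    # mirrored columns: W_full[u, W-v] = conj(W[(-u) % H, v])
    vsrc = np.arange(1, w - wh + 1)          # columns that have a mirror image
    urev = (-np.arange(h)) % h
    wf[:, :, w - vsrc] = np.conj(wf[:, urev][:, :, vsrc])
    return wf


def _fold_half(gwf: np.ndarray, wh: int) -> np.ndarray:
    """Fold a full-spectrum gradient back onto the half-spectrum params."""
    c, h, w = gwf.shape
    g = gwf[:, :, :wh].copy()
    vsrc = np.arange(1, w - wh + 1)
    urev = (-np.arange(h)) % h
    g[:, :, vsrc] += np.conj(gwf[:, urev][:, :, w - vsrc])
    return g


def frequency_filter(x: Tensor, wr: Tensor, wi: Tensor) -> Tensor:
    """Apply a learnable per-channel complex filter in the 2D Fourier domain."""
    b, c, h, w = x.shape
    wh = w // 2 + 1
    if wr.shape != (c, h, wh) or wi.shape != (c, h, wh):
        raise ValueError(
            f"frequency filter shape {wr.shape} does not match the "
            f"(C,H,W//2+1)=({c},{h},{wh}) half-spectrum of the input")
    wfull = _full_spectrum(wr.data, wi.data, w)
    xf = np.fft.fft2(x.data)
    out = np.real(np.fft.ifft2(xf * wfull)).astype(x.dtype)

    def bwd(g):
        gi = np.fft.ifft2(g)
        gx = np.real(np.fft.fft2(gi * wfull)).astype(x.dtype)
        gwfull = np.conj(xf * gi).sum(axis=0)
        gw = _fold_half(gwfull, wh)
        return gx, np.real(gw).astype(wr.dtype), np.imag(gw).astype(wi.dtype)

    return make_op(out, (x, wr, wi), bwd)
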