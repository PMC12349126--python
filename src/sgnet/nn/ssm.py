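"""Selective state-space scan with a manual adjoint.

Implements the discretised input-dependent linear recurrence used by Mamba-
style blocks.  For each sequence position t:

    h_t = exp(delta_t * A) * h_{t-1} + (delta_t * u_t) * B_t
    y_t = <C_t, h_t> + D * u_t

with per-(channel, state) transition ``A`` (shared over time), input-dependent
``delta`` (already softplus-positive), and per-position low-rank ``B_t, C_t``.
The forward pass is a sequential loop over t with vectorised (G, D, N) inner
arithmetic; the backward pass runs the reverse-time adjoint recurrence.

Shapes (G = batch x scan-directions, D = inner channels, N = state size):
    u, delta : (G, D, L)      A, Dskip : (G, D, N), (G, D)
    B, C     : (G, N, L)      output   : (G, D, L)
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, is_grad_enabled, make_op
from .functional import add_macs


def selective_scan(u: Tensor, delta: Tensor, A: Tensor, B: Tensor, C: Tensor,
                   Dskip: Tensor) -> Tensor:
    g_, d_, l_ = u.shape
    n_ = A.shape[-1]
    if delta.shape != (g_, d_, l_) or A.shape != (g_, d_, n_) or \
            B.shape != (g_, n_, l_) or C.shape != (g_, n_, l_) or \
            Dskip.shape != (g_, d_):
        raise ValueError("selective_scan: inconsistent operand shapes")

    ud, dd, ad, bd, cd, dsd = (t.data for t in (u, delta, A, B, C, Dskip))
    keep = is_grad_enabled() and any(
        t.requires_grad for t in (u, delta, A, B, C, Dskip))

    dA = np.exp(dd[:, :, None, :] * ad[:, :, :, None])        # G,D,N,L
    dBu = (dd * ud)[:, :, None, :] * bd[:, None, :, :]        # G,D,N,L
    h = np.zeros((g_, d_, n_), dtype=ud.dtype)
    y = np.empty_like(ud)
    hs = np.empty((g_, d_, n_, l_), dtype=ud.dtype) if keep else None
    for t in range(l_):
        h = dA[:, :, :, t] * h + dBu[:, :, :, t]
        if keep:
            hs[:, :, :, t] = h
        y[:, :, t] = np.einsum("gdn,gn->gd", h, cd[:, :, t])
    y = y + dsd[:, :, None] * ud
    add_macs(2 * g_ * d_ * n_ * l_ + g_ * d_ * l_)

    def bwd(gy):
        gu = gy * dsd[:, :, None]
        gds = (gy * ud).sum(axis=2)
        gdelta = np.zeros_like(dd)
        gA = np.zeros_like(ad)
        gB = np.zeros_like(bd)
        gC = np.zeros_like(cd)
        gh = np.zeros((g_, d_, n_), dtype=ud.dtype)
        for t in range(l_ - 1, -1, -1):
            gh = gh + gy[:, :, None, t] * cd[:, None, :, t]
            gC[:, :, t] = np.einsum("gdn,gd->gn", hs[:, :, :, t], gy[:, :, t])
            h_prev = hs[:, :, :, t - 1] if t > 0 else np.zeros_like(gh)
            g_dA = gh * h_prev                                 # G,D,N
            gA += g_dA * dd[:, :, None, t] * dA[:, :, :, t]
            gdelta[:, :, t] = (g_dA * ad * dA[:, :, :, t]).sum(axis=2) \
                + (gh * bd[:, None, :, t]).sum(axis=2) * ud[:, :, t]
            gB[:, :, t] = np.einsum("gdn,gd->gn", gh, dd[:, :, t] * ud[:, :, t])
            gu[:, :, t] += (gh * bd[:, None, :, t]).sum(axis=2) * dd[:, :, t]
            gh = gh * dA[:, :, :, t]
        return gu, gdelta, gA, gB, gC, gds

    return make_op(y, (u, delta, A, B, C, Dskip), bwd)


def selective_scan_reference(u: np.ndarray, delta: np.ndarray, A: np.ndarray,
                             B: np.ndarray, C: np.ndarray,
                             Dskip: np.ndarray) -> np.ndarray:
    """Plain step-by-step recurrence oracle (independent of the op above)."""
    g_, d_, l_ = u.shape
    n_ = A.shape[-1]
    y = np.zeros_like(u)
    for gi in range(g_):
        for di in range(d_):
            h = np.zeros(n_)
            for t in range(l_):
                a_bar = np.exp(delta[gi, di, t] * A[gi, di])
                h = a_bar * h + delta[gi, di, t] * u[gi, di, t] * B[gi, :, t]
                y[gi, di, t] = float(C[gi, :, t] @ h) + Dskip[gi, di] * u[gi, di, t]
    return y
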