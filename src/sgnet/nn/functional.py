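"""Composite differentiable functions built from autograd primitives."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, concat


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def silu(x: Tensor) -> Tensor:
    return x * x.sigmoid()


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    return x * 0.5 * ((x * (1.0 / np.sqrt(2.0))).erf() + 1.0)


def softplus(x: Tensor) -> Tensor:
    # log(1 + e^x) = relu(x) + log1p(e^{-|x|}); the exp argument is <= 0.
    return x.relu() + ((-x.abs()).exp() + 1.0).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k average pooling on NCHW input."""
    b, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    return (x.reshape(b, c, h // k, k, w // k, k)
             .mean(axis=(3, 5)))


def global_avg_pool(x: Tensor, keepdims: bool = True) -> Tensor:
    return x.mean(axis=(2, 3), keepdims=keepdims)


def zpool(x: Tensor, axis: int = 1) -> Tensor:
    """Concatenate max and mean along ``axis`` (keeping it, size 2)."""
    return concat([x.max(axis=axis, keepdims=True),
                   x.mean(axis=axis, keepdims=True)], axis=axis)


def binary_cross_entropy_with_logits(logits: Tensor, target: Tensor,
                                     reduction: str = "mean") -> Tensor:
    """Numerically stable BCE on logits: max(x,0) - x*y + log(1+e^{-|x|})."""
    target = as_tensor(target)
    loss = logits.relu() - logits * target + ((-logits.abs()).exp() + 1.0).log()
    if reduction == "mean":
        return loss.mean()
    if reduction == "sum":
        return loss.sum()
    return loss


def soft_dice_loss(logits: Tensor, target: Tensor, smooth: float = 1e-5) -> Tensor:
    """1 - soft Dice on sigmoid probabilities, pooled over the whole batch."""
    p = logits.sigmoid()
    target = as_tensor(target)
    inter = (p * target).sum()
    denom = p.sum() + target.sum()
    return 1.0 - (inter * 2.0 + smooth) / (denom + smooth)


def bce_dice(logits: Tensor, target: Tensor, smooth: float = 1e-5) -> Tensor:
    return (binary_cross_entropy_with_logits(logits, target)
            + soft_dice_loss(logits, target, smooth))


# ---------------------------------------------------------------------------
# multiply-accumulate counting (thop-style: convs / linears / scans counted,
# normalisation, activations and FFTs not)
# ---------------------------------------------------------------------------

class _MacCounter:
    __slots__ = ("macs",)

    def __init__(self):
        self.macs = 0


_ACTIVE_COUNTER: _MacCounter | None = None


class count_macs:
    """Context manager accumulating multiply-accumulate counts of structured ops."""

    def __enter__(self) -> _MacCounter:
        global _ACTIVE_COUNTER
        self._counter = _MacCounter()
        self._prev = _ACTIVE_COUNTER
        _ACTIVE_COUNTER = self._counter
        return self._counter

    def __exit__(self, *exc):
        global _ACTIVE_COUNTER
        _ACTIVE_COUNTER = self._prev
        return False


def add_macs(n: int):
    if _ACTIVE_COUNTER is not None:
        _ACTIVE_COUNTER.macs += int(n)
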