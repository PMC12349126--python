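"""Weight initialisation with a process-global, reseedable generator."""

from __future__ import annotations

import numpy as np

_rng = np.random.default_rng(0)


def seed_all(seed: int):
    """Reset the initialisation RNG; call before building a model for
    reproducible weights."""
    global _rng
    _rng = np.random.default_rng(seed)


def rng() -> np.random.Generator:
    return _rng


def trunc_normal(shape, std: float = 0.02, dtype=np.float32) -> np.ndarray:
    """Normal(0, std) truncated to +/- 2 std (resampling the tails)."""
    x = _rng.standard_normal(shape) * std
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = _rng.standard_normal(bad.sum()) * std
        bad = np.abs(x) > 2 * std
    return x.astype(dtype)


def kaiming_normal(shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    return (_rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def zeros(shape, dtype=np.float32) -> np.ndarray:
    return np.zeros(shape, dtype=dtype)


def ones(shape, dtype=np.float32) -> np.ndarray:
    return np.ones(shape, dtype=dtype)
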