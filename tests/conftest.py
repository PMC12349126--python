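import numpy as np
import pytest

from sgnet import nn
from sgnet.nn import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function of the array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grads_match(tensors, out_fn, tol: float = 1e-6):
    """Check autograd gradients of a scalar-valued graph against central
    differences, for every leaf tensor (float64 data expected)."""
    loss = out_fn()
    for t in tensors:
        t.grad = None
    loss.backward()
    for k, t in enumerate(tensors):
        ng = numerical_gradient(lambda: out_fn().item(), t.data)
        ag = t.grad if t.grad is not None else np.zeros_like(t.data)
        denom = np.max(np.abs(ng)) + 1e-8
        err = np.max(np.abs(ag - ng)) / denom
        assert err < tol, f"gradient mismatch on arg {k}: rel err {err:.2e}"


@pytest.fixture
def leaf(rng):
    def make(shape, scale=1.0):
        return Tensor(rng.standard_normal(shape) * scale, requires_grad=True)
    return make
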