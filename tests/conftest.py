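import numpy as np
import pytest

from lvquant.autodiff import Tensor


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar-valued f at x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        hi = f(x)
        flat[i] = old - eps
        lo = f(x)
        flat[i] = old
        gf[i] = (hi - lo) / (2 * eps)
    return g


def analytic_grad(op, *arrays, wrt: int = 0):
    """Backward-pass gradient of sum(op(*tensors)) w.r.t. one input."""
    tensors = [Tensor(np.asarray(a, dtype=np.float64), requires_grad=True)
               for a in arrays]
    out = op(*tensors)
    out.sum().backward()
    return tensors[wrt].grad


def check_grad(op, *arrays, wrt: int = 0, atol: float = 1e-5, rtol: float = 1e-4):
    """Compare autodiff and finite-difference gradients of sum(op(...))."""
    arrays = [np.asarray(a, dtype=np.float64) for a in arrays]
    got = analytic_grad(op, *arrays, wrt=wrt)

    def scalar(x):
        args = [Tensor(a.copy()) for a in arrays]
        args[wrt] = Tensor(np.asarray(x, dtype=np.float64))
        return float(op(*args).sum().data)

    want = numeric_grad(scalar, arrays[wrt].copy())
    np.testing.assert_allclose(got, want, atol=atol, rtol=rtol)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
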