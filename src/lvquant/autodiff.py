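"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the segmentation and regression networks
need: broadcast-aware arithmetic, batched matmul, elementwise nonlinearities,
reductions, reshapes, 3D convolution (arbitrary stride/padding, small
kernels), non-overlapping transposed 3D convolution, and 1x2x2 max pooling.

Gradients are accumulated through a topologically sorted tape rooted at the
scalar the caller backpropagates from.  All computation is plain numpy, so a
fixed seed gives bit-identical runs on a single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "concatenate", "conv3d", "conv_transpose3d", "maxpool3d_hw2",
    "softmax", "relu", "leaky_relu", "sigmoid", "no_grad",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (cheap inference)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._saved = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._saved
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            # an intermediate's grad is consumed exactly once: free it so the
            # peak memory of deep graphs stays close to the forward peak
            if not t.requires_grad:
                t.grad = None
                t._backward = None
                t._prev = ()

    @staticmethod
    def _track(*ts):
        return _GRAD_ENABLED and any(t.requires_grad or t._prev for t in ts)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out = Tensor(self.data + other.data, _prev=(self, other) if Tensor._track(self, other) else ())

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        if out._prev:
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,) if Tensor._track(self) else ())
        if out._prev:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(np.asarray(other, dtype=self.data.dtype)) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out = Tensor(self.data * other.data, _prev=(self, other) if Tensor._track(self, other) else ())

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        if out._prev:
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(np.asarray(other, dtype=self.data.dtype)) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,) if Tensor._track(self) else ())
        if out._prev:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data, _prev=(self, other) if Tensor._track(self, other) else ())

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))
        if out._prev:
            out._backward = bw
        return out

    # -- elementwise --------------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,) if Tensor._track(self) else ())
        if out._prev:
            out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,) if Tensor._track(self) else ())
        if out._prev:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo, hi):
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,) if Tensor._track(self) else ())
        if out._prev:
            mask = ((self.data >= lo) & (self.data <= hi)).astype(self.data.dtype)
            out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _prev=(self,) if Tensor._track(self) else ())

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(ge, self.data.shape).copy())
        if out._prev:
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape --------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,) if Tensor._track(self) else ())
        if out._prev:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,) if Tensor._track(self) else ())
        if out._prev:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,) if Tensor._track(self) else ())

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)
        if out._prev:
            out._backward = bw
        return out


# -- functional ops ---------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    pos = x.data > 0   # boolean mask: cheap to keep on the tape
    out = Tensor(np.where(pos, x.data, 0), _prev=(x,) if Tensor._track(x) else ())
    if out._prev:
        out._backward = lambda g: x._accum(np.where(pos, g, 0))
    return out


def leaky_relu(x: Tensor, slope: float) -> Tensor:
    """Leaky ReLU with a scalar negative slope."""
    slope = float(slope)
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, slope * x.data),
                 _prev=(x,) if Tensor._track(x) else ())
    if out._prev:
        out._backward = lambda g: x._accum(np.where(pos, g, slope * g))
    return out


def sigmoid(x: Tensor) -> Tensor:
    # stable in both tails: exp of a non-positive argument only
    pos = x.data >= 0
    e = np.exp(np.where(pos, -x.data, x.data))
    s = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e))
    out = Tensor(s, _prev=(x,) if Tensor._track(x) else ())
    if out._prev:
        out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax, fused (single node on the tape)."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _prev=(x,) if Tensor._track(x) else ())
    if out._prev:
        out._backward = lambda g: x._accum(
            s * (g - (g * s).sum(axis=axis, keepdims=True)))
    return out


def normalize_affine(x: Tensor, gamma: Tensor, beta: Tensor,
                     group_shape: tuple, affine_shape: tuple,
                     eps: float = 1e-5):
    """Fused normalization + affine, the core of group/layer/batch norm.

    `group_shape` reshapes x so the LAST axis enumerates one normalization
    group; `affine_shape` broadcasts gamma/beta against x.  Returns
    (y, mean, var) with mean/var as plain arrays (for running statistics).
    """
    xg = x.data.reshape(group_shape)
    mu = xg.mean(axis=-1, keepdims=True)
    var = xg.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(x.data.shape)
    gb = gamma.data.reshape(affine_shape)
    y = xhat * gb + beta.data.reshape(affine_shape)
    prev = (x, gamma, beta)
    out = Tensor(y, _prev=prev if any(Tensor._track(t) for t in prev) else ())

    def bw(g):
        red = tuple(i for i, n in enumerate(affine_shape) if n == 1)
        gamma._accum((g * xhat).sum(axis=red).reshape(gamma.data.shape))
        beta._accum(g.sum(axis=red).reshape(beta.data.shape))
        dxh = (g * gb).reshape(group_shape)
        xh = xhat.reshape(group_shape)
        dx = inv * (dxh - dxh.mean(axis=-1, keepdims=True)
                    - xh * (dxh * xh).mean(axis=-1, keepdims=True))
        x._accum(dx.reshape(x.data.shape))
    if out._prev:
        out._backward = bw
    return out, mu.reshape(-1), var.reshape(-1)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch norm over axis 1 of a (N, C, ...) tensor.

    Returns (y, batch_mean, batch_var) with the statistics as plain arrays.
    """
    axes = (0,) + tuple(range(2, x.data.ndim))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    shape = mu.shape
    gb = gamma.data.reshape(shape)
    y = xhat * gb + beta.data.reshape(shape)
    prev = (x, gamma, beta)
    out = Tensor(y, _prev=prev if any(Tensor._track(t) for t in prev) else ())

    def bw(g):
        gamma._accum((g * xhat).sum(axis=axes).reshape(gamma.data.shape))
        beta._accum(g.sum(axis=axes).reshape(beta.data.shape))
        dxh = g * gb
        dx = inv * (dxh - dxh.mean(axis=axes, keepdims=True)
                    - xhat * (dxh * xhat).mean(axis=axes, keepdims=True))
        x._accum(dx)
    if out._prev:
        out._backward = bw
    return out, mu.reshape(-1), var.reshape(-1)


def concatenate(ts, axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in ts], axis=axis)
    track = any(Tensor._track(t) for t in ts)
    out = Tensor(data, _prev=tuple(ts) if track else ())

    def bw(g):
        ofs = 0
        for t in ts:
            n = t.data.shape[axis]
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(ofs, ofs + n)
            t._accum(g[tuple(sl)])
            ofs += n
    if out._prev:
        out._backward = bw
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1, 1), padding=(0, 0, 0)) -> Tensor:
    """3D convolution over (N, C, D, H, W) with kernel (Co, C, kd, kh, kw).

    Implemented as a sum over kernel offsets of channel-mixing tensordot
    contractions, accumulated with the contracted axis leading so each
    offset is a single BLAS call; one final transpose restores the
    channels-second layout.  Memory stays flat: nothing beyond the output
    and one padded buffer is materialized.
    """
    N, C, D, H, W = x.data.shape
    Co, Ci, kd, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Ci}")
    sd, sh, sw = stride
    pd, ph, pw = padding
    Do = (D + 2 * pd - kd) // sd + 1
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1

    def padded():
        if pd or ph or pw:
            return np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        return x.data

    xp = padded()
    out_t = np.zeros((Co, N, Do, Ho, Wo), dtype=x.data.dtype)
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                xs = xp[:, :, i:i + Do * sd:sd, j:j + Ho * sh:sh, k:k + Wo * sw:sw]
                out_t += np.tensordot(w.data[:, :, i, j, k], xs, axes=(1, 1))
    out_data = np.ascontiguousarray(out_t.transpose(1, 0, 2, 3, 4))
    del out_t
    if b is not None:
        out_data += b.data.reshape(1, Co, 1, 1, 1)
    prev = [t for t in (x, w, b) if t is not None]
    out = Tensor(out_data, _prev=tuple(prev) if any(Tensor._track(t) for t in prev) else ())

    def bw(g):
        xpb = xp
        gw = np.empty_like(w.data)
        gxp_t = np.zeros((C, N, D + 2 * pd, H + 2 * ph, W + 2 * pw),
                         dtype=x.data.dtype)
        # one (Co, N*Do*Ho*Wo) copy of the output gradient, reused by all
        # 2*k^3 contractions below instead of a fresh transpose per call
        gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3, 4)).reshape(Co, -1)
        wmat = w.data.reshape(Co, C, -1)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    sl = (slice(None), slice(None),
                          slice(i, i + Do * sd, sd),
                          slice(j, j + Ho * sh, sh),
                          slice(k, k + Wo * sw, sw))
                    off = (i * kh + j) * kw + k
                    xs = np.ascontiguousarray(
                        xpb[sl].transpose(1, 0, 2, 3, 4)).reshape(C, -1)
                    gw[:, :, i, j, k] = gmat @ xs.T
                    gxp_t[(slice(None),) + sl[1:]] += \
                        (wmat[:, :, off].T @ gmat).reshape(C, N, Do, Ho, Wo)
        w._accum(gw)
        gxp = gxp_t.transpose(1, 0, 2, 3, 4)
        gx = gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W] if (pd or ph or pw) else gxp
        x._accum(np.ascontiguousarray(gx))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
    if out._prev:
        out._backward = bw
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride=(1, 2, 2)) -> Tensor:
    """Transposed 3D convolution restricted to kernel == stride (no overlap).

    Kernel layout (Cin, Cout, kd, kh, kw); output spatial size = input * stride.
    """
    N, C, D, H, W = x.data.shape
    Ci, Co, kd, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError("channel mismatch in transposed conv")
    # (N,D,H,W,Co,kd,kh,kw) -> (N,Co,D,kd,H,kh,W,kw) -> (N,Co,D*kd,H*kh,W*kw)
    t = np.tensordot(x.data, w.data, axes=([1], [0]))
    out_data = np.ascontiguousarray(t.transpose(0, 4, 1, 5, 2, 6, 3, 7)).reshape(
        N, Co, D * kd, H * kh, W * kw)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Co, 1, 1, 1)
    prev = [t_ for t_ in (x, w, b) if t_ is not None]
    out = Tensor(out_data, _prev=tuple(prev) if any(Tensor._track(t_) for t_ in prev) else ())

    def bw(g):
        g8 = g.reshape(N, Co, D, kd, H, kh, W, kw).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        # g8: (N,D,H,W,Co,kd,kh,kw)
        gx = np.tensordot(g8, w.data, axes=([4, 5, 6, 7], [1, 2, 3, 4]))  # (N,D,H,W,Cin)
        x._accum(np.ascontiguousarray(gx.transpose(0, 4, 1, 2, 3)))
        gw = np.tensordot(x.data, g8, axes=([0, 2, 3, 4], [0, 1, 2, 3]))  # (Cin,Co,kd,kh,kw)
        w._accum(gw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
    if out._prev:
        out._backward = bw
    return out


def maxpool3d_hw2(x: Tensor) -> Tensor:
    """Max pooling with kernel and stride 1x2x2 (halves H and W, keeps slices)."""
    N, C, D, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("spatial size must be even for 1x2x2 pooling")
    xr = x.data.reshape(N, C, D, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 3, 5, 4, 6)
    flat = np.ascontiguousarray(xr).reshape(N, C, D, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, _prev=(x,) if Tensor._track(x) else ())

    def bw(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        gx = gf.reshape(N, C, D, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 3, 5, 4, 6)
        x._accum(np.ascontiguousarray(gx).reshape(N, C, D, H, W))
    if out._prev:
        out._backward = bw
    return out
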