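"""Neural-network layers and optimizers on top of :mod:`lvquant.autodiff`.

Contains only what the two network paths use: 3D conv / transposed conv,
group / batch / layer normalization, randomized leaky ReLU, linear layers,
multi-head self-attention blocks, squeeze-and-excitation, and the two
optimizers the training recipe prescribes (RAdam for the segmentation path,
momentum SGD for the regression and classification parameters).

Convolution and linear kernels use He (Kaiming) normal initialization.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import (Tensor, batch_norm_train, concatenate, conv3d,
                       conv_transpose3d, leaky_relu, maxpool3d_hw2,
                       normalize_affine, relu, sigmoid, softmax)

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Tiny module base: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, c in self._children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        d = {("param." + k): p.data.copy() for k, p in self.named_parameters()}
        d.update({("buffer." + k): np.asarray(v).copy() for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d):
        for k, p in self.named_parameters():
            p.data = np.asarray(d["param." + k], dtype=p.data.dtype).reshape(p.data.shape)
        buf = {k: v for k, v in self.named_buffers()}
        for k in buf:
            self._set_buffer_by_path(k, d["buffer." + k])

    def _set_buffer_by_path(self, path, value):
        obj, parts = self, path.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        cur = getattr(obj, parts[-1])
        setattr(obj, parts[-1], np.asarray(value, dtype=np.asarray(cur).dtype))

    def seed_stochastic(self, rng: np.random.Generator):
        """Attach one RNG to every stochastic layer (randomized activations)."""
        if isinstance(self, RReLU):
            self.rng = rng
        for _, c in self._children():
            c.seed_stochastic(rng)


def _he(shape, fan_in, rng):
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(DTYPE)


# a module-level rng only for weight init; models pass their own
_INIT_RNG = np.random.default_rng(0)


def set_init_rng(rng: np.random.Generator):
    global _INIT_RNG
    _INIT_RNG = rng


class Conv3d(Module):
    def __init__(self, cin, cout, kernel, stride=(1, 1, 1), padding=(0, 0, 0), bias=True):
        super().__init__()
        if isinstance(kernel, int):
            kernel = (kernel,) * 3
        self.stride, self.padding = tuple(stride), tuple(padding)
        fan_in = cin * int(np.prod(kernel))
        self.weight = Parameter(_he((cout, cin) + tuple(kernel), fan_in, _INIT_RNG))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    """Transposed conv with kernel == stride (non-overlapping upsampling)."""

    def __init__(self, cin, cout, stride=(1, 2, 2), bias=True):
        super().__init__()
        self.stride = tuple(stride)
        fan_in = cin
        self.weight = Parameter(_he((cin, cout) + self.stride, fan_in, _INIT_RNG))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return conv_transpose3d(x, self.weight, self.bias, self.stride)


class Linear(Module):
    def __init__(self, fin, fout, bias=True):
        super().__init__()
        self.weight = Parameter(_he((fin, fout), fin, _INIT_RNG))
        self.bias = Parameter(np.zeros(fout)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class GroupNorm(Module):
    def __init__(self, num_groups, num_channels, eps=1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("channels must divide into groups")
        self.g, self.eps = num_groups, eps
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))

    def forward(self, x):
        n, c = x.shape[0], x.shape[1]
        affine = (1, c) + (1,) * (len(x.shape) - 2)
        y, _, _ = normalize_affine(x, self.gamma, self.beta,
                                   group_shape=(n, self.g, -1),
                                   affine_shape=affine, eps=self.eps)
        return y


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x):
        affine = (1,) * (len(x.shape) - 1) + (x.shape[-1],)
        y, _, _ = normalize_affine(x, self.gamma, self.beta,
                                   group_shape=x.shape, affine_shape=affine,
                                   eps=self.eps)
        return y


class BatchNorm3d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x):
        shape = (1, x.shape[1], 1, 1, 1)
        if self.training:
            y, mu, var = batch_norm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.astype(DTYPE)
            self.running_var = (1 - m) * self.running_var + m * var.astype(DTYPE)
            return y
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(shape)
        mu = self.running_mean.reshape(shape)
        y = (x - Tensor(mu)) * Tensor(inv)
        return y * self.gamma.reshape(shape) + self.beta.reshape(shape)


class RReLU(Module):
    """Randomized leaky ReLU: slope ~ U(lower, upper) while training,
    the mean slope at evaluation."""

    def __init__(self, lower=1 / 8, upper=1 / 3):
        super().__init__()
        self.lower, self.upper = lower, upper
        self.rng: np.random.Generator | None = None

    def forward(self, x):
        if self.training and self.rng is not None:
            slope = float(self.rng.uniform(self.lower, self.upper))
        else:
            slope = (self.lower + self.upper) / 2.0
        return leaky_relu(x, slope)


class SqueezeExcite(Module):
    """Channel attention: global average pool -> bottleneck MLP -> sigmoid gate."""

    def __init__(self, channels, reduction=8):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden)
        self.fc2 = Linear(hidden, channels)

    def gate(self, x):
        s = x.mean(axis=(2, 3, 4))            # (N, C)
        return sigmoid(self.fc2(relu(self.fc1(s))))

    def forward(self, x):
        g = self.gate(x)
        n, c = g.shape
        return x * g.reshape(n, c, 1, 1, 1)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim, heads):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must divide heads")
        self.h, self.dh = heads, dim // heads
        self.qkv = Linear(dim, 3 * dim)
        self.proj = Linear(dim, dim)
        self.last_attention: np.ndarray | None = None  # (B, h, T, T), eval aid

    def forward(self, x):
        b, t, e = x.shape
        qkv = self.qkv(x).reshape(b, t, 3, self.h, self.dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]        # each (B, h, T, dh)
        att = softmax(q @ k.transpose(0, 1, 3, 2) * (1.0 / math.sqrt(self.dh)), axis=-1)
        self.last_attention = att.data
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, t, e)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm encoder block: MHSA + MLP, residual connections."""

    def __init__(self, dim, heads, mlp_ratio=4):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * mlp_ratio)
        self.fc2 = Linear(dim * mlp_ratio, dim)

    def forward(self, x):
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(relu(self.fc1(self.ln2(x))))


# -- optimizers ---------------------------------------------------------------


class SGD:
    """Momentum SGD with L2 weight decay."""

    def __init__(self, params, lr, momentum=0.0, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {"v": [v.copy() for v in self.v], "lr": self.lr}

    def load_state_dict(self, d):
        self.v = [np.asarray(v) for v in d["v"]]
        self.lr = float(d["lr"])


class RAdam:
    """Rectified Adam (variance-rectified adaptive moments)."""

    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        t = self.t
        rho_inf = 2.0 / (1.0 - b2) - 1.0
        rho_t = rho_inf - 2.0 * t * b2 ** t / (1.0 - b2 ** t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1.0 - b1 ** t)
            if rho_t > 4.0:
                v_hat = np.sqrt(v / (1.0 - b2 ** t))
                r = math.sqrt(((rho_t - 4) * (rho_t - 2) * rho_inf)
                              / ((rho_inf - 4) * (rho_inf - 2) * rho_t))
                p.data -= self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p.data -= self.lr * m_hat

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {"m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v], "t": self.t, "lr": self.lr}

    def load_state_dict(self, d):
        self.m = [np.asarray(m) for m in d["m"]]
        self.v = [np.asarray(v) for v in d["v"]]
        self.t = int(d["t"])
        self.lr = float(d["lr"])
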