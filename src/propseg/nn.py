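"""Minimal reverse-mode autodiff and neural-network layers on numpy.

Implements exactly the primitives the propagation segmenter needs: 2D
convolution (stride 1, "same" padding) via im2col, non-overlapping
transposed convolution for upsampling, 2x2 max pooling, block average
pooling, batch normalization, ReLU/sigmoid, channel concatenation and a
numerically stable binary cross entropy on logits, plus an Adam optimizer.

Tensors are NCHW, float32 by default; every op is deterministic, so fixed
seeds give bitwise-identical training runs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "Parameter", "Module", "Conv2d", "ConvTranspose2d",
    "BatchNorm2d", "Adam", "relu", "sigmoid", "concat", "maxpool2d",
    "avgpool2d", "upsample_nearest", "bce_with_logits", "add", "smul",
]


class Tensor:
    """A numpy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def detach(self):
        return Tensor(self.data)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _needs_graph(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


# ---------------------------------------------------------------- basic ops

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, g)
        _accum(b, g)

    return Tensor(out_data, parents=(a, b), backward=bwd if _needs_graph(a, b) else None)


def smul(a: Tensor, s: float) -> Tensor:
    def bwd(g):
        _accum(a, g * s)

    return Tensor(a.data * s, parents=(a,), backward=bwd if _needs_graph(a) else None)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        _accum(x, g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bwd if _needs_graph(x) else None)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def bwd(g):
        _accum(x, g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=bwd if _needs_graph(x) else None)


def concat(ts, axis=1) -> Tensor:
    ts = list(ts)
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return Tensor(out_data, parents=tuple(ts),
                  backward=bwd if _needs_graph(*ts) else None)


# ------------------------------------------------------------- convolution

def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 'same' convolution. w: (O, C, k, k), k odd; b: (O,)."""
    N, C, H, W = x.data.shape
    O, _, k, _ = w.data.shape
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    # cols[n, h, w, c, i, j] = xp[n, c, h+i, w+j]
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
    cols2 = cols.reshape(N, H * W, C * k * k)
    wmat = w.data.reshape(O, -1)
    out = cols2 @ wmat.T + b.data
    out_data = np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(N, O, H, W)

    def bwd(g):
        g2 = g.reshape(N, O, H * W)
        if w.requires_grad or w._parents:
            dw = np.einsum("nop,npc->oc", g2, cols2, optimize=True)
            _accum(w, dw.reshape(w.data.shape))
        if b.requires_grad or b._parents:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dcols = np.einsum("nop,oc->npc", g2, wmat, optimize=True)
            dcols = dcols.reshape(N, H, W, C, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j]
            _accum(x, dxp[:, :, p:p + H, p:p + W])

    return Tensor(out_data, parents=(x, w, b),
                  backward=bwd if _needs_graph(x, w, b) else None)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2) -> Tensor:
    """Non-overlapping transposed conv: kernel size == stride. w: (C, O, s, s)."""
    N, C, H, W = x.data.shape
    _, O, s, _ = w.data.shape
    out6 = np.einsum("nchw,coij->nohiwj", x.data, w.data, optimize=True)
    out_data = out6.reshape(N, O, H * s, W * s) + b.data[None, :, None, None]

    def bwd(g):
        g6 = g.reshape(N, O, H, s, W, s)
        if w.requires_grad or w._parents:
            _accum(w, np.einsum("nchw,nohiwj->coij", x.data, g6, optimize=True))
        if b.requires_grad or b._parents:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            _accum(x, np.einsum("nohiwj,coij->nchw", g6, w.data, optimize=True))

    return Tensor(out_data, parents=(x, w, b),
                  backward=bwd if _needs_graph(x, w, b) else None)


# ----------------------------------------------------------------- pooling

def maxpool2d(x: Tensor, f: int = 2) -> Tensor:
    N, C, H, W = x.data.shape
    x6 = x.data.reshape(N, C, H // f, f, W // f, f)
    out_data = x6.max(axis=(3, 5))

    def bwd(g):
        mask = (x6 == out_data[:, :, :, None, :, None])
        cnt = mask.sum(axis=(3, 5), keepdims=True)  # split gradient on ties
        dx = mask * (g[:, :, :, None, :, None] / cnt)
        _accum(x, dx.reshape(N, C, H, W))

    return Tensor(out_data, parents=(x,), backward=bwd if _needs_graph(x) else None)


def avgpool2d(x: Tensor, f: int) -> Tensor:
    N, C, H, W = x.data.shape
    out_data = x.data.reshape(N, C, H // f, f, W // f, f).mean(axis=(3, 5))

    def bwd(g):
        dx = np.repeat(np.repeat(g, f, axis=2), f, axis=3) / (f * f)
        _accum(x, dx)

    return Tensor(out_data, parents=(x,), backward=bwd if _needs_graph(x) else None)


def upsample_nearest(x: Tensor, f: int) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, f, axis=2), f, axis=3)

    def bwd(g):
        N, C, H, W = x.data.shape
        _accum(x, g.reshape(N, C, H, f, W, f).sum(axis=(3, 5)))

    return Tensor(out_data, parents=(x,), backward=bwd if _needs_graph(x) else None)


# -------------------------------------------------------------------- loss

def bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross entropy, computed stably from logits."""
    zd = z.data
    loss = np.maximum(zd, 0) - zd * y + np.log1p(np.exp(-np.abs(zd)))
    out_data = np.asarray(loss.mean(), dtype=zd.dtype)

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-zd))
        _accum(z, g * (p - y) / zd.size)

    return Tensor(out_data, parents=(z,), backward=bwd if _needs_graph(z) else None)


# ----------------------------------------------------------------- modules

class Module:
    """Container with named parameters, train/eval mode and a state dict."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def _children(self):
        for val in vars(self).values():
            if isinstance(val, Module):
                yield val
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield item

    def train(self, mode=True):
        self.training = mode
        for c in self._children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def named_buffers(self, prefix=""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, np.ndarray):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_buffers(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    def state_dict(self):
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({"buf:" + k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, arr in state.items():
            if key.startswith("buf:"):
                bufs[key[4:]][...] = arr
            else:
                params[key].data[...] = arr


class Conv2d(Module):
    def __init__(self, c_in, c_out, k, rng, dtype=np.float32):
        super().__init__()
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0, scale, (c_out, c_in, k, k)).astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    def __init__(self, c_in, c_out, stride, rng, dtype=np.float32):
        super().__init__()
        fan_in = c_in
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0, scale, (c_in, c_out, stride, stride)).astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self.stride = stride

    def __call__(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[:, None, None]) * inv[:, None, None]
        out_data = gamma.data[:, None, None] * xhat + beta.data[:, None, None]
        training = self.training

        def bwd(g):
            if gamma.requires_grad:
                _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                _accum(beta, g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                gi = gamma.data[:, None, None] * inv[:, None, None]
                if training:
                    m = g.shape[0] * g.shape[2] * g.shape[3]
                    gm = g.mean(axis=(0, 2, 3))[:, None, None]
                    gxm = (g * xhat).mean(axis=(0, 2, 3))[:, None, None]
                    _accum(x, gi * (g - gm - xhat * gxm))
                else:
                    _accum(x, gi * g)

        return Tensor(out_data, parents=(x, gamma, beta),
                      backward=bwd if _needs_graph(x, gamma, beta) else None)


# --------------------------------------------------------------- optimizer

class Adam:
    """Adam with externally supplied per-step learning rate."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
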