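"""A small reverse-mode automatic-differentiation engine over NumPy.

The package trains and runs its networks on CPU through this engine: a
:class:`Tensor` records the operations applied to it and ``backward()``
replays them in reverse.  Convolutions are lowered to BLAS matrix products
via ``sliding_window_view`` (im2col); everything else is ordinary NumPy.

Design notes
------------
* ``float32`` end to end; gradients accumulate in ``float32``.
* A global :func:`no_grad` context disables taping, so large inference-only
  forwards cost no graph memory.
* Broadcasting follows NumPy; backward un-broadcasts by summing the added
  axes.
* Batch-norm is *compositional* (built from mean/var primitives) rather than
  a monolithic primitive, so quantities derived from batch statistics — such
  as a branch's response to a zero input, needed for exactly fusible padding
  — stay differentiable.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True

# when set to a list, convolution ops append their multiply-accumulate counts
PROFILE: list | None = None


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        grad = grad.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = _unbroadcast(grad, self.data.shape).copy()
        else:
            self.grad += _unbroadcast(grad, self.data.shape)

    def backward(self, grad=None):
        topo, seen = [], set()

        def build(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float32)
        )
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                t._backward = None
                t._prev = ()

    # -- basics ------------------------------------------------------------
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

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- elementwise arithmetic --------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(g)
                if other.requires_grad:
                    other._accum(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(g * other.data)
                if other.requires_grad:
                    other._accum(g * self.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(g / other.data)
                if other.requires_grad:
                    other._accum(-g * self.data / (other.data**2))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor._make(self.data**p, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._make(self.data.reshape(shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor._make(self.data.transpose(axes), (self,), None)
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bw
        return out

    # -- nonlinearities -----------------------------------------------------
    def sigmoid(self):
        s = _sigmoid(self.data)
        out = Tensor._make(s, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1 - s))
        return out

    def silu(self):
        s = _sigmoid(self.data)
        out = Tensor._make(self.data * s, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1 + self.data * (1 - s)))
        return out

    def relu(self):
        out = Tensor._make(np.maximum(self.data, 0), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor._make(e, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor._make(r, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / r)
        return out

    def softplus(self):
        # stable: log(1 + e^x) = max(x,0) + log1p(e^{-|x|})
        out_data = np.maximum(self.data, 0) + np.log1p(np.exp(-np.abs(self.data)))
        out = Tensor._make(out_data, (self,), None)
        if out.requires_grad:
            s = _sigmoid(self.data)
            out._backward = lambda g: self._accum(g * s)
        return out

    def clamp_min(self, lo: float):
        out = Tensor._make(np.maximum(self.data, lo), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (self.data >= lo))
        return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    mask = a.data >= b.data
    out = Tensor._make(np.where(mask, a.data, b.data), (a, b), None)
    if out.requires_grad:
        def bw(g):
            if a.requires_grad:
                a._accum(g * mask)
            if b.requires_grad:
                b._accum(g * ~mask)
        out._backward = bw
    return out


def minimum(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    mask = a.data <= b.data
    out = Tensor._make(np.where(mask, a.data, b.data), (a, b), None)
    if out.requires_grad:
        def bw(g):
            if a.requires_grad:
                a._accum(g * mask)
            if b.requires_grad:
                b._accum(g * ~mask)
        out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), None)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor._make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), None)
    if out.requires_grad:
        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))
        out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor._make(a.data @ b.data, (a, b), None)
    if out.requires_grad:
        def bw(g):
            if a.requires_grad:
                a._accum(g @ b.data.swapaxes(-1, -2))
            if b.requires_grad:
                b._accum(a.data.swapaxes(-1, -2) @ g)
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor._make(s, (x,), None)
    if out.requires_grad:
        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))
        out._backward = bw
    return out


def pad2d(x: Tensor, p: int) -> Tensor:
    if p == 0:
        return x
    spec = [(0, 0)] * (x.ndim - 2) + [(p, p), (p, p)]
    out = Tensor._make(np.pad(x.data, spec), (x,), None)
    if out.requires_grad:
        out._backward = lambda g: x._accum(g[..., p:-p, p:-p])
    return out


def _cols(xp: np.ndarray, kh: int, kw: int, s: int) -> np.ndarray:
    """[N,C,Hp,Wp] -> [N, C*kh*kw, Ho*Wo] patch matrix (a view-then-copy)."""
    n, c = xp.shape[:2]
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """2-D convolution, NCHW, square stride/padding, optional groups."""
    n, c, h, wd = x.shape
    d, cg, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wd + 2 * padding - kw) // stride + 1
    dg = d // groups
    if groups == 1:
        cols, ho, wo = _cols(xp, kh, kw, stride)
        out_data = (w.data.reshape(d, -1) @ cols).reshape(n, d, ho, wo)
        cols_per_g = [cols]
    else:
        outs, cols_per_g = [], []
        for gi in range(groups):
            cols_g, ho, wo = _cols(xp[:, gi * cg:(gi + 1) * cg], kh, kw, stride)
            cols_per_g.append(cols_g)
            outs.append(w.data[gi * dg:(gi + 1) * dg].reshape(dg, -1) @ cols_g)
        out_data = np.concatenate(outs, axis=1).reshape(n, d, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, d, 1, 1)
    if PROFILE is not None:
        PROFILE.append(d * cg * kh * kw * ho * wo)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data, parents, None)
    if out.requires_grad:
        def bw(g):
            gmat = g.reshape(n, d, ho * wo)
            if b is not None and b.requires_grad:
                b._accum(gmat.sum(axis=(0, 2)))
            for gi in range(groups):
                gm = gmat[:, gi * dg:(gi + 1) * dg]
                cols_g = cols_per_g[gi]
                if w.requires_grad:
                    gw = np.einsum("ndl,nkl->dk", gm, cols_g, optimize=True)
                    full = np.zeros_like(w.data)
                    full[gi * dg:(gi + 1) * dg] = gw.reshape(dg, cg, kh, kw)
                    w._accum(full)
                if x.requires_grad:
                    gcols = np.einsum("dk,ndl->nkl", w.data[gi * dg:(gi + 1) * dg].reshape(dg, -1), gm, optimize=True)
                    gcols = gcols.reshape(n, cg, kh, kw, ho, wo)
                    gxp = np.zeros((n, cg, h + 2 * padding, wd + 2 * padding), dtype=np.float32)
                    for i in range(kh):
                        for j in range(kw):
                            gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += gcols[:, :, i, j]
                    gx = gxp[:, :, padding:padding + h, padding:padding + wd]
                    full = np.zeros_like(x.data)
                    full[:, gi * cg:(gi + 1) * cg] = gx
                    x._accum(full)
        out._backward = bw
    return out


def conv_transpose2d_s2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (non-overlapping tiles).

    ``w`` has layout [C_in, C_out, 2, 2]; output is [N, C_out, 2H, 2W].
    """
    n, c, h, wd = x.shape
    _, d, kh, kw = w.shape
    out_data = np.einsum("ncij,cdab->ndiajb", x.data, w.data, optimize=True).reshape(
        n, d, h * kh, wd * kw
    )
    if b is not None:
        out_data = out_data + b.data.reshape(1, d, 1, 1)
    if PROFILE is not None:
        PROFILE.append(c * d * kh * kw * h * wd)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(np.ascontiguousarray(out_data), parents, None)
    if out.requires_grad:
        def bw(g):
            g6 = g.reshape(n, d, h, kh, wd, kw).transpose(0, 1, 2, 4, 3, 5)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                w._accum(np.einsum("ncij,ndijab->cdab", x.data, g6, optimize=True))
            if x.requires_grad:
                x._accum(np.einsum("ndijab,cdab->ncij", g6, w.data, optimize=True))
        out._backward = bw
    return out


def max_pool2d(x: Tensor, k: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, wd = x.shape
    xp = np.pad(
        x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, k * k)
    idx = flat.argmax(axis=-1)
    out = Tensor._make(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], (x,), None)
    if out.requires_grad:
        def bw(g):
            gxp = np.zeros_like(xp, dtype=np.float32)
            ii, jj = np.unravel_index(idx, (k, k))
            ni, ci, yi, xi = np.indices((n, c, ho, wo), sparse=False)
            np.add.at(gxp, (ni, ci, yi * stride + ii, xi * stride + jj), g)
            x._accum(gxp[:, :, padding:padding + h, padding:padding + wd])
        out._backward = bw
    return out


def avg_pool2d(x: Tensor, k: int, stride: int, padding: int = 0) -> Tensor:
    """Average pooling with divisor k**2 everywhere (padding counted)."""
    n, c, h, wd = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    out = Tensor._make(win.mean(axis=(-2, -1)), (x,), None)
    if out.requires_grad:
        ho, wo = out.data.shape[2], out.data.shape[3]
        def bw(g):
            gxp = np.zeros_like(xp, dtype=np.float32)
            gs = g / (k * k)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += gs
            x._accum(gxp[:, :, padding:padding + h, padding:padding + wd])
        out._backward = bw
    return out


def upsample_nearest2(x: Tensor, scale: int = 2) -> Tensor:
    out = Tensor._make(
        x.data.repeat(scale, axis=2).repeat(scale, axis=3), (x,), None
    )
    if out.requires_grad:
        n, c, h, w = x.shape
        def bw(g):
            x._accum(g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5)))
        out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray, weight: np.ndarray | None = None,
                    reduction: str = "mean") -> Tensor:
    """Numerically stable binary cross-entropy on logits (targets constant)."""
    t = np.asarray(targets, dtype=np.float32)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weight is not None:
        loss = loss * weight
    if reduction == "mean":
        val, scale = loss.mean(), 1.0 / loss.size
    elif reduction == "sum":
        val, scale = loss.sum(), 1.0
    else:
        raise ValueError(reduction)
    out = Tensor._make(np.float32(val), (logits,), None)
    if out.requires_grad:
        def bw(g):
            gg = (_sigmoid(z) - t) * scale * g
            if weight is not None:
                gg = gg * weight
            logits._accum(gg)
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters survive no_grad construction


class Module:
    """Minimal module with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        yield from m.modules()

    def named_parameters(self, prefix=""):
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield from m.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                out[f"{name}.running_mean"] = m.running_mean.copy()
                out[f"{name}.running_var"] = m.running_var.copy()
        return out

    def load_state_dict(self, sd: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(sd[name], dtype=np.float32).reshape(p.data.shape)
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(sd[f"{name}.running_mean"], dtype=np.float32)
                m.running_var = np.asarray(sd[f"{name}.running_var"], dtype=np.float32)

    def _named_modules(self, prefix=""):
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield f"{prefix}{name}", v
                yield from v._named_modules(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{prefix}{name}.{i}", m
                        yield from m._named_modules(f"{prefix}{name}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.groups = s, g
        self.padding = (k // 2) if p is None else p
        fan_in = (c1 // g) * k * k
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(c2, c1 // g, k, k)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=c2)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class ConvTranspose2dS2(Module):
    """Kernel-2 stride-2 transposed convolution (used to double resolution)."""

    def __init__(self, c1, c2, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / math.sqrt(c1 * 4)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(c1, c2, 2, 2)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=c2))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d_s2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization with momentum-style running statistics.

    The default forward is a single fused primitive (one graph node).  With
    ``track_zero_response=True`` the forward is built compositionally from
    mean/variance primitives instead, which keeps the layer's *zero-input
    response* — needed for exactly fusible padding in the multi-branch
    block — differentiable w.r.t. the batch statistics.
    """

    def __init__(self, c, eps: float = 1e-3, momentum: float = 0.03,
                 track_zero_response: bool = False):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.track_zero_response = track_zero_response
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        # batch statistics of the latest forward, as tensors
        self._last_mean: Tensor | None = None
        self._last_std: Tensor | None = None

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if not self.training:
            std = np.sqrt(self.running_var + self.eps)
            scale = (self.gamma.data / std).reshape(1, c, 1, 1)
            shift = (self.beta.data - self.gamma.data * self.running_mean / std).reshape(1, c, 1, 1)
            out = Tensor._make(x.data * scale + shift, (x, self.gamma, self.beta), None)
            if out.requires_grad:
                xd = x.data
                def bw(g):
                    if x.requires_grad:
                        x._accum(g * scale)
                    xn = (xd - self.running_mean.reshape(1, c, 1, 1)) / std.reshape(1, c, 1, 1)
                    self.gamma._accum((g * xn).sum(axis=(0, 2, 3)))
                    self.beta._accum(g.sum(axis=(0, 2, 3)))
                out._backward = bw
            self._last_mean, self._last_std = Tensor(self.running_mean), Tensor(std)
            return out
        if self.track_zero_response:
            mu = x.mean(axis=(0, 2, 3))
            var = ((x - mu.reshape(1, c, 1, 1)) ** 2).mean(axis=(0, 2, 3))
            self._update_running(mu.data, var.data, x.data)
            std = (var + self.eps).sqrt()
            self._last_mean, self._last_std = mu, std
            xn = (x - mu.reshape(1, c, 1, 1)) / std.reshape(1, c, 1, 1)
            return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)
        # fused training path
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        self._update_running(mu, var, x.data)
        std = np.sqrt(var + self.eps)
        xn = (x.data - mu.reshape(1, c, 1, 1)) / std.reshape(1, c, 1, 1)
        out = Tensor._make(
            xn * self.gamma.data.reshape(1, c, 1, 1) + self.beta.data.reshape(1, c, 1, 1),
            (x, self.gamma, self.beta), None,
        )
        if out.requires_grad:
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            def bw(g):
                gsum = g.sum(axis=(0, 2, 3))
                gx_hat = (g * xn).sum(axis=(0, 2, 3))
                self.beta._accum(gsum)
                self.gamma._accum(gx_hat)
                if x.requires_grad:
                    coef = (self.gamma.data / (std * n)).reshape(1, c, 1, 1)
                    x._accum(coef * (n * g - gsum.reshape(1, c, 1, 1)
                                     - xn * gx_hat.reshape(1, c, 1, 1)))
            out._backward = bw
        self._last_mean, self._last_std = Tensor(mu), Tensor(std)
        return out

    def _update_running(self, mu, var, xdata):
        n = xdata.shape[0] * xdata.shape[2] * xdata.shape[3]
        self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
        unbiased = var * (n / max(n - 1, 1))
        self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased

    def zero_response(self) -> Tensor:
        """BN output for a zero input, w.r.t. the statistics just used."""
        return self.beta - self.gamma * self._last_mean / self._last_std


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __getitem__(self, i):
        return self.mods[i]


class SGD:
    """SGD with momentum and optional weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(lr0: float, epoch: int, total: int, lr_final_frac: float = 0.01) -> float:
    """Cosine annealing from ``lr0`` to ``lr0 * lr_final_frac``."""
    return lr0 * (lr_final_frac + (1 - lr_final_frac) * 0.5 * (1 + math.cos(math.pi * epoch / total)))
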