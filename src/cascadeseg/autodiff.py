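"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the segmentation network needs: broadcasting
arithmetic, matmul, reductions, reshape/transpose/concat, ReLU, exp/log/sqrt,
stride-1 "same" 3-D convolution, 2x max-pooling and 2x linear upsampling.
Tensors wrap float32 numpy arrays and record a backward closure; ``backward()``
walks the graph in reverse topological order.  A global switch (``no_grad``)
disables graph construction, which the EM attention module uses to keep its
inner iteration out of the gradient path.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager suspending graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """A node in the autodiff graph.

    ``data`` is always a float32 ndarray. ``grad`` is populated by
    ``backward()`` for tensors created with ``requires_grad=True`` and for
    intermediates on the path to one.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad or parents else ()
        self._backward = backward

    # ---- graph plumbing ----------------------------------------------------

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

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (two U-Net stages)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- operators ---------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if not req:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=[p for p in parents if p.requires_grad],
                  backward=backward)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---- elementwise -----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


# ---- reductions & shape ----------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    orig = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(orig))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, ts, backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2) if b.data.ndim > 1
                                       else np.outer(g, b.data), a.data.shape))
        if b.requires_grad:
            if a.data.ndim == 1 and b.data.ndim == 2:
                b._accumulate(np.outer(a.data, g))
            else:
                b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return _make(out_data, (a, b), backward)


# ---- spatial ops (single sample, channel-first) ----------------------------

def _conv3d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Cross-correlate x (C,D,H,W) with w (O,C,k,k,k), stride 1, same padding."""
    k = w.shape[-1]
    p = (k - 1) // 2
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))  # (C,D,H,W,k,k,k)
    out = np.tensordot(w, win, axes=([1, 2, 3, 4], [0, 4, 5, 6]))
    return np.ascontiguousarray(out, dtype=np.float32)


def conv3d(x, weight, bias=None) -> Tensor:
    """Stride-1 'same' 3-D convolution of a single sample.

    x: (C_in, D, H, W); weight: (C_out, C_in, k, k, k); bias: (C_out,).
    Odd k required so spatial size is preserved.
    """
    x, weight = _wrap(x), _wrap(weight)
    k = weight.data.shape[-1]
    if k % 2 == 0:
        raise ValueError("conv3d requires odd kernel size")
    if x.data.shape[0] != weight.data.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[0]} channels, "
            f"kernel expects {weight.data.shape[1]}")
    out_data = _conv3d_same(x.data, weight.data)
    parents = [x, weight]
    if bias is not None:
        bias = _wrap(bias)
        out_data = out_data + bias.data[:, None, None, None]
        parents.append(bias)

    def backward(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        if x.requires_grad:
            # dL/dx = correlation of g with spatially flipped, channel-swapped w
            w_t = np.ascontiguousarray(
                weight.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
            x._accumulate(_conv3d_same(g, w_t))
        if weight.requires_grad:
            p = (k - 1) // 2
            xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p))) if p else x.data
            win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
            gw = np.tensordot(g, win, axes=([1, 2, 3], [1, 2, 3]))  # (O,C,k,k,k)
            weight._accumulate(np.ascontiguousarray(gw, dtype=np.float32))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(1, 2, 3)))

    return _make(out_data, parents, backward)


def maxpool3d_2(x) -> Tensor:
    """2x2x2 max pooling, stride 2, over (C, D, H, W). Dims must be even."""
    x = _wrap(x)
    C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError("maxpool3d_2 requires even spatial dimensions")
    v = x.data.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
    v = v.transpose(0, 1, 3, 5, 2, 4, 6).reshape(C, D // 2, H // 2, W // 2, 8)
    idx = v.argmax(axis=-1)
    out_data = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gv = np.zeros((C, D // 2, H // 2, W // 2, 8), dtype=np.float32)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gv = gv.reshape(C, D // 2, H // 2, W // 2, 2, 2, 2)
        gv = gv.transpose(0, 1, 4, 2, 5, 3, 6).reshape(C, D, H, W)
        x._accumulate(gv)

    return _make(np.ascontiguousarray(out_data), (x,), backward)


def _up1d(a: np.ndarray, axis: int) -> np.ndarray:
    """Linear 2x upsampling along one axis (half-voxel aligned, edges clamped)."""
    a = np.moveaxis(a, axis, -1)
    prev = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
    nxt = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    even = 0.75 * a + 0.25 * prev
    odd = 0.75 * a + 0.25 * nxt
    out = np.stack([even, odd], axis=-1).reshape(a.shape[:-1] + (2 * a.shape[-1],))
    return np.moveaxis(out, -1, axis)


def _up1d_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    gx = 0.75 * (ge + go)
    t = 0.25 * ge
    gx[..., :-1] += t[..., 1:]
    gx[..., 0] += t[..., 0]
    u = 0.25 * go
    gx[..., 1:] += u[..., :-1]
    gx[..., -1] += u[..., -1]
    return np.moveaxis(gx, -1, axis)


def upsample3d_2(x) -> Tensor:
    """Trilinear 2x upsampling over the three spatial axes of (C, D, H, W)."""
    x = _wrap(x)
    out_data = x.data
    for ax in (1, 2, 3):
        out_data = _up1d(out_data, ax)
    out_data = np.ascontiguousarray(out_data, dtype=np.float32)

    def backward(g):
        if not x.requires_grad:
            return
        for ax in (3, 2, 1):
            g = _up1d_adjoint(g, ax)
        x._accumulate(np.ascontiguousarray(g, dtype=np.float32))

    return _make(out_data, (x,), backward)


# ---- composite helpers -----------------------------------------------------

def log_softmax(x: Tensor, axis: int = 0) -> Tensor:
    """Numerically stable log-softmax along ``axis`` (max is treated as const)."""
    x = _wrap(x)
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    shifted = x - m
    lse = log(tsum(exp(shifted), axis=axis, keepdims=True))
    return shifted - lse


def softmax(x: Tensor, axis: int = 0) -> Tensor:
    return exp(log_softmax(x, axis=axis))


# ---- parameters, modules, optimizer ----------------------------------------

class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight parameter container with recursive discovery."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect_params(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.named_parameters(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Module):
                    out.extend(item.modules())
        return out


def _collect_params(v) -> list[Parameter]:
    if isinstance(v, Parameter):
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect_params(item))
        return out
    return []


class AdamW:
    """Adam with decoupled weight decay.

    ``beta1`` is the first-moment (momentum) decay; the second-moment decay is
    left at the conventional 0.999.
    """

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 beta1: float = 0.95, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            if self.weight_decay:
                p.data *= (1.0 - self.lr * self.weight_decay)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Kaiming-normal initialisation for ReLU networks."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)
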