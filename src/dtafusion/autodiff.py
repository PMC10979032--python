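"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The graphs handled here are small (tens of nodes, feature widths of a few
hundred at most), so the engine favours clarity over kernel fusion: every
operation records a closure that scatters the upstream gradient to its
parents, and :meth:`Tensor.backward` walks the tape in reverse topological
order. Only the operations the affinity network needs are provided.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "add", "sub", "mul", "matmul", "scale", "square",
    "relu", "elu", "tanh",
    "softmax_rows", "sum_", "mean_", "max_axis",
    "transpose", "reshape", "concat", "take_rows", "embedding", "pad_rows", "slice_rows",
    "conv1d_nodes", "maxpool1d_nodes", "dropout",
    "Adam",
]


class Tensor:
    """A NumPy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.grad is None and not t._parents:
                t.grad = g.copy()
            elif not t._parents:
                t.grad = t.grad + g
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # ergonomic operators -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __mul__(self, other):
        if np.isscalar(other):
            return scale(self, other)
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ("name",)

    def __init__(self, data, name=""):
        super().__init__(data, requires_grad=True)
        self.name = name


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# arithmetic


def add(a, b):
    out = Tensor(a.data + b.data, parents=(a, b),
                 backward=lambda g: ((a, _unbroadcast(g, a.data.shape)),
                                     (b, _unbroadcast(g, b.data.shape))))
    return out


def sub(a, b):
    return Tensor(a.data - b.data, parents=(a, b),
                  backward=lambda g: ((a, _unbroadcast(g, a.data.shape)),
                                      (b, _unbroadcast(-g, b.data.shape))))


def mul(a, b):
    return Tensor(a.data * b.data, parents=(a, b),
                  backward=lambda g: ((a, _unbroadcast(g * b.data, a.data.shape)),
                                      (b, _unbroadcast(g * a.data, b.data.shape))))


def scale(a, c):
    c = float(c)
    return Tensor(a.data * c, parents=(a,), backward=lambda g: ((a, g * c),))


def square(a):
    return Tensor(a.data ** 2, parents=(a,), backward=lambda g: ((a, 2.0 * a.data * g),))


def matmul(a, b):
    def bw(g):
        ga = g @ b.data.T if b.data.ndim == 2 else np.outer(g, b.data)
        gb = a.data.T @ g if a.data.ndim == 2 else np.outer(a.data, g)
        if a.data.ndim == 1 and b.data.ndim == 2:
            ga = g @ b.data.T
            gb = np.outer(a.data, g)
        return ((a, ga.reshape(a.data.shape)), (b, gb.reshape(b.data.shape)))

    return Tensor(a.data @ b.data, parents=(a, b), backward=bw)


# ---------------------------------------------------------------------------
# nonlinearities


def relu(a):
    mask = a.data > 0
    return Tensor(a.data * mask, parents=(a,), backward=lambda g: ((a, g * mask),))


def elu(a, alpha=1.0):
    neg = a.data <= 0
    out = np.where(neg, alpha * np.expm1(a.data), a.data)
    local = np.where(neg, out + alpha, 1.0)
    return Tensor(out, parents=(a,), backward=lambda g: ((a, g * local),))


def tanh(a):
    out = np.tanh(a.data)
    return Tensor(out, parents=(a,), backward=lambda g: ((a, g * (1.0 - out ** 2)),))


def softmax_rows(a):
    """Row-wise softmax over the last axis."""
    z = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=-1, keepdims=True)
        return ((a, s * (g - dot)),)

    return Tensor(s, parents=(a,), backward=bw)


# ---------------------------------------------------------------------------
# reductions


def sum_(a, axis=None):
    def bw(g):
        if axis is None:
            return ((a, np.broadcast_to(g, a.data.shape).copy()),)
        return ((a, np.broadcast_to(np.expand_dims(g, axis), a.data.shape).copy()),)

    return Tensor(a.data.sum(axis=axis), parents=(a,), backward=bw)


def mean_(a, axis=None):
    n = a.data.size if axis is None else a.data.shape[axis]
    return scale(sum_(a, axis=axis), 1.0 / n)


def max_axis(a, axis=0):
    """Max-reduce along ``axis``; the gradient flows to the arg-max entries."""
    idx = a.data.argmax(axis=axis)
    out = a.data.max(axis=axis)

    def bw(g):
        full = np.zeros_like(a.data)
        grid = np.indices(out.shape)
        sel = list(grid)
        sel.insert(axis, idx)
        full[tuple(sel)] = g
        return ((a, full),)

    return Tensor(out, parents=(a,), backward=bw)


# ---------------------------------------------------------------------------
# structure


def transpose(a):
    return Tensor(a.data.T, parents=(a,), backward=lambda g: ((a, g.T),))


def reshape(a, shape):
    return Tensor(a.data.reshape(shape), parents=(a,),
                  backward=lambda g: ((a, g.reshape(a.data.shape)),))


def concat(tensors, axis=0):
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        pieces = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            pieces.append((t, g[tuple(sl)]))
        return tuple(pieces)

    return Tensor(out, parents=tuple(tensors), backward=bw)


def take_rows(a, index):
    """Select rows (axis 0) by an integer index array; grads scatter-add back."""
    index = np.asarray(index, dtype=np.intp)

    def bw(g):
        full = np.zeros_like(a.data)
        np.add.at(full, index, g)
        return ((a, full),)

    return Tensor(a.data[index], parents=(a,), backward=bw)


def embedding(table, index):
    """Look up rows of a (vocab, dim) table; alias of take_rows for clarity."""
    return take_rows(table, index)


def pad_rows(a, before, after):
    pad = [(before, after)] + [(0, 0)] * (a.data.ndim - 1)
    out = np.pad(a.data, pad)

    def bw(g):
        sl = slice(before, out.shape[0] - after)
        return ((a, g[sl]),)

    return Tensor(out, parents=(a,), backward=bw)


def slice_rows(a, start, stop):
    def bw(g):
        full = np.zeros_like(a.data)
        full[start:stop] = g
        return ((a, full),)

    return Tensor(a.data[start:stop], parents=(a,), backward=bw)


def conv1d_nodes(x, kernel, bias=None):
    """Width-3, same-padded 1-D convolution along the node axis.

    ``x`` is (L, d_in); ``kernel`` is (3, d_in, d_out). Implemented as three
    shifted matrix products so the gradient falls out of existing ops.
    """
    L = x.data.shape[0]
    xp = pad_rows(x, 1, 1)
    taps = []
    for k in range(3):
        tap = _kernel_tap(kernel, k)
        taps.append(matmul(slice_rows(xp, k, k + L), tap))
    out = add(add(taps[0], taps[1]), taps[2])
    if bias is not None:
        out = add(out, bias)
    return out


def _kernel_tap(kernel, k):
    def bw(g):
        full = np.zeros_like(kernel.data)
        full[k] = g
        return ((kernel, full),)

    return Tensor(kernel.data[k], parents=(kernel,), backward=bw)


def maxpool1d_nodes(x, window=3, stride=2):
    """Same-padded max pooling along the node axis; output length ceil(L/2)."""
    L, d = x.data.shape
    out_len = int(np.ceil(L / stride))
    pad_total = max((out_len - 1) * stride + window - L, 0)
    before = pad_total // 2
    padded = np.full((L + pad_total, d), -np.inf)
    padded[before:before + L] = x.data
    windows = np.stack([padded[t * stride:t * stride + window] for t in range(out_len)])
    flat_arg = windows.argmax(axis=1)  # (out_len, d) index within window
    out = windows.max(axis=1)

    def bw(g):
        full = np.zeros_like(x.data)
        for t in range(out_len):
            src = t * stride + flat_arg[t] - before
            valid = (src >= 0) & (src < L)
            cols = np.nonzero(valid)[0]
            np.add.at(full, (src[cols], cols), g[t, cols])
        return ((x, full),)

    return Tensor(out, parents=(x,), backward=bw)


def dropout(a, rate, rng, training):
    if not training or rate <= 0.0:
        return a
    keep = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return Tensor(a.data * keep, parents=(a,), backward=lambda g: ((a, g * keep),))


# ---------------------------------------------------------------------------
# optimisation


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

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

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
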