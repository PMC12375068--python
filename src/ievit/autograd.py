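"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for convolutional/transformer networks:
tensors wrap ``numpy`` arrays, operations record their inputs and a closure
computing vector-Jacobian products, and :meth:`Tensor.backward` walks the tape
in reverse topological order.  Convolutions are implemented with the
shift-and-accumulate decomposition (one matmul / elementwise product per
kernel offset), which keeps peak memory proportional to the feature map
rather than to the unfolded patch matrix.

All operations preserve the dtype of their inputs; the layers in this package
use float32, while gradient checks in the test-suite run in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological sort
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._vjp is None:
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*ts):
    return any(isinstance(t, Tensor) and (t.requires_grad or t._parents) for t in ts)


def _node(data, parents, vjp):
    if _track(*parents):
        return Tensor(data, _parents=tuple(parents), _vjp=vjp)
    return Tensor(data)


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _node(out, (a, b), vjp)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def vjp(g):
        return (_unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape))

    return _node(out, (a, b), vjp)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def vjp(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        if ga.shape != a.shape:
            ga = _unbroadcast(ga, a.shape)
        if gb.shape != b.shape:
            gb = _unbroadcast(gb, b.shape)
        return ga, gb

    return _node(out, (a, b), vjp)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.shape
    out = a.data.reshape(shape)

    def vjp(g):
        return (g.reshape(old),)

    return _node(out, (a,), vjp)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)
    out = a.data.transpose(axes)

    def vjp(g):
        return (g.transpose(inv),)

    return _node(out, (a,), vjp)


def take(a, idx) -> Tensor:
    a = as_tensor(a)
    out = a.data[idx]

    def vjp(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return (ga,)

    return _node(out, (a,), vjp)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(out, tuple(tensors), vjp)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).astype(a.dtype, copy=False),)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.shape).astype(a.dtype, copy=False),)

    return _node(out, (a,), vjp)


def mean_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[i] for i in ax]))
    return mul(sum_(a, axis, keepdims), 1.0 / n)


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))

    def vjp(g):
        return (g * out * (1.0 - out),)

    return _node(out, (a,), vjp)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0)

    def vjp(g):
        return (g * (a.data > 0),)

    return _node(out, (a,), vjp)


def swish(a) -> Tensor:
    """x * sigmoid(x), applied elementwise."""
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = a.data * s

    def vjp(g):
        return (g * (s + a.data * s * (1.0 - s)),)

    return _node(out, (a,), vjp)


def softmax(a, axis=-1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return _node(out, (a,), vjp)


def softmax_cross_entropy(logits, labels) -> Tensor:
    """Mean categorical cross-entropy from raw logits and integer labels."""
    logits = as_tensor(logits)
    labels = np.asarray(labels)
    n = logits.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    loss = -logp[np.arange(n), labels].mean()

    def vjp(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        return (g * p / n,)

    return _node(np.asarray(loss, dtype=logits.dtype), (logits,), vjp)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def layer_norm(x, gamma, beta, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis; gamma/beta have that axis's length."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data * xhat + beta.data

    def vjp(g):
        dxhat = g * gamma.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        dx = inv * (dxhat - m1 - xhat * m2)
        axes = tuple(range(g.ndim - 1))
        return (dx.astype(x.dtype, copy=False),
                (g * xhat).sum(axis=axes),
                g.sum(axis=axes))

    return _node(out, (x, gamma, beta), vjp)


def batch_norm(x, gamma, beta, running_mean, running_var,
               training: bool, momentum: float = 0.9, eps: float = 1e-3) -> Tensor:
    """Channel-wise batch normalization for NHWC maps.

    In training mode the batch statistics are used and the running buffers
    (plain numpy arrays) are updated in place; in inference mode the running
    buffers are used, making the output deterministic per sample.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = tuple(range(x.ndim - 1))
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mu
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data * xhat + beta.data
    n = int(np.prod([x.shape[i] for i in axes]))

    def vjp(g):
        dxhat = g * gamma.data
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        if training:
            m1 = dxhat.mean(axis=axes)
            m2 = (dxhat * xhat).mean(axis=axes)
            dx = inv * (dxhat - m1 - xhat * m2)
        else:
            dx = inv * dxhat
        return dx.astype(x.dtype, copy=False), dgamma, dbeta

    del n
    return _node(out, (x, gamma, beta), vjp)


# ---------------------------------------------------------------------------
# convolution and pooling (NHWC, "same" padding)
# ---------------------------------------------------------------------------

def _same_pads(k: int, stride: int, size: int):
    """Total padding so that output size = ceil(size / stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def conv2d(x, w, b=None, stride: int = 1) -> Tensor:
    """2-D cross-correlation, weights (K, K, C_in, C_out), same padding.

    Decomposed into one (C_in x C_out) matmul per kernel offset, which is
    BLAS-friendly and gives a cheap exact backward pass.
    """
    x, w = as_tensor(x), as_tensor(w)
    K = w.shape[0]
    B, H, W_, C = x.shape
    pt, pb = _same_pads(K, stride, H)
    pl, pr = _same_pads(K, stride, W_)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    OH, OW = -(-H // stride), -(-W_ // stride)
    Cout = w.shape[3]
    out = np.zeros((B, OH, OW, Cout), dtype=x.dtype)
    slices = []
    for ki in range(K):
        for kj in range(K):
            sl = xp[:, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride, :]
            slices.append(sl)
            out += sl @ w.data[ki, kj]
    if b is not None:
        b = as_tensor(b)
        out += b.data

    def vjp(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        idx = 0
        for ki in range(K):
            for kj in range(K):
                sl = slices[idx]
                idx += 1
                dw[ki, kj] = np.tensordot(sl, g, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, ki:ki + stride * OH:stride,
                    kj:kj + stride * OW:stride, :] += g @ w.data[ki, kj].T
        dx = dxp[:, pt:pt + H, pl:pl + W_, :]
        if b is not None:
            return dx, dw, g.sum(axis=(0, 1, 2))
        return dx, dw

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, vjp)


def depthwise_conv2d(x, w, stride: int = 1) -> Tensor:
    """Depthwise convolution, weights (K, K, C, alpha); output C*alpha channels."""
    x, w = as_tensor(x), as_tensor(w)
    K, _, C, alpha = w.shape
    B, H, W_, _ = x.shape
    pt, pb = _same_pads(K, stride, H)
    pl, pr = _same_pads(K, stride, W_)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    OH, OW = -(-H // stride), -(-W_ // stride)
    out5 = np.zeros((B, OH, OW, C, alpha), dtype=x.dtype)
    slices = []
    for ki in range(K):
        for kj in range(K):
            sl = xp[:, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride, :]
            slices.append(sl)
            out5 += sl[..., None] * w.data[ki, kj]
    out = out5.reshape(B, OH, OW, C * alpha)

    def vjp(g):
        g5 = g.reshape(B, OH, OW, C, alpha)
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        idx = 0
        for ki in range(K):
            for kj in range(K):
                sl = slices[idx]
                idx += 1
                dw[ki, kj] = np.einsum("bhwc,bhwca->ca", sl, g5)
                dxp[:, ki:ki + stride * OH:stride,
                    kj:kj + stride * OW:stride, :] += (g5 * w.data[ki, kj]).sum(-1)
        return dxp[:, pt:pt + H, pl:pl + W_, :], dw

    return _node(out, (x, w), vjp)


def max_pool2d(x, k: int = 3, stride: int = 1) -> Tensor:
    x = as_tensor(x)
    B, H, W_, C = x.shape
    pt, pb = _same_pads(k, stride, H)
    pl, pr = _same_pads(k, stride, W_)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)),
                constant_values=-np.inf)
    OH, OW = -(-H // stride), -(-W_ // stride)
    out = np.full((B, OH, OW, C), -np.inf, dtype=x.dtype)
    arg = np.zeros((B, OH, OW, C), dtype=np.int8)
    for idx in range(k * k):
        ki, kj = divmod(idx, k)
        sl = xp[:, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride, :]
        better = sl > out
        out = np.where(better, sl, out)
        arg = np.where(better, np.int8(idx), arg)

    def vjp(g):
        dxp = np.zeros_like(xp)
        for idx in range(k * k):
            ki, kj = divmod(idx, k)
            dxp[:, ki:ki + stride * OH:stride,
                kj:kj + stride * OW:stride, :] += g * (arg == idx)
        return (dxp[:, pt:pt + H, pl:pl + W_, :],)

    return _node(out, (x,), vjp)


def avg_pool2d(x, k: int = 3, stride: int = 1) -> Tensor:
    """Average pooling with same padding; edge windows average valid cells only."""
    x = as_tensor(x)
    B, H, W_, C = x.shape
    pt, pb = _same_pads(k, stride, H)
    pl, pr = _same_pads(k, stride, W_)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    ones = np.pad(np.ones((1, H, W_, 1), dtype=x.dtype),
                  ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    OH, OW = -(-H // stride), -(-W_ // stride)
    out = np.zeros((B, OH, OW, C), dtype=x.dtype)
    cnt = np.zeros((1, OH, OW, 1), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            out += xp[:, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride, :]
            cnt += ones[:, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride, :]
    out /= cnt

    def vjp(g):
        dxp = np.zeros_like(xp)
        gs = g / cnt
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki:ki + stride * OH:stride,
                    kj:kj + stride * OW:stride, :] += gs
        return (dxp[:, pt:pt + H, pl:pl + W_, :],)

    return _node(out, (x,), vjp)


def global_avg_pool(x) -> Tensor:
    """Spatial mean per channel: (B, H, W, C) -> (B, C)."""
    return mean_(as_tensor(x), axis=(1, 2))
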