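"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: float64 tensors, a handful of ops (dense and
2-D convolution arithmetic, pooling, pointwise nonlinearities, reductions,
concatenation) — exactly what a VGG-style classifier with channel/spatial
attention needs for training and for gradient-based class-activation maps.

Gradients are accumulated on every node that requires them, including
intermediate activations, so a caller can read ``tensor.grad`` for any
tensor in the graph after ``backward()`` (used by Grad-CAM).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "rsub_const",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "concat",
    "reshape",
    "mean_axes",
    "max_axis",
    "conv2d",
    "maxpool2x2",
    "softmax",
    "softmax_cross_entropy",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph construction helpers -------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise arithmetic ---------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(-_unbroadcast(g, b.shape))

    return _node(a.data - b.data, (a, b), backward)


def rsub_const(c: float, a: Tensor) -> Tensor:
    """c - a, for complementary gates (1 - Ma)."""

    def backward(g):
        a._accumulate(-g)

    return _node(c - a.data, (a,), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _node(a.data @ b.data, (a, b), backward)


# -- nonlinearities ------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(np.where(mask, a.data, 0.0), (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable logistic
    x = a.data
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)

    def backward(g):
        a._accumulate(g * out * (1.0 - out))

    return _node(out, (a,), backward)


# -- shape ops -----------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        a._accumulate(g.reshape(a.shape))

    return _node(a.data.reshape(shape), (a,), backward)


# -- reductions ----------------------------------------------------------

def mean_axes(a: Tensor, axes, keepdims: bool = False) -> Tensor:
    axes = tuple(axes)
    n = int(np.prod([a.shape[ax] for ax in axes]))

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g / n, a.shape))

    return _node(a.data.mean(axis=axes, keepdims=keepdims), (a,), backward)


def max_axis(a: Tensor, axis: int, keepdims: bool = True) -> Tensor:
    idx = np.argmax(a.data, axis=axis)
    out = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(idx, axis), g, axis=axis)
        a._accumulate(ga)

    return _node(out if keepdims else np.squeeze(out, axis), (a,), backward)


# -- convolution and pooling (NHWC, stride 1, zero 'same' padding) -------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, zero-padded 'same' convolution.

    x: (N, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,) or None.
    Implemented as kh*kw shifted matrix products so no im2col buffer of
    size N*H*W*kh*kw*Cin is ever materialised.
    """
    N, H, W, Cin = x.shape
    kh, kw, _, Cout = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.zeros((N, H, W, Cout))
    for i in range(kh):
        for j in range(kw):
            out += xp[:, i : i + H, j : j + W, :] @ w.data[i, j]
    if b is not None:
        out += b.data

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i : i + H, j : j + W, :] += g @ w.data[i, j].T
            x._accumulate(gxp[:, ph : ph + H, pw : pw + W, :])
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[i, j] = np.tensordot(
                        xp[:, i : i + H, j : j + W, :], g, axes=([0, 1, 2], [0, 1, 2])
                    )
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (trailing odd row/col dropped)."""
    N, H, W, C = x.shape
    Hc, Wc = (H // 2) * 2, (W // 2) * 2
    xc = x.data[:, :Hc, :Wc, :]
    r = xc.reshape(N, Hc // 2, 2, Wc // 2, 2, C)
    # windows last so argmax is per 2x2 patch
    rw = r.transpose(0, 1, 3, 5, 2, 4).reshape(N, Hc // 2, Wc // 2, C, 4)
    idx = rw.argmax(axis=-1)
    out = np.take_along_axis(rw, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros((N, Hc // 2, Wc // 2, C, 4))
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gr = gw.reshape(N, Hc // 2, Wc // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        gx = np.zeros_like(x.data)
        gx[:, :Hc, :Wc, :] = gr.reshape(N, Hc, Wc, C)
        x._accumulate(gx)

    return _node(out, (x,), backward)


# -- classification head -------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean categorical cross-entropy over a batch of integer labels.

    Returns the scalar loss tensor and the softmax probabilities.
    """
    n = logits.shape[0]
    probs = softmax(logits.data)
    eps = 1e-12
    loss_val = -np.log(probs[np.arange(n), labels] + eps).mean()

    def backward(g):
        gl = probs.copy()
        gl[np.arange(n), labels] -= 1.0
        logits._accumulate(g * gl / n)

    return _node(loss_val, (logits,), backward), probs
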