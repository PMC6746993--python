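"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the peptide classifiers need: broadcasting
add/mul, matmul, the usual pointwise nonlinearities, 1-D convolution with
"same" padding, non-overlapping 1-D max pooling, concatenation, slicing and
reshaping, inverted dropout, and a fused softmax cross-entropy loss.
Gradients flow through a topologically sorted tape rooted at a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "tanh",
    "sigmoid",
    "conv1d_same",
    "maxpool1d",
    "concat",
    "reshape",
    "slice_axis1",
    "slice_cols",
    "dropout",
    "softmax",
    "softmax_cross_entropy",
]


class Tensor:
    """A numpy array plus gradient bookkeeping.

    Leaf tensors created with ``requires_grad=True`` are trainable
    parameters; intermediate tensors carry a closure that propagates the
    upstream gradient to their parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: BPTT graphs exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (reverse numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward):
    return Tensor(data, parents=parents, backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - out_data * out_data))

    return _make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (x,), backward)


def _im2col(x, k):
    """(N, L, C) -> (N, L, k*C) windows of width k, zero-padded ("same")."""
    n, length, c = x.shape
    pad_left = (k - 1) // 2
    pad_right = k - 1 - pad_left
    xp = np.pad(x, ((0, 0), (pad_left, pad_right), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    # windows: (N, L, C, k) -> (N, L, k, C)
    return np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(n, length, k * c)


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution, stride 1, zero-padded so output length equals input.

    ``x``: (N, L, C_in); ``w``: (k, C_in, C_out); ``b``: (C_out,).
    """
    k, c_in, c_out = w.data.shape
    n, length, _ = x.data.shape
    cols = _im2col(x.data, k)  # (N, L, k*C_in)
    w2 = w.data.reshape(k * c_in, c_out)
    out_data = cols.reshape(n * length, k * c_in) @ w2 + b.data
    out_data = out_data.reshape(n, length, c_out)

    def backward(g):
        g2 = g.reshape(n * length, c_out)
        if w.requires_grad:
            gw = cols.reshape(n * length, k * c_in).T @ g2
            w._accumulate(gw.reshape(k, c_in, c_out))
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            gcols = (g2 @ w2.T).reshape(n, length, k, c_in)
            pad_left = (k - 1) // 2
            gx = np.zeros((n, length + k - 1, c_in))
            for j in range(k):  # k is small (3..9); scatter-add per tap
                gx[:, j : j + length, :] += gcols[:, :, j, :]
            x._accumulate(gx[:, pad_left : pad_left + length, :])

    return _make(out_data, (x, w, b), backward)


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling along axis 1; length must divide evenly."""
    n, length, c = x.data.shape
    if length % pool != 0:
        raise ValueError(f"length {length} not divisible by pool width {pool}")
    blocks = x.data.reshape(n, length // pool, pool, c)
    arg = blocks.argmax(axis=2)
    out_data = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        if x.requires_grad:
            gb = np.zeros_like(blocks)
            np.put_along_axis(gb, arg[:, :, None, :], g[:, :, None, :], axis=2)
            x._accumulate(gb.reshape(n, length, c))

    return _make(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tuple(tensors), backward)


def reshape(x: Tensor, shape) -> Tensor:
    out_data = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.data.shape))

    return _make(out_data, (x,), backward)


def slice_axis1(x: Tensor, i: int) -> Tensor:
    """x[:, i, :] for stepping a recurrence over the position axis."""
    out_data = x.data[:, i, :]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, i, :] = g
            x._accumulate(gx)

    return _make(out_data, (x,), backward)


def slice_cols(x: Tensor, a: int, b: int) -> Tensor:
    out_data = x.data[:, a:b]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, a:b] = g
            x._accumulate(gx)

    return _make(out_data, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain-numpy softmax over the last axis (inference path, no grad)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean sparse cross-entropy of integer ``labels`` under softmax(logits)."""
    labels = np.asarray(labels, dtype=np.int64)
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(g * grad / n)

    return _make(np.asarray(loss), (logits,), backward)
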