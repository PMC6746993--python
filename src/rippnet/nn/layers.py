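"""Trainable layers composed from the autograd primitives.

Every layer owns named parameter tensors (exposed via ``parameters()``) so a
model can be flattened into a name -> array mapping for serialization. The
``training`` flag and an explicit ``rng`` make stochastic regularisation
(dropout, recurrent dropout) reproducible and strictly off at inference.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    name: str

    def parameters(self) -> list[tuple[str, Tensor]]:
        return [(f"{self.name}/{k}", v) for k, v in self._params()]

    def _params(self) -> list[tuple[str, Tensor]]:
        return []


class Dense(Layer):
    def __init__(self, name, rng, n_in, n_out, activation=None):
        self.name = name
        self.activation = activation
        self.w = Tensor(glorot_uniform(rng, (n_in, n_out), n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def _params(self):
        return [("W", self.w), ("b", self.b)]

    def __call__(self, x, training=False, rng=None):
        out = ag.add(ag.matmul(x, self.w), self.b)
        if self.activation == "relu":
            out = ag.relu(out)
        elif self.activation == "tanh":
            out = ag.tanh(out)
        return out


class Conv1D(Layer):
    """Stride-1 "same"-padded convolution over the position axis, ReLU."""

    def __init__(self, name, rng, c_in, c_out, kernel):
        self.name = name
        self.kernel = kernel
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.w = Tensor(
            glorot_uniform(rng, (kernel, c_in, c_out), fan_in, fan_out), requires_grad=True
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def _params(self):
        return [("W", self.w), ("b", self.b)]

    def __call__(self, x, training=False, rng=None):
        return ag.relu(ag.conv1d_same(x, self.w, self.b))


class MaxPool1D(Layer):
    def __init__(self, pool):
        self.name = f"maxpool{pool}"
        self.pool = pool

    def __call__(self, x, training=False, rng=None):
        return ag.maxpool1d(x, self.pool)


class LSTM(Layer):
    """Single-direction LSTM returning the final hidden state.

    Gate order in the stacked weight matrices is (input, forget, cell,
    output). ``recurrent_dropout`` drops the hidden state entering the
    recurrent matmul with one mask shared across all positions, as is
    standard for variational recurrent dropout; it is inactive at inference.
    """

    def __init__(self, name, rng, n_in, units, recurrent_dropout=0.0):
        self.name = name
        self.units = units
        self.recurrent_dropout = recurrent_dropout
        self.wx = Tensor(
            glorot_uniform(rng, (n_in, 4 * units), n_in, 4 * units), requires_grad=True
        )
        self.wh = Tensor(
            glorot_uniform(rng, (units, 4 * units), units, 4 * units), requires_grad=True
        )
        bias = np.zeros(4 * units)
        bias[units : 2 * units] = 1.0  # forget-gate bias 1: standard LSTM practice
        self.b = Tensor(bias, requires_grad=True)

    def _params(self):
        return [("Wx", self.wx), ("Wh", self.wh), ("b", self.b)]

    def __call__(self, x, training=False, rng=None, reverse=False):
        n, length, _ = x.data.shape
        u = self.units
        h = Tensor(np.zeros((n, u)))
        c = Tensor(np.zeros((n, u)))
        drop_mask = None
        if training and self.recurrent_dropout > 0.0:
            keep = rng.random((n, u)) >= self.recurrent_dropout
            drop_mask = Tensor(keep / (1.0 - self.recurrent_dropout))
        steps = range(length - 1, -1, -1) if reverse else range(length)
        for t in steps:
            xt = ag.slice_axis1(x, t)
            h_rec = ag.mul(h, drop_mask) if drop_mask is not None else h
            gates = ag.add(ag.add(ag.matmul(xt, self.wx), ag.matmul(h_rec, self.wh)), self.b)
            i = ag.sigmoid(ag.slice_cols(gates, 0, u))
            f = ag.sigmoid(ag.slice_cols(gates, u, 2 * u))
            g = ag.tanh(ag.slice_cols(gates, 2 * u, 3 * u))
            o = ag.sigmoid(ag.slice_cols(gates, 3 * u, 4 * u))
            c = ag.add(ag.mul(f, c), ag.mul(i, g))
            h = ag.mul(o, ag.tanh(c))
        return h


class BiLSTM(Layer):
    """Forward and backward LSTMs over the sequence; final states concatenated."""

    def __init__(self, name, rng, n_in, units, recurrent_dropout=0.0):
        self.name = name
        self.fwd = LSTM(f"{name}/fwd", rng, n_in, units, recurrent_dropout)
        self.bwd = LSTM(f"{name}/bwd", rng, n_in, units, recurrent_dropout)

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()

    def __call__(self, x, training=False, rng=None):
        hf = self.fwd(x, training=training, rng=rng)
        hb = self.bwd(x, training=training, rng=rng, reverse=True)
        return ag.concat([hf, hb], axis=1)


class Dropout(Layer):
    def __init__(self, rate):
        self.name = f"dropout{rate}"
        self.rate = rate

    def __call__(self, x, training=False, rng=None):
        if not training:
            return x
        return ag.dropout(x, self.rate, rng)


class Flatten(Layer):
    name = "flatten"

    def __call__(self, x, training=False, rng=None):
        n = x.data.shape[0]
        return ag.reshape(x, (n, -1))
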