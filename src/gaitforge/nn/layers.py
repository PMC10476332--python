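"""Layers with explicit forward/backward passes.

Conventions: activations are strings ("linear", "sigmoid", "tanh",
"leaky_relu"); sequence tensors are (batch, length, channels); dense inputs
are (batch, features).  Each layer stores its parameters in ``params`` and,
after ``backward``, the matching gradients in ``grads``.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
from scipy.special import expit

LEAKY_SLOPE = 0.2  # Pix2Pix convention


def sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def leaky_relu(x: np.ndarray, alpha: float = LEAKY_SLOPE) -> np.ndarray:
    return np.where(x >= 0, x, alpha * x)


def _activation(name: str) -> Tuple[Callable, Callable]:
    """(f, df_from_preact_and_out) pair for a named activation."""
    if name == "linear":
        return (lambda z: z), (lambda z, a: np.ones_like(z))
    if name == "sigmoid":
        return sigmoid, (lambda z, a: a * (1.0 - a))
    if name == "tanh":
        return np.tanh, (lambda z, a: 1.0 - a**2)
    if name == "leaky_relu":
        return (
            lambda z: leaky_relu(z),
            lambda z, a: np.where(z >= 0, 1.0, LEAKY_SLOPE),
        )
    raise ValueError(f"unknown activation {name!r}")


def _glorot(rng: np.random.Generator, shape: Tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


class Layer:
    params: Dict[str, np.ndarray]
    grads: Dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Dense(Layer):
    """Fully connected layer on (batch, features) inputs."""

    def __init__(self, in_dim: int, units: int, activation: str = "linear",
                 rng: Optional[np.random.Generator] = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _glorot(rng, (in_dim, units), in_dim, units)
        self.params["b"] = np.zeros(units)
        self.act_name = activation
        self._f, self._df = _activation(activation)

    def forward(self, x, train=False):
        self._x = x
        self._z = x @ self.params["W"] + self.params["b"]
        self._a = self._f(self._z)
        return self._a

    def backward(self, dout):
        dz = dout * self._df(self._z, self._a)
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T


class PhaseDense(Layer):
    """Dense layer applied along the sequence axis, shared across channels.

    Maps (batch, L_in, C) -> (batch, units, C): each channel's length-L
    profile passes through the same (L_in x units) weight matrix.  This is
    how a trailing dense layer can reshape a per-channel sequence while
    keeping the channel count.
    """

    def __init__(self, in_len: int, units: int, activation: str = "linear",
                 rng: Optional[np.random.Generator] = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _glorot(rng, (in_len, units), in_len, units)
        self.params["b"] = np.zeros(units)
        self._f, self._df = _activation(activation)

    def forward(self, x, train=False):
        b, L, c = x.shape
        self._shape = (b, L, c)
        self._xt = x.transpose(0, 2, 1).reshape(b * c, L)
        self._z = self._xt @ self.params["W"] + self.params["b"]
        self._a = self._f(self._z)
        units = self.params["W"].shape[1]
        return self._a.reshape(b, c, units).transpose(0, 2, 1)

    def backward(self, dout):
        b, L, c = self._shape
        units = self.params["W"].shape[1]
        d = dout.transpose(0, 2, 1).reshape(b * c, units)
        dz = d * self._df(self._z, self._a)
        self.grads["W"] = self._xt.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        dx = dz @ self.params["W"].T
        return dx.reshape(b, c, L).transpose(0, 2, 1)


def _same_pad(L: int, kernel: int, stride: int) -> Tuple[int, int]:
    out = -(-L // stride)  # ceil
    total = max((out - 1) * stride + kernel - L, 0)
    left = total // 2
    return left, total - left


class Conv1D(Layer):
    """1-D convolution with 'same' padding on (batch, L, C_in) inputs."""

    def __init__(self, in_ch: int, filters: int, kernel: int, stride: int = 1,
                 activation: str = "linear",
                 rng: Optional[np.random.Generator] = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride = kernel, stride
        fan_in = kernel * in_ch
        self.params["W"] = _glorot(rng, (kernel * in_ch, filters), fan_in, filters)
        self.params["b"] = np.zeros(filters)
        self._f, self._df = _activation(activation)

    def forward(self, x, train=False):
        b, L, c = x.shape
        left, right = _same_pad(L, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        self._pad = (left, right, L)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        win = win[:, :: self.stride]           # (b, Lout, c, k)
        self._col = win.transpose(0, 1, 3, 2).reshape(b, -1, self.kernel * c)
        self._z = self._col @ self.params["W"] + self.params["b"]
        self._a = self._f(self._z)
        return self._a

    def backward(self, dout):
        b, Lout, f = dout.shape
        k = self.kernel
        left, right, L = self._pad
        c = self._col.shape[2] // k
        dz = dout * self._df(self._z, self._a)
        self.grads["W"] = (
            self._col.reshape(-1, self._col.shape[2]).T @ dz.reshape(-1, f)
        )
        self.grads["b"] = dz.sum(axis=(0, 1))
        dcol = dz @ self.params["W"].T            # (b, Lout, k*c)
        dcol = dcol.reshape(b, Lout, k, c)
        dxp = np.zeros((b, L + left + right, c))
        s = self.stride
        for kk in range(k):
            # window start positions are stride-spaced, hence unique slices
            dxp[:, kk : kk + Lout * s : s] += dcol[:, :, kk, :]
        return dxp[:, left : left + L, :]


class ConvTranspose1D(Layer):
    """1-D transposed convolution; with stride == kernel the output length
    is exactly ``L * stride`` (the 'same'-padding upsampling case)."""

    def __init__(self, in_ch: int, filters: int, kernel: int = 2, stride: int = 2,
                 activation: str = "linear",
                 rng: Optional[np.random.Generator] = None) -> None:
        super().__init__()
        if kernel != stride:
            raise ValueError("only kernel == stride upsampling is supported")
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride = kernel, stride
        self.params["W"] = _glorot(rng, (kernel, in_ch, filters), in_ch, filters)
        self.params["b"] = np.zeros(filters)
        self._f, self._df = _activation(activation)

    def forward(self, x, train=False):
        self._x = x
        b, L, c = x.shape
        # y[:, t, k, f] = sum_c x[:, t, c] W[k, c, f]  -> interleave over k
        y = np.einsum("blc,kcf->blkf", x, self.params["W"])
        f = self.params["W"].shape[2]
        self._z = y.reshape(b, L * self.kernel, f) + self.params["b"]
        self._a = self._f(self._z)
        return self._a

    def backward(self, dout):
        b, Lk, f = dout.shape
        k = self.kernel
        L = Lk // k
        dz = (dout * self._df(self._z, self._a)).reshape(b, L, k, f)
        self.grads["W"] = np.einsum("blc,blkf->kcf", self._x, dz)
        self.grads["b"] = dz.sum(axis=(0, 1, 2))
        return np.einsum("blkf,kcf->blc", dz, self.params["W"])


class LSTM(Layer):
    """LSTM over (batch, T, in_dim), returning the final hidden state.

    Gates use the standard sigmoid; ``activation`` sets the cell-candidate
    and output squashing nonlinearity (the knob the high-level frameworks
    call the layer's activation), so "sigmoid" or "leaky_relu" cells are
    expressible alongside the classic tanh.
    """

    def __init__(self, in_dim: int, units: int, activation: str = "tanh",
                 rng: Optional[np.random.Generator] = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.units = units
        u = units
        # framework-conventional init: glorot input kernel, per-gate
        # orthogonal recurrent kernel, unit forget-gate bias
        self.params["Wx"] = _glorot(rng, (in_dim, 4 * u), in_dim, 4 * u)
        self.params["Wh"] = np.concatenate(
            [_orthogonal(rng, u) for _ in range(4)], axis=1
        )
        b = np.zeros(4 * u)
        b[u : 2 * u] = 1.0  # forget-gate bias
        self.params["b"] = b
        self._f, self._df = _activation(activation)

    def forward(self, x, train=False):
        b, T, _ = x.shape
        u = self.units
        h = np.zeros((b, u))
        c = np.zeros((b, u))
        self._x = x
        # input projection for every timestep in one matmul
        xp = x @ self.params["Wx"] + self.params["b"]
        self._cache = []
        for t in range(T):
            z = xp[:, t] + h @ self.params["Wh"]
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u : 2 * u])
            g_pre = z[:, 2 * u : 3 * u]
            g = self._f(g_pre)
            o = sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            s = self._f(c_new)
            h_new = o * s
            self._cache.append((h, c, i, f, g_pre, g, o, c_new, s))
            h, c = h_new, c_new
        self._h_last = h
        return h

    def backward(self, dh):
        x = self._x
        b, T, in_dim = x.shape
        u = self.units
        dz_all = np.empty((b, T, 4 * u))
        h_prev_all = np.empty((b, T, u))
        dc = np.zeros((b, u))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g_pre, g, o, c_new, s = self._cache[t]
            h_prev_all[:, t] = h_prev
            do = dh * s
            dc_total = dc + dh * o * self._df(c_new, s)
            dz = dz_all[:, t]
            dz[:, :u] = dc_total * g * i * (1 - i)
            dz[:, u : 2 * u] = dc_total * c_prev * f * (1 - f)
            dz[:, 2 * u : 3 * u] = dc_total * i * self._df(g_pre, g)
            dz[:, 3 * u :] = do * o * (1 - o)
            dh = dz @ self.params["Wh"].T
            dc = dc_total * f
        # parameter/input gradients batched over all timesteps (BLAS paths)
        dz_flat = dz_all.reshape(b * T, 4 * u)
        self.grads["Wx"] = x.reshape(b * T, in_dim).T @ dz_flat
        self.grads["Wh"] = h_prev_all.reshape(b * T, u).T @ dz_flat
        self.grads["b"] = dz_flat.sum(axis=0)
        return dz_all @ self.params["Wx"].T


class GaussianNoise(Layer):
    """Additive white noise, active only during training passes."""

    def __init__(self, std: float, rng: Optional[np.random.Generator] = None) -> None:
        super().__init__()
        self.std = std
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if train and self.std > 0:
            return x + self.rng.normal(0.0, self.std, size=x.shape)
        return x

    def backward(self, dout):
        return dout


class Sequential:
    """A plain layer chain with shared forward/backward plumbing."""

    def __init__(self, layers: List[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_weights(self) -> List[Dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()}
                for layer in self.layers]

    def set_weights(self, weights: List[Dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k][...] = w[k]
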