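"""Layers for the pure-numpy neural network backend.

Each layer implements ``forward(x, train)`` and ``backward(grad)``;
trainable arrays live in ``params`` with matching ``grads``.  Data
layout is channels-last: images are (N, H, W, C), sequences are
(N, T, F).  Initialization follows the Glorot/orthogonal conventions of
mainstream deep-learning frameworks so that the architectures behave as
practitioners expect.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv2D",
    "MaxPool2D",
    "BatchNorm",
    "Dropout",
    "Flatten",
    "FlattenToSequence",
    "LSTM",
    "Softmax",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape == (rows, cols) else q.T[:rows, :cols]


class Layer:
    """Base layer: parameter-free identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Dense(Layer):
    """Fully connected layer, optionally with ReLU."""

    def __init__(self, n_in: int, n_out: int, activation: str = "linear", *, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.params = {
            "W": _glorot(rng, n_in, n_out, (n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._z = z
            return np.maximum(z, 0.0)
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        self.grads["W"][...] = self._x.T @ grad
        self.grads["b"][...] = grad.sum(axis=0)
        return grad @ self.params["W"].T


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,H,W,C) -> (N, H', W', kh*kw*C) patches for stride-1 valid conv."""
    n, h, w, c = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, kh, kw, c), strides=(s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return patches.reshape(n, oh, ow, kh * kw * c)


class Conv2D(Layer):
    """2D convolution, 'valid' padding, stride 1, optional ReLU."""

    def __init__(self, c_in: int, filters: int, kernel: int = 3, activation: str = "relu", *, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.activation = activation
        fan_in = kernel * kernel * c_in
        self.params = {
            "W": _glorot(rng, fan_in, filters, (kernel, kernel, c_in, filters)),
            "b": np.zeros(filters),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        self._xshape = x.shape
        k = self.kernel
        self._cols = _im2col(np.ascontiguousarray(x), k, k)
        w = self.params["W"].reshape(-1, self.params["W"].shape[-1])
        z = self._cols @ w + self.params["b"]
        if self.activation == "relu":
            self._z = z
            return np.maximum(z, 0.0)
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        k = self.kernel
        n, h, w, c = self._xshape
        wmat = self.params["W"].reshape(-1, self.params["W"].shape[-1])
        cols2d = self._cols.reshape(-1, wmat.shape[0])
        grad2d = grad.reshape(-1, wmat.shape[1])
        self.grads["W"][...] = (cols2d.T @ grad2d).reshape(self.params["W"].shape)
        self.grads["b"][...] = grad2d.sum(axis=0)
        dcols = (grad2d @ wmat.T).reshape(n, h - k + 1, w - k + 1, k, k, c)
        dx = np.zeros((n, h, w, c))
        for i in range(k):
            for j in range(k):
                dx[:, i : i + h - k + 1, j : j + w - k + 1, :] += dcols[:, :, :, i, j, :]
        return dx


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols dropped."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        self._xshape = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        flat = xc.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad):
        n, h, w, c = self._xshape
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((n, h2, w2, c, 4))
        np.put_along_axis(dflat, self._argmax[..., None], grad[..., None], axis=-1)
        dx = np.zeros((n, h, w, c))
        dx[:, : 2 * h2, : 2 * w2, :] = (
            dflat.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * h2, 2 * w2, c)
        )
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channels).

    Two trainable arrays (gamma, beta) per channel; running statistics
    are used at inference time.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = np.prod([x.shape[a] for a in axes]) if train else None
        self._xhat = (x - mean) / np.sqrt(var + self.eps)
        self._std = np.sqrt(var + self.eps)
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        axes = self._axes
        self.grads["gamma"][...] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"][...] = grad.sum(axis=axes)
        g = self.params["gamma"]
        if not self._train:
            return grad * g / self._std
        m = self._m
        dxhat = grad * g
        return (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, *, rng=None):
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class FlattenToSequence(Layer):
    """(N, H, W, C) -> (N, H, W*C): rows become timesteps.

    This is the bridge between the convolutional stack and the
    recurrent layers of the hybrid model: each image row (one slice of
    the time-frequency map) is treated as one timestep.
    """

    def forward(self, x, train=False):
        self._shape = x.shape
        n, h, w, c = x.shape
        return x.reshape(n, h, w * c)

    def backward(self, grad):
        return grad.reshape(self._shape)


class LSTM(Layer):
    """Single LSTM layer with optional sequence output.

    Gate order is (i, f, g, o); weights W (input), U (recurrent), b.
    Parameter count is 4 * (units * (n_in + units) + units).
    """

    def __init__(self, n_in: int, units: int, return_sequences: bool = False, *, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.units = units
        self.return_sequences = return_sequences
        self.params = {
            "W": _glorot(rng, n_in, 4 * units, (n_in, 4 * units)),
            "U": np.concatenate([_orthogonal(rng, units, units) for _ in range(4)], axis=1),
            "b": np.zeros(4 * units),
        }
        # Forget-gate bias 1: standard trick for gradient flow.
        self.params["b"][units : 2 * units] = 1.0
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    @staticmethod
    def _sigmoid(z):
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def forward(self, x, train=False):
        n, t, _ = x.shape
        u = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._x = x
        self._cache = []
        hs = np.empty((n, t, u))
        for step in range(t):
            z = x[:, step, :] @ W + h @ U + b
            i = self._sigmoid(z[:, :u])
            f = self._sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = self._sigmoid(z[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
            hs[:, step, :] = h
        self._hs = hs
        return hs if self.return_sequences else hs[:, -1, :]

    def backward(self, grad):
        x = self._x
        n, t, _ = x.shape
        u = self.units
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, u))
        dc_next = np.zeros((n, u))
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[step]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += grad[:, step, :]
            elif step == t - 1:
                dh += grad
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dW += x[:, step, :].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step, :] = dz @ W.T
            dh_next = dz @ U.T
        self.grads["W"][...] = dW
        self.grads["U"][...] = dU
        self.grads["b"][...] = db
        return dx


class Softmax(Layer):
    """Softmax over the last axis.

    During training the network combines this with the cross-entropy
    loss, feeding the (p - y) gradient directly into the layer below;
    ``backward`` therefore passes gradients through unchanged.
    """

    def forward(self, x, train=False):
        shifted = x - x.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=-1, keepdims=True)

    def backward(self, grad):
        return grad
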