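"""Minimal neural-network engine (numpy, CPU).

Implements exactly the pieces the patch classifiers need: 2-D convolution
(im2col), ReLU, max/average pooling, global average pooling, fully connected
layers, inverted dropout, softmax cross-entropy and SGD with momentum.
Forward passes are deterministic in eval mode; all stochastic elements
(initialization, dropout masks) draw from an explicit ``numpy.random.Generator``.

Images flow through the network as float32 NCHW batches.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Dropout",
    "Sequential",
    "SGD",
    "softmax",
    "softmax_cross_entropy",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of integer ``labels`` under softmax(logits).

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the mean
    loss with respect to the logits.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), d / n


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    def __init__(self, cin, cout, k, rng, stride=1, pad=0):
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.params["W"] = _he_init(rng, (cout, cin * k * k), cin * k * k)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def _im2col(self, x):
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        n, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
        return np.ascontiguousarray(cols), ho, wo

    def forward(self, x, train=False, rng=None):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        self._xshape = x.shape
        cols, ho, wo = self._im2col(x)
        self._cols = cols
        out = np.matmul(self.params["W"], cols) + self.params["b"][:, None]
        self._hw = (ho, wo)
        return out.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, dout):
        n = dout.shape[0]
        ho, wo = self._hw
        dflat = dout.reshape(n, self.cout, ho * wo)
        self.grads["W"] = np.einsum("nol,nkl->ok", dflat, self._cols)
        self.grads["b"] = dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.params["W"].T, dflat)
        dx = self._col2im(dcols)
        if self.pad:
            p = self.pad
            dx = dx[:, :, p:-p, p:-p]
        return dx

    def _col2im(self, dcols):
        n, c = self._xshape[0], self.cin
        h, w = self._xshape[2], self._xshape[3]
        k, s = self.k, self.stride
        ho, wo = self._hw
        dx = np.zeros((n, c, h, w), dtype=dcols.dtype)
        dcols = dcols.reshape(n, c, k, k, ho, wo)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class _Pool(Layer):
    def __init__(self, k):
        super().__init__()
        self.k = k

    def _blocks(self, x):
        n, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"pooling window {k} must divide spatial dims {(h, w)}")
        return x.reshape(n, c, h // k, k, w // k, k)


class MaxPool2d(_Pool):
    def forward(self, x, train=False, rng=None):
        xr = self._blocks(x)
        out = xr.max(axis=(3, 5))
        self._xr, self._out = xr, out
        return out

    def backward(self, dout):
        mask = self._xr == self._out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dxr = mask * (dout[:, :, :, None, :, None] / counts)
        n, c, hb, k, wb, _ = dxr.shape
        return dxr.reshape(n, c, hb * k, wb * k)


class AvgPool2d(_Pool):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return self._blocks(x).mean(axis=(3, 5))

    def backward(self, dout):
        k = self.k
        d = np.repeat(np.repeat(dout, k, axis=2), k, axis=3)
        return d / (k * k)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, din, dout, rng):
        super().__init__()
        self.params["W"] = _he_init(rng, (din, dout), din)
        self.params["b"] = np.zeros(dout, dtype=np.float32)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def get_state(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers]

    def set_state(self, state) -> None:
        for layer, params in zip(self.layers, state, strict=True):
            for k in layer.params:
                layer.params[k][...] = params[k]


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, net: Sequential, lr: float, momentum: float = 0.9):
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self._vel = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in net.layers
        ]

    def step(self) -> None:
        for layer, vel in zip(self.net.layers, self._vel):
            for k, p in layer.params.items():
                v = vel[k]
                v *= self.momentum
                v -= self.lr * layer.grads[k]
                p += v
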