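"""Minimal CPU neural-network layers with hand-written backpropagation.

Single-image (no batch axis) tensors of shape (H, W, C).  Only the pieces
an encoder-decoder segmentation network needs: 3x3/1x1 convolutions via
im2col, ReLU, 2x2 max pooling, nearest-neighbour upsampling, dropout,
channel concatenation, sigmoid + binary cross-entropy, and Adam.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def he_init(rng: np.random.Generator, kh, kw, cin, cout) -> np.ndarray:
    std = np.sqrt(2.0 / (kh * kw * cin))
    return rng.normal(0.0, std, size=(kh * kw * cin, cout))


class Conv2D:
    """Same-padding convolution, stride 1."""

    def __init__(self, rng, cin: int, cout: int, k: int = 3):
        self.k = k
        self.cin = cin
        self.cout = cout
        self.w = he_init(rng, k, k, cin, cout)
        self.b = np.zeros(cout)
        self._cache = None

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        if p:
            x = np.pad(x, ((p, p), (p, p), (0, 0)))
        win = sliding_window_view(x, (k, k), axis=(0, 1))  # (H, W, C, k, k)
        h, w = win.shape[:2]
        # reorder to (H*W, k*k*C) matching weight layout (k, k, C)
        return win.transpose(0, 1, 3, 4, 2).reshape(h * w, k * k * self.cin)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w, _ = x.shape
        cols = self._im2col(x)
        self._cache = (cols, (h, w))
        return (cols @ self.w + self.b).reshape(h, w, self.cout)

    def backward(self, dout: np.ndarray):
        cols, (h, w) = self._cache
        dflat = dout.reshape(-1, self.cout)
        self.dw = cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = dflat @ self.w.T            # (H*W, k*k*Cin)
        k = self.k
        p = k // 2
        dcols = dcols.reshape(h, w, k, k, self.cin)
        dxp = np.zeros((h + 2 * p, w + 2 * p, self.cin))
        for i in range(k):
            for j in range(k):
                dxp[i:i + h, j:j + w] += dcols[:, :, i, j]
        return dxp[p:p + h, p:p + w] if p else dxp

    def grads(self):
        return [("w", self.dw), ("b", self.db)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2:
    def forward(self, x):
        h, w, c = x.shape
        xr = x.reshape(h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(1, 3))
        self._argmask = xr == out[:, None, :, None, :]
        self._shape = x.shape
        return out

    def backward(self, dout):
        h, w, c = self._shape
        d = self._argmask * dout[:, None, :, None, :]
        return d.reshape(h, w, c)


class Upsample2x2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=0), 2, axis=1)

    def backward(self, dout):
        h2, w2, c = dout.shape
        return dout.reshape(h2 // 2, 2, w2 // 2, 2, c).sum(axis=(1, 3))


class Dropout:
    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def forward(self, x, rng: np.random.Generator | None):
        if rng is None or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss_and_grad(logits: np.ndarray, target: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    pred = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(target * np.log(pred + eps)
                    + (1 - target) * np.log(1 - pred + eps))
    dlogits = (pred - target) / target.size
    return float(loss), dlogits


class Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict = {}

    def step(self, layers):
        self.t += 1
        for li, layer in enumerate(layers):
            if not hasattr(layer, "grads"):
                continue
            params = dict(layer.params())
            for name, g in layer.grads():
                key = (li, name)
                m, v = self.state.get(key, (np.zeros_like(g),
                                            np.zeros_like(g)))
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g * g
                self.state[key] = (m, v)
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
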