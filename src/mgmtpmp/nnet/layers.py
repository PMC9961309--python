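"""Minimal NHWC neural-network layers with explicit backprop.

Everything is float32 and CPU-bound; convolutions are im2col + BLAS matmul,
which is plenty for a 64x64-input network of this size.  Each layer exposes
``params``/``grads`` dicts (shared key names) so the optimizer can walk them
generically.  No layer owns randomness: dropout takes a Generator per call.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, *, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def out_shape(self, in_shape):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride 1, padding 'same' or 'valid'."""

    def __init__(self, in_ch, out_ch, kernel=3, padding="same", *, rng):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        self.in_ch, self.out_ch, self.k, self.padding = in_ch, out_ch, kernel, padding
        fan_in = kernel * kernel * in_ch
        fan_out = kernel * kernel * out_ch
        self.params = {
            "W": glorot_uniform(rng, (fan_in, out_ch), fan_in, fan_out),
            "b": np.zeros(out_ch, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    @property
    def pad(self):
        return (self.k - 1) // 2 if self.padding == "same" else 0

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        s = self.k - 1 - 2 * self.pad
        return (h - s, w - s, self.out_ch)

    def _im2col(self, xp, oh, ow):
        # (N, OH, OW, C, k, k) view -> contiguous (N*OH*OW, k*k*C)
        v = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        cols = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
        return cols.reshape(-1, self.k * self.k * self.in_ch)

    def forward(self, x, *, train=False, rng=None):
        n, h, w, _ = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        oh, ow, _ = self.out_shape(x.shape[1:])
        cols = self._im2col(xp, oh, ow)
        y = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, x.shape, (n, oh, ow))
        return y.reshape(n, oh, ow, self.out_ch)

    def backward(self, dy):
        cols, x_shape, (n, oh, ow) = self._cache
        dy2 = dy.reshape(-1, self.out_ch)
        self.grads["W"][...] = cols.T @ dy2
        self.grads["b"][...] = dy2.sum(axis=0)
        dcols = (dy2 @ self.params["W"].T).reshape(n, oh, ow, self.k, self.k, self.in_ch)
        p = self.pad
        hp, wp = x_shape[1] + 2 * p, x_shape[2] + 2 * p
        dxp = np.zeros((n, hp, wp, self.in_ch), dtype=F32)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, ki : ki + oh, kj : kj + ow, :] += dcols[:, :, :, ki, kj, :]
        return dxp[:, p : hp - p, p : wp - p, :] if p else dxp


class ReLU(Layer):
    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (even spatial dims required)."""

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling needs even spatial dims, got {h}x{w}")
        return (h // 2, w // 2, c)

    def forward(self, x, *, train=False, rng=None):
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = r.max(axis=(2, 4))
        self._cache = (r, out)
        return out

    def backward(self, dy):
        r, out = self._cache
        mask = r == out[:, :, None, :, None, :]
        ties = mask.sum(axis=(2, 4), keepdims=True)
        dr = mask * (dy[:, :, None, :, None, :] / ties)
        n, h2, _, w2, _, c = r.shape
        return dr.reshape(n, h2 * 2, w2 * 2, c).astype(F32)


class BatchNorm(Layer):
    """Spatial batch normalization over (N, H, W) per channel.

    Training uses batch statistics and maintains running statistics with a
    fixed momentum (0.9, an internal default recorded here); inference and
    feature extraction use the running statistics.
    """

    RUNNING_MOMENTUM = 0.9
    EPS = 1e-5

    def __init__(self, channels):
        super().__init__()
        self.params = {
            "gamma": np.ones(channels, dtype=F32),
            "beta": np.zeros(channels, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, *, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.RUNNING_MOMENTUM
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.EPS)
        xhat = (x - mean) / std
        self._cache = (xhat, std, x.shape)
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(F32)

    def backward(self, dy):
        xhat, std, shape = self._cache
        nn = shape[0] * shape[1] * shape[2]
        dgamma = (dy * xhat).sum(axis=(0, 1, 2))
        dbeta = dy.sum(axis=(0, 1, 2))
        self.grads["gamma"][...] = dgamma
        self.grads["beta"][...] = dbeta
        g = self.params["gamma"] / std
        return (g * (dy - dbeta / nn - xhat * dgamma / nn)).astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs a Generator")
        self._mask = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return (x * self._mask).astype(F32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(F32)


class Flatten(Layer):
    def out_shape(self, in_shape):
        h, w, c = in_shape
        return h * w * c

    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer, no built-in activation."""

    def __init__(self, in_dim, out_dim, *, rng):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params = {
            "W": glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim),
            "b": np.zeros(out_dim, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def out_shape(self, in_shape):
        if in_shape != self.in_dim:
            raise ValueError(f"expected input dim {self.in_dim}, got {in_shape}")
        return self.out_dim

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"][...] = self._x.T @ dy
        self.grads["b"][...] = dy.sum(axis=0)
        return dy @ self.params["W"].T
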