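"""Minimal CNN building blocks with explicit backpropagation.

Plain numpy layers (float32) sufficient for a VGG-style trunk with
fully connected heads: 3x3 same-padding convolution, 2x2 max/average
pooling, ReLU, dense, inverted dropout, and softmax cross-entropy.
Convolution runs through an im2col matrix multiply; its input gradient is
computed as a convolution of the output gradient against the spatially
flipped, channel-transposed kernel, so no scatter-adds are needed.

Each parameterised layer owns its initialisation Generator and each dropout
layer its mask Generator, which keeps training trajectories reproducible and
makes a two-head network bit-identical to a one-head network on the shared
parts when the second head's loss weight is zero.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for stride-1 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)


class Layer:
    trainable = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_and_grads(self):
        return []


class Conv2d(Layer):
    """3x3 stride-1 same-padding convolution with He-initialised weights."""

    trainable = True

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        #: set False on the network's first layer: its input gradient is
        #: never consumed and computing it costs a full extra convolution
        self.input_grad = True
        fan_in = c_in * k * k
        self.weight = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.bias = np.zeros(c_out, dtype=DTYPE)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        cols = _im2col(x.astype(DTYPE, copy=False), self.k, self.pad)
        y = cols @ self.weight.T + self.bias
        if train:
            self._cols, self._shape = cols, (n, c, h, w)
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, _, h, w = self._shape
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out).astype(DTYPE, copy=False)
        self.dweight = dy_mat.T @ self._cols
        self.dbias = dy_mat.sum(axis=0)
        self._cols = None
        if not self.input_grad:
            return None
        # dx = conv(dy, W flipped spatially, channels transposed)
        w_sp = self.weight.reshape(self.c_out, self.c_in, self.k, self.k)
        w_rot = w_sp[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.c_in, self.c_out * self.k * self.k)
        dy_img = dy.astype(DTYPE, copy=False)
        cols = _im2col(dy_img, self.k, self.k - 1 - self.pad)  # == self.pad for odd k, same padding
        dx = cols @ w_rot.T
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)

    def params_and_grads(self):
        return [("weight", self), ("bias", self)]

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size


class MaxPool2(Layer):
    """2x2 non-overlapping max pooling (first-occurrence tie break)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size ({h}, {w}) not divisible by 2")
        windows = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = windows.argmax(axis=-1)
        if train:
            self._idx, self._shape = idx, (n, c, h, w)
        return np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        grad = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(grad, self._idx[..., None], dy[..., None].astype(DTYPE, copy=False), axis=-1)
        return grad.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class AvgPool2(Layer):
    """2x2 average pooling, used to downsample the input image cheaply."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size ({h}, {w}) not divisible by 2")
        self._shape = (n, c, h, w)
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3).astype(DTYPE, copy=False) / 4.0


class ReLU(Layer):
    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(DTYPE)
        self.bias = np.zeros(n_out, dtype=DTYPE)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.weight + self.bias

    def backward(self, dy):
        dy = dy.astype(DTYPE, copy=False)
        self.dweight = self._x.T @ dy
        self.dbias = dy.sum(axis=0)
        self._x = None
        return dy @ self.weight.T

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size


class Dropout(Layer):
    """Inverted dropout: active only during training passes."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(DTYPE) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    labels = np.asarray(labels)
    n = logits.shape[0]
    p = softmax(np.asarray(logits, dtype=float))
    eps = np.finfo(float).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(DTYPE)


def run_forward(layers, x, train=False):
    for layer in layers:
        x = layer.forward(x, train=train)
    return x


def run_backward(layers, dy):
    for layer in reversed(layers):
        dy = layer.backward(dy)
        if dy is None:  # a layer declared its input gradient unneeded
            break
    return dy


def sgd_step(layers, lr: float) -> None:
    """Plain (vanilla) gradient-descent update on every trainable layer."""
    for layer in layers:
        if layer.trainable:
            layer.weight -= lr * layer.dweight
            layer.bias -= lr * layer.dbias


def count_params(layers) -> int:
    return sum(layer.n_params for layer in layers if layer.trainable)
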