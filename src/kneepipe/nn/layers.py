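"""Layers with explicit forward/backward passes.

Convolution uses an im2col formulation built on
``numpy.lib.stride_tricks.sliding_window_view``; the backward pass scatters
column gradients back with a small loop over kernel offsets. Grouped
convolution (the ResNeXt aggregated-transform form) partitions channels into
``groups`` independent blocks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """2-D convolution (cross-correlation) over NCHW batches.

    Parameters
    ----------
    in_channels, out_channels : int
    kernel_size : int (square kernels only)
    stride, padding : int
    groups : int
        Channel groups; ``in_channels`` and ``out_channels`` must both be
        divisible by ``groups``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(
            _he_init(rng, (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in),
            name="conv.weight")
        self.bias = Parameter(np.zeros(out_channels), name="conv.bias")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, s, p, g = self.k, self.stride, self.padding, self.groups
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"kernel {k} larger than padded input {xp.shape[2:]}")
        # (n, c, ho, wo, k, k)
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (n, ho, wo, g, c_g*k*k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, ho, wo, g, (self.cin // g) * k * k)
        wg = self.weight.data.reshape(g, self.cout // g, -1)
        out = np.einsum("nhwgk,gok->nhwgo", cols, wg, optimize=True)
        out = out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        out += self.bias.data[None, :, None, None]
        self._cache = (cols, xp.shape, x.shape, ho, wo)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xp_shape, x_shape, ho, wo = self._cache
        n = x_shape[0]
        k, s, p, g = self.k, self.stride, self.padding, self.groups
        gr = grad.transpose(0, 2, 3, 1).reshape(n, ho, wo, g, self.cout // g)
        self.weight.grad += np.einsum("nhwgo,nhwgk->gok", gr, cols,
                                      optimize=True).reshape(self.weight.shape)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        wg = self.weight.data.reshape(g, self.cout // g, -1)
        dcols = np.einsum("nhwgo,gok->nhwgk", gr, wg, optimize=True)
        dcols = dcols.reshape(n, ho, wo, self.cin, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class MaxPool2d(Module):
    """2x2 (by default) max pooling with stride equal to the window size.

    Odd trailing rows/columns are dropped (floor semantics).
    """

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.size
        ho, wo = h // k, w // k
        xv = x[:, :, :ho * k, :wo * k].reshape(n, c, ho, k, wo, k)
        xv = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
        idx = xv.argmax(axis=-1)
        out = np.take_along_axis(xv, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, ho, wo)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, x_shape, ho, wo = self._cache
        n, c, h, w = x_shape
        k = self.size
        dview = np.zeros((n, c, ho, wo, k * k))
        np.put_along_axis(dview, idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros(x_shape)
        dx[:, :, :ho * k, :wo * k] = (
            dview.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho * k, wo * k))
        return dx


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (out_features, in_features), in_features),
                                name="linear.weight")
        self.bias = Parameter(np.zeros(out_features), name="linear.bias")
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.weight.shape[1]:
            raise ValueError(f"expected {self.weight.shape[1]} features, got {x.shape[-1]}")
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class Sigmoid(Module):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Randomness comes from the
    generator handed in at construction so whole-model runs are seedable."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class GlobalAvgPool2d(Module):
    """NCHW -> NC channel means (the squeeze step of an SE unit)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)
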