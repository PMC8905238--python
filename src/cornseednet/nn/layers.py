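"""Minimal CPU neural-network layers with hand-written backprop.

Float32 throughout; convolution is im2col + one BLAS matmul per layer, the
gradient w.r.t. the input is accumulated by kh*kw strided slice-adds.  Layers
cache what backward needs during a training forward pass; ``train=False``
skips caches and uses running statistics in batch norm.

Correctness of every backward pass is verified against central-difference
numerical gradients in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameter/gradient dicts plus forward/backward."""

    def __init__(self):
        self.params = {}
        self.grads = {}
        self.buffers = {}

    def children(self):
        return []

    def iter_layers(self):
        yield self
        for c in self.children():
            yield from c.iter_layers()

    def parameters(self):
        """Yield (layer, name) pairs over the whole subtree, in fixed order."""
        for layer in self.iter_layers():
            for name in sorted(layer.params):
                yield layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def forward(self, x, train=True):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, train=True):
        return self.forward(x, train=train)


class Conv2d(Layer):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.pad = stride, pad
        fan_in = in_ch * kernel * kernel
        self.params["w"] = (rng.standard_normal((out_ch, in_ch, kernel, kernel))
                            * np.sqrt(2.0 / fan_in)).astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def _im2col(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        sw = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = sw.shape[:4]
        cols = np.ascontiguousarray(sw.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k)
        return cols, (ho, wo)

    def forward(self, x, train=True):
        n = x.shape[0]
        self._in_shape = x.shape
        cols, (ho, wo) = self._im2col(x)
        wmat = self.params["w"].reshape(self.out_ch, -1)
        out = cols @ wmat.T
        if "b" in self.params:
            out += self.params["b"]
        self._cols = cols if train else None
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, _, ho, wo = dout.shape
        k, s, p = self.kernel, self.stride, self.pad
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.grads["w"] = (dmat.T @ self._cols).reshape(self.params["w"].shape)
        if "b" in self.params:
            self.grads["b"] = dmat.sum(axis=0)
        dcols = (dmat @ self.params["w"].reshape(self.out_ch, -1)).reshape(
            n, ho, wo, self.in_ch, k, k)
        _, _, h, w = self._in_shape
        dxp = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, n_ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(n_ch, dtype=np.float32)
        self.params["beta"] = np.zeros(n_ch, dtype=np.float32)
        self.buffers["running_mean"] = np.zeros(n_ch, dtype=np.float32)
        self.buffers["running_var"] = np.ones(n_ch, dtype=np.float32)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] = ((1 - m) * self.buffers["running_mean"]
                                            + m * mean).astype(np.float32)
            self.buffers["running_var"] = ((1 - m) * self.buffers["running_var"]
                                           + m * var).astype(np.float32)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._xhat, self._invstd = xhat, invstd
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None]).astype(x.dtype)

    def backward(self, dout):
        xhat, invstd = self._xhat, self._invstd
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"] * invstd
        dsum = dout.sum(axis=(0, 2, 3))
        dxsum = (dout * xhat).sum(axis=(0, 2, 3))
        dx = (g[None, :, None, None] / n) * (
            n * dout - dsum[None, :, None, None] - xhat * dxsum[None, :, None, None])
        self._xhat = self._invstd = None
        return dx.astype(dout.dtype)


class ReLU(Layer):
    def forward(self, x, train=True):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    def __init__(self, kernel, stride=None, pad=0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride or kernel
        self.pad = pad

    def forward(self, x, train=True):
        k, s, p = self.kernel, self.stride, self.pad
        self._in_shape = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        self._pad_shape = x.shape
        sw = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = sw.shape[:4]
        flat = sw.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
        return np.ascontiguousarray(out)

    def backward(self, dout):
        k, s, p = self.kernel, self.stride, self.pad
        n, c, ho, wo = dout.shape
        hp, wp = self._pad_shape[2], self._pad_shape[3]
        dxp = np.zeros((n, c, hp, wp), dtype=dout.dtype)
        ai, aj = np.divmod(self._idx, k)
        rows = (np.arange(ho)[None, None, :, None] * s + ai)
        cols = (np.arange(wo)[None, None, None, :] * s + aj)
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, rows, cols), dout)
        self._idx = None
        h, w = self._in_shape[2], self._in_shape[3]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), (n, c, h, w)).astype(dout.dtype)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, in_dim, out_dim, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params["w"] = (rng.standard_normal((out_dim, in_dim))
                            * np.sqrt(2.0 / in_dim)).astype(np.float32)
        self.params["b"] = np.zeros(out_dim, dtype=np.float32)

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["w"]
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def children(self):
        return self.layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Bottleneck(Layer):
    """ResNet bottleneck: 1x1 reduce -> 3x3 -> 1x1 expand, plus identity (or
    1x1 projection) shortcut added before the final ReLU."""

    def __init__(self, in_ch, mid_ch, stride=1, rng=None, expansion=4):
        super().__init__()
        out_ch = mid_ch * expansion
        self.main = Sequential([
            Conv2d(in_ch, mid_ch, 1, bias=False, rng=rng),
            BatchNorm2d(mid_ch),
            ReLU(),
            Conv2d(mid_ch, mid_ch, 3, stride=stride, pad=1, bias=False, rng=rng),
            BatchNorm2d(mid_ch),
            ReLU(),
            Conv2d(mid_ch, out_ch, 1, bias=False, rng=rng),
            BatchNorm2d(out_ch),
        ])
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential([
                Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(out_ch),
            ])
        else:
            self.shortcut = None
        self.out_ch = out_ch

    def children(self):
        return [self.main] + ([self.shortcut] if self.shortcut else [])

    def forward(self, x, train=True):
        h = self.main.forward(x, train=train)
        s = self.shortcut.forward(x, train=train) if self.shortcut else x
        out = h + s
        if train:
            self._mask = out > 0
        return np.maximum(out, 0.0)

    def backward(self, dout):
        dout = dout * self._mask
        self._mask = None
        dx = self.main.backward(dout)
        if self.shortcut:
            dx = dx + self.shortcut.backward(dout)
        else:
            dx = dx + dout
        return dx
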