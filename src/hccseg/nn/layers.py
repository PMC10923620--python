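"""Minimal CNN layer zoo with hand-derived backpropagation.

All layers operate on ``(N, C, H, W)`` arrays and cache whatever the backward
pass needs during ``forward``.  The engine is deliberately small: stride-1
"same" convolutions, 2x2/stride-2 pooling and transposed convolutions, batch
normalization, ReLU/sigmoid, and a fixed-factor bilinear upsampler — exactly
the pieces the encoder-decoder and fusion architectures require.  Gradients
are exact (verified against finite differences in the test suite), not
approximate.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2x2",
    "BilinearUpsample",
    "ConvBlock",
]


class Param:
    """A named trainable array with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: ``forward`` caches, ``backward`` consumes the cache."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Layer):
    """Stride-1 convolution with odd kernel size and "same" zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv", dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes only")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.pad = kernel // 2
        fan_in = c_in * kernel * kernel
        self.w = Param(f"{name}.w", _he_init(rng, (c_out, c_in * kernel * kernel), fan_in, dtype))
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=dtype))
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        # (N, C, H, W, k, k) view -> (N*H*W, C*k*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        out = cols @ self.w.value.T + self.b.value
        self._cols = cols if train else None
        self._xshape = x.shape
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.k, self.pad
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.w.grad += g.T @ self._cols
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.w.value).reshape(n, h, w, c, k, k)
        if k == 1:
            return dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # N, C, k, k, H, W
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
        return dxp[:, :, p:p + h, p:p + w]

    def params(self) -> list[Param]:
        return [self.w, self.b]


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (doubles H and W)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "deconv", dtype=np.float32):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(f"{name}.w", _he_init(rng, (c_in, c_out, 2, 2), c_in * 4, dtype))
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=dtype))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        t = np.tensordot(x, self.w.value, axes=([1], [0]))  # N,H,W,cout,2,2
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.c_out, 2 * h, 2 * w)
        y += self.b.value[None, :, None, None]
        self._x = x if train else None
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        gr = grad.reshape(n, self.c_out, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        self.w.grad += np.tensordot(x, gr, axes=([0, 2, 3], [0, 1, 2]))
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dx = np.tensordot(gr, self.w.value, axes=([3, 4, 5], [1, 2, 3]))
        return dx.transpose(0, 3, 1, 2)

    def params(self) -> list[Param]:
        return [self.w, self.b]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, c: int, name: str = "bn", momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self._cache = None
        self._calib: list | None = None

    def begin_calibration(self) -> None:
        """Start exact recomputation of the running statistics."""
        c = len(self.running_mean)
        self._calib = [np.zeros(c), np.zeros(c), 0]

    def end_calibration(self) -> None:
        s1, s2, n = self._calib
        if n > 0:
            mean = s1 / n
            self.running_mean = mean
            self.running_var = np.maximum(s2 / n - mean * mean, 0.0)
        self._calib = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self._calib is not None:
            # calibration pass: normalize with batch stats, accumulate exact
            # moments over the whole calibration set
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            x64 = x.astype(np.float64)
            self._calib[0] += x64.sum(axis=(0, 2, 3))
            self._calib[1] += (x64 * x64).sum(axis=(0, 2, 3))
            self._calib[2] += m
        elif train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gx = grad * self.gamma.value[None, :, None, None]
        s1 = gx.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
        s2 = (gx * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
        return (inv[None, :, None, None] / m) * (m * gx - s1 - xhat * s2)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.empty_like(x)
        np.negative(np.abs(x), out=out)
        np.exp(out, out=out)
        pos = x >= 0
        out = np.where(pos, 1.0 / (1.0 + out), out / (1.0 + out))
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; requires even H and W."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = (x.reshape(n, c, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h // 2, w // 2, 4))
        self._argmax = xr.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        return (flat.reshape(n, c, h // 2, w // 2, 2, 2)
                    .transpose(0, 1, 2, 4, 3, 5)
                    .reshape(n, c, h, w))


class BilinearUpsample(Layer):
    """Fixed integer-factor bilinear upsampling (no trainable parameters)."""

    def __init__(self, factor: int):
        self.factor = factor
        self._mats: dict[int, np.ndarray] = {}

    def _matrix(self, size_in: int, dtype) -> np.ndarray:
        key = size_in
        if key not in self._mats:
            f = self.factor
            size_out = size_in * f
            a = np.zeros((size_out, size_in))
            src = (np.arange(size_out) + 0.5) / f - 0.5
            src = np.clip(src, 0, size_in - 1)
            lo = np.floor(src).astype(int)
            hi = np.minimum(lo + 1, size_in - 1)
            t = src - lo
            a[np.arange(size_out), lo] += 1 - t
            a[np.arange(size_out), hi] += t
            self._mats[key] = a
        return self._mats[key].astype(dtype)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        ah = self._matrix(x.shape[2], x.dtype)
        aw = self._matrix(x.shape[3], x.dtype)
        self._ah, self._aw = ah, aw
        return np.einsum("oh,nchw,pw->ncop", ah, x, aw, optimize=True)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.einsum("oh,ncop,pw->nchw", self._ah, grad, self._aw, optimize=True)


class ConvBlock(Layer):
    """3x3 conv -> batch norm -> ReLU, the repeated unit of both paths."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "block", kernel: int = 3, dtype=np.float32):
        self.conv = Conv2d(c_in, c_out, kernel, rng, name=f"{name}.conv", dtype=dtype)
        self.bn = BatchNorm2d(c_out, name=f"{name}.bn", dtype=dtype)
        self.relu = ReLU()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(grad)))

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()
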