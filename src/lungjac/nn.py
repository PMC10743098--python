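"""A compact NumPy engine for small 3D convolutional regression networks.

Implements exactly the layer set the volume-regression architecture needs —
3D convolution (stride 1/2, zero "same" padding), non-overlapping transposed
convolution, instance normalization, and ReLU — each with a hand-derived
backward pass, plus He-normal initialization and Adam/AMSGrad.  Correctness
of every backward pass is pinned by numerical gradient-check tests.

Tensors are single samples laid out channel-first, ``(C, nx, ny, nz)``;
batching is realized by gradient accumulation over samples.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv3d",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "ReLU",
    "AMSGrad",
    "he_normal",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self):
        self.grad[...] = 0.0


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    """He-normal initialization: N(0, sqrt(2 / fan_in))."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution with zero 'same' padding and stride 1 or 2.

    For odd kernels and even extents, stride 2 halves each spatial axis.
    Realized as a sum of 27 (k^3) channel-matrix products over shifted
    views, which keeps every inner product inside a contiguous GEMM.
    """

    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, kernel, stride
        self.pad = (kernel - 1) // 2
        fan_in = cin * kernel**3
        w = np.zeros((cout, cin, kernel, kernel, kernel), dtype=dtype) if zero_init \
            else he_normal(rng, (cout, cin, kernel, kernel, kernel), fan_in, dtype)
        self.W = Parameter(w, "conv.W")
        self.b = Parameter(np.zeros(cout, dtype=dtype), "conv.b")
        self._xp = None
        self._xshape = None

    def parameters(self):
        return [self.W, self.b]

    def _out_shape(self, xshape):
        s = self.stride
        return tuple(-(-n // s) for n in xshape[1:])

    def forward(self, x: np.ndarray) -> np.ndarray:
        p, k, s = self.pad, self.k, self.stride
        x = np.ascontiguousarray(x)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
        self._xp = xp
        self._xshape = x.shape
        Do, Ho, Wo = self._out_shape(x.shape)
        N = Do * Ho * Wo
        y = np.zeros((self.cout, N), dtype=x.dtype)
        for di in range(k):
            for dj in range(k):
                for dk in range(k):
                    xs = np.ascontiguousarray(
                        xp[:, di:di + s * Do:s, dj:dj + s * Ho:s, dk:dk + s * Wo:s]
                    ).reshape(self.cin, N)
                    y += self.W.value[:, :, di, dj, dk] @ xs
        y = y.reshape((self.cout, Do, Ho, Wo))
        return y + self.b.value[:, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        p, k, s = self.pad, self.k, self.stride
        xp = self._xp
        C, D, H, Wd = self._xshape
        Do, Ho, Wo = gy.shape[1:]
        N = Do * Ho * Wo
        gy_flat = np.ascontiguousarray(gy).reshape(self.cout, N)
        self.b.grad += gy_flat.sum(axis=1)
        gxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                for dk in range(k):
                    sl = (slice(None), slice(di, di + s * Do, s),
                          slice(dj, dj + s * Ho, s), slice(dk, dk + s * Wo, s))
                    xs = np.ascontiguousarray(xp[sl]).reshape(self.cin, N)
                    self.W.grad[:, :, di, dj, dk] += gy_flat @ xs.T
                    gxp[sl] += (self.W.value[:, :, di, dj, dk].T @ gy_flat).reshape(
                        self.cin, Do, Ho, Wo)
        self._xp = None
        if p:
            return gxp[:, p:p + D, p:p + H, p:p + Wd]
        return gxp


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel == stride (non-overlapping upsampling)."""

    def __init__(self, cin: int, cout: int, factor: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.s = cin, cout, factor
        self.W = Parameter(he_normal(rng, (cin, cout, factor, factor, factor), cin, dtype),
                           "upconv.W")
        self.b = Parameter(np.zeros(cout, dtype=dtype), "upconv.b")
        self._x = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        s = self.s
        t = np.tensordot(self.W.value, x, axes=([0], [0]))  # (cout,s,s,s,D,H,W)
        t = t.transpose(0, 4, 1, 5, 2, 6, 3)                # (cout,D,s,H,s,W,s)
        D, H, Wd = x.shape[1:]
        y = t.reshape(self.cout, D * s, H * s, Wd * s)
        return y + self.b.value[:, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        s = self.s
        x = self._x
        D, H, Wd = x.shape[1:]
        gt = gy.reshape(self.cout, D, s, H, s, Wd, s).transpose(0, 2, 4, 6, 1, 3, 5)
        # gt: (cout, s, s, s, D, H, W)
        gW = np.tensordot(gt, x, axes=([4, 5, 6], [1, 2, 3]))  # (cout,s,s,s,cin)
        self.W.grad += gW.transpose(4, 0, 1, 2, 3)
        self.b.grad += gy.sum(axis=(1, 2, 3))
        gx = np.tensordot(self.W.value, gt, axes=([1, 2, 3, 4], [0, 1, 2, 3]))
        self._x = None
        return gx


class InstanceNorm3d(Layer):
    """Per-channel normalization over the spatial axes with affine scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype), "in.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), "in.beta")
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        self._cache = (xhat, istd)
        return self.gamma.value[:, None, None, None] * xhat + self.beta.value[:, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, istd = self._cache
        N = xhat[0].size
        g = gy * self.gamma.value[:, None, None, None]
        self.gamma.grad += (gy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += gy.sum(axis=(1, 2, 3))
        gsum = g.sum(axis=(1, 2, 3), keepdims=True)
        gxhat_dot = (g * xhat).sum(axis=(1, 2, 3), keepdims=True)
        gx = (istd / N) * (N * g - gsum - xhat * gxhat_dot)
        self._cache = None
        return gx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.where(self._mask, gy, 0.0)
        self._mask = None
        return gx


class AMSGrad:
    """Adam with the AMSGrad maximum-of-second-moments variant."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 amsgrad: bool = True):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.amsgrad = amsgrad
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.vhat = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            if self.amsgrad:
                np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
                denom = np.sqrt(self.vhat[i] / bc2) + self.eps
            else:
                denom = np.sqrt(self.v[i] / bc2) + self.eps
            p.value -= self.lr * (self.m[i] / bc1) / denom
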