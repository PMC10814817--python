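"""Layers with explicit forward/backward passes.

Internally every tensor is laid out NHWC — channels last — so that 1x1
convolutions are plain GEMMs on free reshapes and the 3x3 im2col matrix is
assembled from nine contiguous slice copies instead of a strided gather.
The public model API still speaks (N, C, H, W); the network transposes once
at entry and exit.  Each layer caches what its backward pass needs on
``forward`` and accumulates parameter gradients into ``Param.grad``;
``backward`` returns the gradient with respect to its input.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from ._kernels import HAVE_NUMBA, conv3x3_dw, conv3x3_dx, conv3x3_fwd


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, same padding, He init. NHWC tensors.

    Weights are stored as ``(k*k*C_in, C_out)`` so forward is a single GEMM
    on the im2col matrix; the im2col matrix is cached for the weight-gradient
    GEMM in backward.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels))
        self.w = Param(w)
        self.b = Param(np.zeros(out_channels))
        self._cache: Optional[Tuple] = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def _use_direct(self, h: int, w: int) -> bool:
        # direct numba kernel wins where pixels are many and channels few;
        # im2col+GEMM wins deeper in the network
        return (
            HAVE_NUMBA and self.k == 3 and h * w >= 4096 and self.cin * self.cout <= 640
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if self._use_direct(h, w):
            x = np.ascontiguousarray(x)
            y = np.empty((n, h, w, self.cout), dtype=np.float32)
            w4 = self.w.value.reshape(self.k, self.k, c, self.cout)
            conv3x3_fwd(x, w4, self.b.value, y)
            if train:
                self._cache = ("direct", x, (n, h, w, c))
            return y
        if self.k == 1:
            cols = x.reshape(-1, c)
        else:
            p = self.k // 2
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            cols = np.empty((n, h, w, self.k * self.k * c), dtype=np.float32)
            for i in range(self.k):
                for j in range(self.k):
                    kk = i * self.k + j
                    cols[..., kk * c : (kk + 1) * c] = xp[:, i : i + h, j : j + w, :]
            cols = cols.reshape(-1, self.k * self.k * c)
        y = cols @ self.w.value + self.b.value
        if train:
            self._cache = ("cols", cols, (n, h, w, c))
        return y.reshape(n, h, w, self.cout)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kind, cols, (n, h, w, c) = self._cache
        self._cache = None
        if kind == "direct":
            x = cols  # the cached contiguous input
            g = np.ascontiguousarray(grad)
            w4 = self.w.value.reshape(self.k, self.k, c, self.cout)
            dw4 = self.w.grad.reshape(self.k, self.k, c, self.cout)
            conv3x3_dw(x, g, dw4)
            self.b.grad += g.reshape(-1, self.cout).sum(axis=0)
            dx = np.zeros((n, h, w, c), dtype=np.float32)
            conv3x3_dx(g, w4, dx)
            return dx
        g2 = np.ascontiguousarray(grad).reshape(-1, self.cout)
        self.w.grad += cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        dcols = g2 @ self.w.value.T
        if self.k == 1:
            return dcols.reshape(n, h, w, c)
        p = self.k // 2
        dcols = dcols.reshape(n, h, w, self.k * self.k * c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                kk = i * self.k + j
                dxp[:, i : i + h, j : j + w, :] += dcols[..., kk * c : (kk + 1) * c]
        return dxp[:, p : p + h, p : p + w, :]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv_std
        xhat = xhat.astype(np.float32)
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        m = grad.shape[0] * grad.shape[1] * grad.shape[2]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        dxhat = grad * self.gamma.value
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (inv_std / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, np.float32(0.0))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, grad, np.float32(0.0))


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2, exact argmax routing in backward."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, h, w, c))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._cache
        self._cache = None
        g = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(g, idx[..., None], grad[..., None], axis=-1)
        g = g.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(g).reshape(n, h, w, c)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (non-overlapping upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.cin, self.cout = in_channels, out_channels
        w = rng.normal(0.0, np.sqrt(2.0 / in_channels), size=(in_channels, 4 * out_channels))
        self.w = Param(w)
        self.b = Param(np.zeros(out_channels))
        self._cache = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xm = x.reshape(-1, c)
        ym = xm @ self.w.value  # (N*H*W, 2*2*Cout)
        y = ym.reshape(n, h, w, 2, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        y = np.ascontiguousarray(y).reshape(n, 2 * h, 2 * w, self.cout) + self.b.value
        if train:
            self._cache = (xm, (n, h, w, c))
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (xm, (n, h, w, c)), self._cache = self._cache, None
        gm = grad.reshape(n, h, 2, w, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        gm = np.ascontiguousarray(gm).reshape(-1, 4 * self.cout)
        self.w.grad += xm.T @ gm
        self.b.grad += grad.sum(axis=(0, 1, 2))
        return (gm @ self.w.value.T).reshape(n, h, w, c)


class ConvBNReLU(Layer):
    """conv -> batch norm -> ReLU, the basic unit of both backbones."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, use_bn: bool = True):
        self.conv = Conv2d(cin, cout, k, rng)
        self.bn = BatchNorm2d(cout) if use_bn else None
        self.relu = ReLU()
        self.out_channels = cout

    def params(self) -> List[Param]:
        p = self.conv.params()
        if self.bn is not None:
            p += self.bn.params()
        return p

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = self.conv.forward(x, train)
        if self.bn is not None:
            y = self.bn.forward(y, train)
        return self.relu.forward(y, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu.backward(grad)
        if self.bn is not None:
            g = self.bn.backward(g)
        return self.conv.backward(g)
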