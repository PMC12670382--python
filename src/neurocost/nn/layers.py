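"""Minimal NumPy layers for feedforward vision networks.

Layers are declared with shape metadata only; parameter arrays are allocated
when :meth:`Layer.initialize` is called with a seeded ``numpy.random.Generator``
(or when trained weights are assigned).  This keeps large architectures cheap
to describe and partition, and makes seeded re-initialization explicit.

Data layout is NCHW throughout, float32.  Convolution is im2col-based; the
backward passes exist so small networks can be trained with plain SGD.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: a differentiable map with optional parameters."""

    #: True for layers carrying learnable weights (conv / fc).
    has_params: bool = False
    #: "conv" | "fc" | None — used by block partitioning.
    kind: str | None = None

    def initialize(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        """Allocate parameters. No-op for parameter-free layers."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_and_grads(self):
        return []

    @property
    def initialized(self) -> bool:
        return True


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # Fan-in-scaled uniform: U(-1/sqrt(fan_in), +1/sqrt(fan_in)) for both
    # weights and biases — the standard default for ReLU conv nets.
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Layer):
    has_params = True
    kind = "conv"

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, name: str | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.name = name or f"conv{in_channels}x{out_channels}k{kernel_size}"
        self.weight: np.ndarray | None = None
        self.bias: np.ndarray | None = None
        self.dweight = self.dbias = None
        self._cache = None

    @property
    def initialized(self) -> bool:
        return self.weight is not None

    def initialize(self, rng: np.random.Generator) -> None:
        fan_in = self.in_channels * self.kernel_size ** 2
        self.weight = _fan_in_uniform(
            rng, (self.out_channels, self.in_channels,
                  self.kernel_size, self.kernel_size), fan_in)
        self.bias = _fan_in_uniform(rng, (self.out_channels,), fan_in)

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = windows.shape[:4]
        # (N, Hout*Wout, C*k*k)
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        return np.ascontiguousarray(cols), ho, wo

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.initialized:
            raise RuntimeError(f"{self.name}: parameters not initialized")
        cols, ho, wo = self._im2col(x)
        wmat = self.weight.reshape(self.out_channels, -1)
        out = cols @ wmat.T + self.bias
        self._cache = (x.shape, cols)
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.out_channels, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        n, _, ho, wo = grad.shape
        g = grad.reshape(n, self.out_channels, ho * wo).transpose(0, 2, 1)
        self.dbias = g.sum(axis=(0, 1))
        self.dweight = np.einsum("nlo,nlc->oc", g, cols).reshape(self.weight.shape)
        dcols = g @ self.weight.reshape(self.out_channels, -1)
        return self._col2im(dcols, x_shape, ho, wo)

    def _col2im(self, dcols: np.ndarray, x_shape, ho: int, wo: int) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, w = x_shape
        dx = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        for ki in range(k):
            for kj in range(k):
                dx[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dx[:, :, p:p + h, p:p + w] if p else dx

    def params_and_grads(self):
        return [(self, "weight", "dweight"), (self, "bias", "dbias")]

    @property
    def n_params(self) -> int:
        return self.out_channels * (self.in_channels * self.kernel_size ** 2 + 1)


class Linear(Layer):
    has_params = True
    kind = "fc"

    def __init__(self, in_features: int, out_features: int, name: str | None = None):
        self.in_features = in_features
        self.out_features = out_features
        self.name = name or f"fc{in_features}x{out_features}"
        self.weight = self.bias = None
        self.dweight = self.dbias = None
        self._cache = None

    @property
    def initialized(self) -> bool:
        return self.weight is not None

    def initialize(self, rng: np.random.Generator) -> None:
        self.weight = _fan_in_uniform(
            rng, (self.out_features, self.in_features), self.in_features)
        self.bias = _fan_in_uniform(rng, (self.out_features,), self.in_features)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.initialized:
            raise RuntimeError(f"{self.name}: parameters not initialized")
        self._cache = x
        return x @ self.weight.T + self.bias

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self.dweight = grad.T @ x
        self.dbias = grad.sum(axis=0)
        return grad @ self.weight

    def params_and_grads(self):
        return [(self, "weight", "dweight"), (self, "bias", "dbias")]

    @property
    def n_params(self) -> int:
        return self.out_features * (self.in_features + 1)


class ReLU(Layer):
    name = "relu"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0)


class MaxPool2d(Layer):
    """Non-overlapping max pooling (kernel == stride)."""

    def __init__(self, kernel_size: int = 2):
        self.kernel_size = kernel_size
        self.name = f"maxpool{kernel_size}"

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        n, c, h, w = x.shape
        ho, wo = h // k, w // k
        xt = x[:, :, :ho * k, :wo * k].reshape(n, c, ho, k, wo, k)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
        self._argmax = xt.argmax(axis=-1)
        self._in_shape = x.shape
        return xt.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        n, c, h, w = self._in_shape
        ho, wo = h // k, w // k
        dx = np.zeros((n, c, ho, wo, k * k), dtype=grad.dtype)
        np.put_along_axis(dx, self._argmax[..., None], grad[..., None], axis=-1)
        dx = dx.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
        out = np.zeros(self._in_shape, dtype=grad.dtype)
        out[:, :, :ho * k, :wo * k] = dx.reshape(n, c, ho * k, wo * k)
        return out


class AdaptiveAvgPool2d(Layer):
    """Average pooling to a fixed output grid, any input size.

    Output cell (i, j) averages the input slab
    [floor(i*H/out) : ceil((i+1)*H/out)) x [floor(j*W/out) : ceil((j+1)*W/out)).
    """

    def __init__(self, output_size: int):
        self.output_size = output_size
        self.name = f"adaptiveavgpool{output_size}"

    @staticmethod
    def _bounds(insize: int, outsize: int):
        starts = (np.arange(outsize) * insize) // outsize
        ends = -((-(np.arange(outsize) + 1) * insize) // outsize)  # ceil
        return starts, ends

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        o = self.output_size
        hs, he = self._bounds(h, o)
        ws, we = self._bounds(w, o)
        out = np.empty((n, c, o, o), dtype=x.dtype)
        for i in range(o):
            for j in range(o):
                out[:, :, i, j] = x[:, :, hs[i]:he[i], ws[j]:we[j]].mean(axis=(2, 3))
        self._cache = (x.shape, hs, he, ws, we)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, hs, he, ws, we = self._cache
        dx = np.zeros(x_shape, dtype=grad.dtype)
        o = self.output_size
        for i in range(o):
            for j in range(o):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                dx[:, :, hs[i]:he[i], ws[j]:we[j]] += \
                    grad[:, :, i, j][:, :, None, None] / area
        return dx


class Flatten(Layer):
    name = "flatten"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)
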