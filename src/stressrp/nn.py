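"""Minimal NumPy neural-network core used by the stress classifiers.

Implements exactly the pieces the five-block convolutional branches need:
same-padding 2-D/1-D convolution (im2col + GEMM), ReLU, 2x stride-2 max
pooling, global average pooling, dense layers, softmax cross-entropy, and
plain SGD.  Everything runs in float32, forward and backward are pure
NumPy, and all parameter initialization is driven by an explicit
``numpy.random.Generator`` so training is bit-reproducible for a fixed
seed and thread configuration.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "Conv1d", "ReLU", "MaxPool2d", "MaxPool1d",
    "GlobalAvgPool2d", "GlobalAvgPool1d", "Dense", "Sequential",
    "softmax", "cross_entropy", "sgd_step",
]

DTYPE = np.float32


class Layer:
    """Base layer: stateless unless it declares parameters."""

    frozen = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params_and_grads(self):
        return []


def _im2col2d(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) for stride-1 same-padding convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im2d(dcols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Conv2d(Layer):
    """3x3 (configurable) stride-1 convolution with same padding, He init."""

    def __init__(self, cin: int, cout: int, k: int,
                 rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        fan_in = cin * k * k
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in),
                            size=(cout, fan_in)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        self._cols = _im2col2d(x, self.k, self.pad)
        n, _, h, w = x.shape
        out = np.matmul(self.w, self._cols)
        out += self.b[None, :, None]
        return out.reshape(n, self.cout, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = grad.shape
        g = grad.reshape(n, self.cout, h * w)
        self.dw = np.matmul(g, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.db = g.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T.astype(DTYPE), g)
        return _col2im2d(dcols, self._xshape, self.k, self.pad)

    def params_and_grads(self):
        return [(self, "w", "dw"), (self, "b", "db")]


def _im2col1d(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, length = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = np.empty((n, c, k, length), dtype=x.dtype)
    for i in range(k):
        cols[:, :, i] = xp[:, :, i:i + length]
    return cols.reshape(n, c * k, length)


def _col2im1d(dcols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    n, c, length = shape
    dxp = np.zeros((n, c, length + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, length)
    for i in range(k):
        dxp[:, :, i:i + length] += dcols[:, :, i]
    return dxp[:, :, pad:pad + length]


class Conv1d(Layer):
    """Kernel-3 (configurable) stride-1 1-D convolution, same padding."""

    def __init__(self, cin: int, cout: int, k: int,
                 rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        fan_in = cin * k
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in),
                            size=(cout, fan_in)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        self._cols = _im2col1d(x, self.k, self.pad)
        out = np.matmul(self.w, self._cols)
        out += self.b[None, :, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = np.matmul(grad, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.db = grad.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T.astype(DTYPE), grad)
        return _col2im1d(dcols, self._xshape, self.k, self.pad)

    def params_and_grads(self):
        return [(self, "w", "dw"), (self, "b", "db")]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling; trailing odd rows/columns are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._xshape = x.shape
        xr = x[:, :, :2 * h2, :2 * w2].reshape(n, c, h2, 2, w2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._argmax[..., None],
                                  axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, c, h2, w2, 4), dtype=grad.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], grad[..., None],
                          axis=-1)
        dxr = dxr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._xshape, dtype=grad.dtype)
        dx[:, :, :2 * h2, :2 * w2] = dxr.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class MaxPool1d(Layer):
    """Size-2 stride-2 max pooling over the last axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        l2 = length // 2
        self._xshape = x.shape
        xr = x[:, :, :2 * l2].reshape(n, c, l2, 2)
        self._argmax = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._argmax[..., None],
                                  axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._xshape
        l2 = length // 2
        dxr = np.zeros((n, c, l2, 2), dtype=grad.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], grad[..., None],
                          axis=-1)
        dx = np.zeros(self._xshape, dtype=grad.dtype)
        dx[:, :, :2 * l2] = dxr.reshape(n, c, 2 * l2)
        return dx


class GlobalAvgPool2d(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               self._xshape).astype(grad.dtype)


class GlobalAvgPool1d(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._xshape
        return np.broadcast_to(grad[:, :, None] / length,
                               self._xshape).astype(grad.dtype)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        self.w = rng.normal(0, np.sqrt(2.0 / din),
                            size=(din, dout)).astype(DTYPE)
        self.b = np.zeros(dout, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params_and_grads(self):
        return [(self, "w", "dw"), (self, "b", "db")]


class Sequential:
    """A chain of layers with shared frozen/trainable bookkeeping."""

    def __init__(self, layers: list[Layer], frozen: bool = False):
        self.layers = layers
        if frozen:
            self.freeze()

    def freeze(self) -> None:
        for layer in self.layers:
            layer.frozen = True

    @property
    def frozen(self) -> bool:
        return all(layer.frozen for layer in self.layers
                   if layer.params_and_grads())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_and_grads())
        return out

    def state(self) -> list[np.ndarray]:
        """Copies of all parameter arrays, in layer order."""
        return [getattr(obj, name).copy()
                for obj, name, _ in self.params_and_grads()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray,
                  targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean two-class cross-entropy and its gradient w.r.t. the logits."""
    n = len(targets)
    probs = softmax(logits)
    eps = np.finfo(DTYPE).tiny
    loss = float(-np.mean(np.log(probs[np.arange(n), targets] + eps)))
    grad = probs.astype(DTYPE)
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / DTYPE(n)


def sgd_step(modules, lr: float) -> None:
    """In-place SGD update over every unfrozen parameter."""
    for module in modules:
        for obj, pname, gname in module.params_and_grads():
            if not obj.frozen:
                p = getattr(obj, pname)
                p -= DTYPE(lr) * getattr(obj, gname)
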