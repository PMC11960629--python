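"""Minimal CNN building blocks in NumPy.

Implements exactly the pieces the classifier architecture needs — 3×3
same-padding convolution, 2×2 max-pooling, ReLU, inverted dropout, dense
layers, softmax cross-entropy and Adam — with hand-written backward passes.
Convolutions are evaluated as nine shifted matrix products (one per kernel
tap), which keeps memory flat and routes all heavy lifting through BLAS.

Gradient correctness is established by finite-difference checks in the
test suite; layers accept float32 (training default) or float64 (used for
those checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "ReLU",
    "MaxPool2",
    "Dropout",
    "Flatten",
    "Dense",
    "ConvNet",
    "Adam",
    "softmax",
    "softmax_xent",
    "pooled_shapes",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(logits.dtype)


class Conv3x3:
    """3×3 convolution, stride 1, zero padding preserving spatial size."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / (9 * c_in))  # He initialization for ReLU
        self.w = (rng.standard_normal((3, 3, c_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xpad: np.ndarray | None = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xpad = xpad
        y = np.empty((n, h, w, self.w.shape[-1]), dtype=x.dtype)
        y[:] = self.b
        for di in range(3):
            for dj in range(3):
                xs = xpad[:, :, di : di + h, dj : dj + w]
                y += np.tensordot(xs, self.w[di, dj], axes=([1], [0]))
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xpad = self._xpad
        n, c, hp, wp = xpad.shape
        h, w = hp - 2, wp - 2
        gt = np.ascontiguousarray(grad.transpose(0, 2, 3, 1))  # (N,H,W,Cout)
        self.db[:] = gt.sum(axis=(0, 1, 2))
        dxpad = np.zeros_like(xpad)
        for di in range(3):
            for dj in range(3):
                xs = xpad[:, :, di : di + h, dj : dj + w]
                self.dw[di, dj] = np.tensordot(xs, gt, axes=([0, 2, 3], [0, 1, 2]))
                dxs = np.tensordot(gt, self.w[di, dj], axes=([3], [1]))  # (N,H,W,Cin)
                dxpad[:, :, di : di + h, dj : dj + w] += dxs.transpose(0, 3, 1, 2)
        return dxpad[:, :, 1:-1, 1:-1]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2:
    """2×2 max pooling, stride 2; odd trailing rows/columns are dropped (floor)."""

    def __init__(self):
        self._shape: tuple | None = None
        self._idx: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._shape = (n, c, h, w)
        xc = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        windows = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._idx = windows.argmax(axis=-1)
        return np.take_along_axis(windows, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        windows = np.zeros((n, c, h2, w2, 4), dtype=grad.dtype)
        np.put_along_axis(windows, self._idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            windows.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx


class Dropout:
    """Inverted dropout: scales kept activations by 1/(1-p) during training,
    identity at inference, so two inference passes are bit-identical."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten:
    def __init__(self):
        self._shape: tuple | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        return grad @ self.w.T


def pooled_shapes(height: int, width: int, n_blocks: int = 3) -> list[tuple[int, int]]:
    """Spatial dimensions after each 2×2/stride-2 pooling stage (floor halving)."""
    shapes = []
    h, w = height, width
    for _ in range(n_blocks):
        h, w = h // 2, w // 2
        shapes.append((h, w))
    return shapes


class ConvNet:
    """Three conv(3×3, same)+ReLU+pool(2×2) blocks, dropout, FC-256, 2-way softmax.

    For a 75-wide × 64-high input the pooled feature maps are 37×32, 18×16
    and 9×8 (width × height), and the flattened feature vector has
    9·8·128 = 9216 entries.
    """

    def __init__(
        self,
        input_height: int,
        input_width: int,
        conv_filters: tuple[int, int, int] = (32, 64, 128),
        fc_units: int = 256,
        conv_dropout: float = 0.25,
        fc_dropout: float = 0.50,
        n_classes: int = 2,
        rng: np.random.Generator | int | None = 0,
        dtype=np.float32,
    ):
        shapes = pooled_shapes(input_height, input_width, len(conv_filters))
        if min(shapes[-1]) < 1:
            raise ValueError(
                f"input {input_height}×{input_width} too small for "
                f"{len(conv_filters)} pooling stages (needs ≥ 8 px per axis)"
            )
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.input_height, self.input_width = input_height, input_width
        self.pooled_shapes = shapes
        self.flatten_features = shapes[-1][0] * shapes[-1][1] * conv_filters[-1]
        self.dtype = dtype

        layers: list = []
        c_prev = 1
        for c in conv_filters:
            layers += [Conv3x3(c_prev, c, rng, dtype), ReLU(), MaxPool2()]
            c_prev = c
        layers += [
            Dropout(conv_dropout, rng),
            Flatten(),
            Dense(self.flatten_features, fc_units, rng, dtype),
            ReLU(),
            Dropout(fc_dropout, rng),
            Dense(fc_units, n_classes, rng, dtype),
        ]
        self.layers = layers

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2] != self.input_height or x.shape[3] != self.input_width:
            raise ValueError(
                f"input shape {x.shape[2]}×{x.shape[3]} (H×W) does not match the "
                f"model's {self.input_height}×{self.input_width}"
            )
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for lay in reversed(self.layers):
            grad = lay.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.params(), weights, strict=True):
            p[...] = w


class Adam:
    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
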