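"""Layers with forward/backward passes, float32 throughout.

Array layout is channels-last: ``(B, H, W, C)`` for 2D, ``(B, D, H, W, C)``
for 3D. Convolutions use `same` zero padding so two 3x3 convolutions plus
one 2x2 pool map a 32-patch to 16, making dense input sizes deterministic.

Implementation notes (single-CPU, memory-bandwidth-bound target):
reductions over the batch axis go through BLAS (``ones @ x`` /
``einsum``) rather than strided ``sum(axis=0)``; batch-norm caches the
centred activations it needs anyway; the input gradient of a network's
first convolution is skipped; pooling backward uses an equality mask with
tie-count division (exact ties occur only in zero-padded regions).
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable array and its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def describe(self) -> dict:
        return {"type": type(self).__name__}


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


def _im2col2d(x: np.ndarray) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, 9*C) columns for a 3x3 `same` convolution."""
    B, H, W, C = x.shape
    p = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(p, (3, 3), axis=(1, 2))
    # win: (B, H, W, C, 3, 3) -> (B, H, W, 3, 3, C)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(B * H * W, 9 * C)


def _im2col3d(x: np.ndarray) -> np.ndarray:
    B, D, H, W, C = x.shape
    p = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(p, (3, 3, 3), axis=(1, 2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 7, 4))
    return cols.reshape(B * D * H * W, 27 * C)


class Conv2D(Layer):
    """3x3 `same` convolution.

    ``first`` marks a network input layer whose input gradient is never
    consumed; its backward pass then skips the transposed convolution.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 first: bool = False) -> None:
        self.cin, self.cout = cin, cout
        self.first = first
        self.w = Param(_he_init(rng, (9 * cin, cout), fan_in=9 * cin))
        self.b = Param(np.zeros(cout))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] = ()

    def forward(self, x, training):
        self._shape = x.shape
        cols = _im2col2d(x)
        if training:
            self._cols = cols
        y = cols @ self.w.value
        y += self.b.value
        return y.reshape(x.shape[:3] + (self.cout,))

    def backward(self, grad):
        B, H, W, _ = self._shape
        g2 = grad.reshape(-1, self.cout)
        self.w.grad += self._cols.T @ g2
        self.b.grad += np.ones(g2.shape[0], F32) @ g2
        if self.first:
            return None
        # gradient w.r.t. input: correlate grad with the rotated kernel
        wk = self.w.value.reshape(3, 3, self.cin, self.cout)
        wrot = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(9 * self.cout, self.cin)
        cols_g = _im2col2d(grad)
        return (cols_g @ wrot).reshape(B, H, W, self.cin)

    def params(self):
        return [self.w, self.b]

    def describe(self):
        return {"type": "Conv2D", "kernel": [3, 3], "in": self.cin,
                "out": self.cout, "padding": "same"}


class Conv3D(Layer):
    """3x3x3 `same` convolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 first: bool = False) -> None:
        self.cin, self.cout = cin, cout
        self.first = first
        self.w = Param(_he_init(rng, (27 * cin, cout), fan_in=27 * cin))
        self.b = Param(np.zeros(cout))
        self._cols = None
        self._shape = ()

    def forward(self, x, training):
        self._shape = x.shape
        cols = _im2col3d(x)
        if training:
            self._cols = cols
        y = cols @ self.w.value
        y += self.b.value
        return y.reshape(x.shape[:4] + (self.cout,))

    def backward(self, grad):
        B, D, H, W, _ = self._shape
        g2 = grad.reshape(-1, self.cout)
        self.w.grad += self._cols.T @ g2
        self.b.grad += np.ones(g2.shape[0], F32) @ g2
        if self.first:
            return None
        wk = self.w.value.reshape(3, 3, 3, self.cin, self.cout)
        wrot = wk[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3).reshape(
            27 * self.cout, self.cin
        )
        cols_g = _im2col3d(grad)
        return (cols_g @ wrot).reshape(B, D, H, W, self.cin)

    def params(self):
        return [self.w, self.b]

    def describe(self):
        return {"type": "Conv3D", "kernel": [3, 3, 3], "in": self.cin,
                "out": self.cout, "padding": "same"}


class BatchNorm(Layer):
    """Batch normalization over all but the channel axis.

    Training uses batch statistics and maintains exponential running
    moments; evaluation uses the running moments.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self._xhat = None
        self._invstd = None

    def forward(self, x, training):
        flat = x.reshape(-1, self.channels)
        n = flat.shape[0]
        if training:
            ones = np.ones(n, F32)
            mu = (ones @ flat) / F32(n)
            xc = flat - mu
            var = np.einsum("nc,nc->c", xc, xc) / F32(n)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
            invstd = (1.0 / np.sqrt(var + self.eps)).astype(F32)
            xc *= invstd  # xc becomes xhat in place
            self._xhat, self._invstd = xc, invstd
            y = xc * self.gamma.value
            y += self.beta.value
            return y.reshape(x.shape)
        a = (self.gamma.value / np.sqrt(self.running_var + self.eps)).astype(F32)
        b = self.beta.value - self.running_mean * a
        y = flat * a
        y += b
        return y.reshape(x.shape)

    def backward(self, grad):
        shape = grad.shape
        g = grad.reshape(-1, self.channels)
        xhat = self._xhat
        n = g.shape[0]
        ones = np.ones(n, F32)
        dbeta = ones @ g
        dgamma = np.einsum("nc,nc->c", g, xhat)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        coef = (self.gamma.value * self._invstd).astype(F32)
        dx = g - dbeta / F32(n) - xhat * (dgamma / F32(n))
        dx *= coef
        return dx.reshape(shape)

    def params(self):
        return [self.gamma, self.beta]

    def describe(self):
        return {"type": "BatchNorm", "channels": self.channels}


class ReLU(Layer):
    def forward(self, x, training):
        y = np.maximum(x, F32(0.0))
        if training:
            self._y = y
        return y

    def backward(self, grad):
        grad = grad * (self._y > 0)
        return grad

    def describe(self):
        return {"type": "ReLU"}


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2.

    Backward routes the gradient through an equality mask divided by the
    tie count; exact ties arise only among identical (e.g. zero-padded)
    inputs, where an even split keeps the gradient magnitude correct.
    """

    def forward(self, x, training):
        B, H, W, C = x.shape
        r = x.reshape(B, H // 2, 2, W // 2, 2, C)
        out = r.max(axis=4).max(axis=2)
        if training:
            self._x_r = r
            self._out = out
        return out

    def backward(self, grad):
        r = self._x_r
        B, H2, _, W2, _, C = r.shape
        mask = r == self._out[:, :, None, :, None, :]
        counts = np.einsum("bhiwjc->bhwc", mask.astype(F32))
        g = (grad / counts)[:, :, None, :, None, :] * mask
        return g.reshape(B, H2 * 2, W2 * 2, C)

    def describe(self):
        return {"type": "MaxPool2D", "kernel": [2, 2]}


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2."""

    def forward(self, x, training):
        B, D, H, W, C = x.shape
        r = x.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        out = r.max(axis=6).max(axis=4).max(axis=2)
        if training:
            self._x_r = r
            self._out = out
        return out

    def backward(self, grad):
        r = self._x_r
        B, D2, _, H2, _, W2, _, C = r.shape
        mask = r == self._out[:, :, None, :, None, :, None, :]
        counts = np.einsum("bdihjwkc->bdhwc", mask.astype(F32))
        g = (grad / counts)[:, :, None, :, None, :, None, :] * mask
        return g.reshape(B, D2 * 2, H2 * 2, W2 * 2, C)

    def describe(self):
        return {"type": "MaxPool3D", "kernel": [2, 2, 2]}


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.p <= 0:
            self._mask = None
            return x
        mask = self.rng.random(x.shape, dtype=F32)
        keep = mask >= self.p
        np.multiply(keep, F32(1.0 / (1.0 - self.p)), out=mask)
        self._mask = mask
        return x * mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        grad = grad * self._mask
        return grad

    def describe(self):
        return {"type": "Dropout", "p": self.p}


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def describe(self):
        return {"type": "Flatten"}


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator) -> None:
        self.nin, self.nout = nin, nout
        self.w = Param(_he_init(rng, (nin, nout), fan_in=nin))
        self.b = Param(np.zeros(nout))
        self._x = None

    def forward(self, x, training):
        if training:
            self._x = x
        y = x @ self.w.value
        y += self.b.value
        return y

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += np.ones(grad.shape[0], F32) @ grad
        return grad @ self.w.value.T

    def params(self):
        return [self.w, self.b]

    def describe(self):
        return {"type": "Dense", "in": self.nin, "units": self.nout}


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def describe(self):
        return {"type": "Sequential", "layers": [l.describe() for l in self.layers]}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
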