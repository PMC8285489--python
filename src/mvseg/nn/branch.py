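"""Kernel-backed 2D branch stem: the performance-critical execution path.

Computes exactly the architecture's branch sequence
[conv3x3 -> BN -> ReLU] x2 -> maxpool 2x2 -> dropout -> dense(32) -> BN ->
ReLU, in channels-first layout via the numba kernels, with hand-written
backpropagation. The 3D branch and the dense head use the generic layer
objects; this class exists because the nine 2D stems dominate runtime.
"""

from __future__ import annotations

import numpy as np

from . import kernels as K
from .layers import F32, Param, _he_init

_MOMENTUM = 0.9
_EPS = 1e-5


class _BNState:
    """Running moments plus per-batch cache for one batch-norm site."""

    __slots__ = ("gamma", "beta", "running_mean", "running_var",
                 "mean", "invstd", "a", "b")

    def __init__(self, channels: int) -> None:
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def affine(self, training: bool, mean=None, var=None):
        """Per-channel scale/shift (a, b) for y = x*a + b."""
        if training:
            self.mean = mean
            self.invstd = (1.0 / np.sqrt(var + _EPS)).astype(F32)
            self.running_mean = (
                _MOMENTUM * self.running_mean + (1 - _MOMENTUM) * mean
            ).astype(F32)
            self.running_var = (
                _MOMENTUM * self.running_var + (1 - _MOMENTUM) * var
            ).astype(F32)
        else:
            self.mean = self.running_mean
            self.invstd = (1.0 / np.sqrt(self.running_var + _EPS)).astype(F32)
        self.a = (self.gamma.value * self.invstd).astype(F32)
        self.b = (self.beta.value - self.mean * self.a).astype(F32)
        return self.a, self.b


class Branch2D:
    """One (view, scale) stem mapping (B, 32, 32, ch) patches to (B, 32)."""

    def __init__(self, ch: int, f1: int, f2: int, dense_units: int,
                 dropout_p: float, init_rng: np.random.Generator,
                 dropout_rng: np.random.Generator) -> None:
        self.ch, self.f1, self.f2 = ch, f1, f2
        self.du, self.p = dense_units, dropout_p
        self.dropout_rng = dropout_rng
        self.w1 = Param(_he_init(init_rng, (ch, 3, 3, f1), fan_in=9 * ch))
        self.b1 = Param(np.zeros(f1))
        self.bn1 = _BNState(f1)
        self.w2 = Param(_he_init(init_rng, (f1, 3, 3, f2), fan_in=9 * f1))
        self.b2 = Param(np.zeros(f2))
        self.bn2 = _BNState(f2)
        n_flat = f2 * 16 * 16
        self.wd = Param(_he_init(init_rng, (n_flat, dense_units), fan_in=n_flat))
        self.bd = Param(np.zeros(dense_units))
        self.bn3 = _BNState(dense_units)

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B = x.shape[0]
        f1, f2 = self.f1, self.f2
        xp1 = np.zeros((B, self.ch, 34, 34), F32)
        K.relayout_pad(np.ascontiguousarray(x, dtype=F32), xp1)
        y1 = np.empty((B, f1, 32, 32), F32)
        K.conv2d_cf(xp1, self.w1.value, self.b1.value, y1)
        if training:
            a1, b1 = self.bn1.affine(True, *K.bn_stats(y1))
        else:
            a1, b1 = self.bn1.affine(False)
        xp2 = np.zeros((B, f1, 34, 34), F32)
        K.bnrelu_fwd(y1, a1, b1, xp2)
        y2 = np.empty((B, f2, 32, 32), F32)
        K.conv2d_cf(xp2, self.w2.value, self.b2.value, y2)
        if training:
            a2, b2 = self.bn2.affine(True, *K.bn_stats(y2))
        else:
            a2, b2 = self.bn2.affine(False)
        xp3 = np.zeros((B, f2, 34, 34), F32)
        K.bnrelu_fwd(y2, a2, b2, xp3)
        pooled = np.empty((B, f2, 16, 16), F32)
        arg = np.empty((B, f2, 16, 16), np.uint8)
        K.maxpool_fwd(xp3[:, :, 1:33, 1:33], pooled, arg)
        if training and self.p > 0:
            mask = self.dropout_rng.random(pooled.shape, dtype=F32)
            keep = mask >= self.p
            np.multiply(keep, F32(1.0 / (1.0 - self.p)), out=mask)
            pooled = pooled * mask
        else:
            mask = None
        flat = pooled.reshape(B, -1)
        d = flat @ self.wd.value + self.bd.value
        if training:
            mu = d.mean(axis=0)
            var = d.var(axis=0)
            a3, b3 = self.bn3.affine(True, mu.astype(F32), var.astype(F32))
        else:
            a3, b3 = self.bn3.affine(False)
        out = np.maximum(d * a3 + b3, F32(0.0))
        if training:
            self._cache = (xp1, y1, xp2, y2, arg, mask, flat, d, out)
        return out

    # -- backward -----------------------------------------------------------

    def backward(self, g: np.ndarray) -> None:
        xp1, y1, xp2, y2, arg, mask, flat, d, out = self._cache
        B = g.shape[0]
        n = F32(B)
        # dense-head BN + ReLU backward (small arrays, plain numpy)
        bn3 = self.bn3
        gm = g * (out > 0)
        xhat3 = (d - bn3.mean) * bn3.invstd
        s1 = gm.sum(axis=0)
        s2 = (gm * xhat3).sum(axis=0)
        bn3.gamma.grad += s2
        bn3.beta.grad += s1
        gd = (bn3.gamma.value * bn3.invstd) * (gm - s1 / n - xhat3 * (s2 / n))
        gd = gd.astype(F32)
        self.wd.grad += flat.T @ gd
        self.bd.grad += gd.sum(axis=0)
        gflat = gd @ self.wd.value.T
        gp = gflat.reshape(B, self.f2, 16, 16)
        if mask is not None:
            gp = gp * mask
        g3 = np.empty((B, self.f2, 32, 32), F32)
        K.maxpool_bwd(np.ascontiguousarray(gp), arg, g3)
        # BN2 + ReLU backward (batch statistics of this step)
        bn2 = self.bn2
        s1b, s2b = K.bnrelu_bwd_sums(g3, y2, bn2.a, bn2.b, bn2.mean, bn2.invstd)
        bn2.gamma.grad += s2b.astype(F32)
        bn2.beta.grad += s1b.astype(F32)
        inv_n = 1.0 / (B * 32 * 32)
        gy2 = np.empty_like(y2)
        K.bnrelu_bwd_dx(g3, y2, bn2.a, bn2.b, bn2.mean, bn2.invstd,
                        bn2.gamma.value, s1b, s2b, inv_n, gy2)
        # conv2 backward
        K.conv2d_dw(xp2, gy2, self.w2.grad, self.b2.grad)
        gy2p = np.zeros((B, self.f2, 34, 34), F32)
        K.pad_interior(gy2, gy2p)
        wrot2 = np.ascontiguousarray(
            self.w2.value[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)
        )
        g1 = np.empty((B, self.f1, 32, 32), F32)
        K.conv2d_cf(gy2p, wrot2, np.zeros(self.f1, F32), g1)
        # BN1 + ReLU backward
        bn1 = self.bn1
        s1a, s2a = K.bnrelu_bwd_sums(g1, y1, bn1.a, bn1.b, bn1.mean, bn1.invstd)
        bn1.gamma.grad += s2a.astype(F32)
        bn1.beta.grad += s1a.astype(F32)
        gy1 = np.empty_like(y1)
        K.bnrelu_bwd_dx(g1, y1, bn1.a, bn1.b, bn1.mean, bn1.invstd,
                        bn1.gamma.value, s1a, s2a, inv_n, gy1)
        # conv1: weight gradients only (input layer)
        K.conv2d_dw(xp1, gy1, self.w1.grad, self.b1.grad)
        self._cache = None

    # -- bookkeeping ----------------------------------------------------------

    def params(self) -> list[Param]:
        return [
            self.w1, self.b1, self.bn1.gamma, self.bn1.beta,
            self.w2, self.b2, self.bn2.gamma, self.bn2.beta,
            self.wd, self.bd, self.bn3.gamma, self.bn3.beta,
        ]

    def batchnorms(self):
        return [self.bn1, self.bn2, self.bn3]

    def describe(self) -> dict:
        du = self.du
        return {
            "type": "Sequential",
            "layers": [
                {"type": "Conv2D", "kernel": [3, 3], "in": self.ch,
                 "out": self.f1, "padding": "same"},
                {"type": "BatchNorm", "channels": self.f1},
                {"type": "ReLU"},
                {"type": "Conv2D", "kernel": [3, 3], "in": self.f1,
                 "out": self.f2, "padding": "same"},
                {"type": "BatchNorm", "channels": self.f2},
                {"type": "ReLU"},
                {"type": "MaxPool2D", "kernel": [2, 2]},
                {"type": "Dropout", "p": self.p},
                {"type": "Flatten"},
                {"type": "Dense", "in": self.f2 * 256, "units": du},
                {"type": "BatchNorm", "channels": du},
                {"type": "ReLU"},
            ],
        }
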