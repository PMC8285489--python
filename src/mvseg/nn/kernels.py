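"""Numba kernels for the 2D branch stems (single-CPU, fused, float32).

The generic layer objects express the architecture; these kernels are the
bandwidth-lean execution path for the 2D convolutional stems: direct `same`
convolution in channels-first layout (no im2col materialization), fused
batch-norm + ReLU passes, and max-pool with stored argmax. Gradient
formulas match the generic layers exactly (up to float summation order).
"""

from __future__ import annotations

import numpy as np
from numba import njit

F32 = np.float32


@njit(cache=True, fastmath=True)
def conv2d_cf(xp, w, b, y):
    """`same` 3x3 convolution; xp (B,ci,H+2,W+2) pre-padded, w (ci,3,3,co),
    y (B,co,H,W) overwritten."""
    B, ci, Hp, Wp = xp.shape
    co = w.shape[3]
    H, W = Hp - 2, Wp - 2
    for n in range(B):
        for c in range(co):
            for i in range(H):
                for j in range(W):
                    y[n, c, i, j] = b[c]
            for ic in range(ci):
                for di in range(3):
                    for dj in range(3):
                        wv = w[ic, di, dj, c]
                        for i in range(H):
                            for j in range(W):
                                y[n, c, i, j] += wv * xp[n, ic, i + di, j + dj]


@njit(cache=True, fastmath=True)
def conv2d_dw(xp, g, dw, db):
    """Accumulate weight/bias gradients; xp (B,ci,H+2,W+2), g (B,co,H,W)."""
    B, ci, Hp, Wp = xp.shape
    co = g.shape[1]
    H, W = Hp - 2, Wp - 2
    for n in range(B):
        for c in range(co):
            s = F32(0.0)
            for i in range(H):
                for j in range(W):
                    s += g[n, c, i, j]
            db[c] += s
            for ic in range(ci):
                for di in range(3):
                    for dj in range(3):
                        acc = F32(0.0)
                        for i in range(H):
                            for j in range(W):
                                acc += xp[n, ic, i + di, j + dj] * g[n, c, i, j]
                        dw[ic, di, dj, c] += acc


@njit(cache=True, fastmath=True)
def bn_stats(x):
    """Per-channel mean and biased variance of x (B,C,H,W); per-plane
    float32 partial sums accumulated in float64."""
    B, C, H, W = x.shape
    n = B * H * W
    mean = np.zeros(C, dtype=np.float64)
    var = np.zeros(C, dtype=np.float64)
    for c in range(C):
        s = 0.0
        s2 = 0.0
        for b in range(B):
            ps = F32(0.0)
            ps2 = F32(0.0)
            for i in range(H):
                for j in range(W):
                    v = x[b, c, i, j]
                    ps += v
                    ps2 += v * v
            s += ps
            s2 += ps2
        m = s / n
        mean[c] = m
        var[c] = s2 / n - m * m
    return mean.astype(F32), np.maximum(var, 0.0).astype(F32)


@njit(cache=True, fastmath=True)
def bnrelu_fwd(x, a, bb, outp):
    """outp interior (margin 1) = relu(x * a + bb); margins stay zero."""
    B, C, H, W = x.shape
    for n in range(B):
        for c in range(C):
            ac = a[c]
            bc = bb[c]
            for i in range(H):
                for j in range(W):
                    v = x[n, c, i, j] * ac + bc
                    outp[n, c, i + 1, j + 1] = v if v > F32(0.0) else F32(0.0)


@njit(cache=True, fastmath=True)
def bnrelu_bwd_sums(g, x, a, bb, mean, invstd):
    """Per-channel sums of the ReLU-masked gradient: s1 = sum(gm) and
    s2 = sum(gm * xhat), where the mask comes from the forward activation
    ``x*a+bb > 0`` and xhat = (x - mean) * invstd."""
    B, C, H, W = x.shape
    s1 = np.zeros(C, dtype=np.float64)
    s2 = np.zeros(C, dtype=np.float64)
    for n in range(B):
        for c in range(C):
            ac = a[c]
            bc = bb[c]
            mc = mean[c]
            isc = invstd[c]
            p1 = F32(0.0)
            p2 = F32(0.0)
            for i in range(H):
                for j in range(W):
                    xv = x[n, c, i, j]
                    gv = g[n, c, i, j] if xv * ac + bc > F32(0.0) else F32(0.0)
                    p1 += gv
                    p2 += gv * ((xv - mc) * isc)
            s1[c] += p1
            s2[c] += p2
    return s1, s2


@njit(cache=True, fastmath=True)
def bnrelu_bwd_dx(g, x, a, bb, mean, invstd, gamma, s1, s2x, inv_n, dx):
    """dx through ReLU then batch norm (training statistics).

    ``s1`` is sum(gm); ``s2x`` is sum(gm * xhat) (caller converts from the
    y-sums). dx = gamma*invstd * (gm - s1/n - xhat * s2x/n).
    """
    B, C, H, W = x.shape
    for n in range(B):
        for c in range(C):
            ac = a[c]
            bc = bb[c]
            coef = gamma[c] * invstd[c]
            m1 = F32(s1[c] * inv_n)
            m2 = F32(s2x[c] * inv_n)
            mc = mean[c]
            isc = invstd[c]
            for i in range(H):
                for j in range(W):
                    y = x[n, c, i, j] * ac + bc
                    gm = g[n, c, i, j] if y > F32(0.0) else F32(0.0)
                    xhat = (x[n, c, i, j] - mc) * isc
                    dx[n, c, i, j] = coef * (gm - m1 - xhat * m2)


@njit(cache=True, fastmath=True)
def maxpool_fwd(x, y, arg):
    """2x2/stride-2 max pool of x (B,C,32,32) -> y (B,C,16,16); arg stores
    the winning window position (0..3, first max wins)."""
    B, C, H, W = x.shape
    for n in range(B):
        for c in range(C):
            for i in range(H // 2):
                for j in range(W // 2):
                    best = x[n, c, 2 * i, 2 * j]
                    bi = np.uint8(0)
                    v = x[n, c, 2 * i, 2 * j + 1]
                    if v > best:
                        best = v
                        bi = np.uint8(1)
                    v = x[n, c, 2 * i + 1, 2 * j]
                    if v > best:
                        best = v
                        bi = np.uint8(2)
                    v = x[n, c, 2 * i + 1, 2 * j + 1]
                    if v > best:
                        best = v
                        bi = np.uint8(3)
                    y[n, c, i, j] = best
                    arg[n, c, i, j] = bi


@njit(cache=True, fastmath=True)
def maxpool_bwd(g, arg, dx):
    """Scatter pooled gradient back to the argmax positions; dx overwritten."""
    B, C, H2, W2 = g.shape
    dx[...] = F32(0.0)
    for n in range(B):
        for c in range(C):
            for i in range(H2):
                for j in range(W2):
                    a = arg[n, c, i, j]
                    dx[n, c, 2 * i + a // 2, 2 * j + a % 2] = g[n, c, i, j]


@njit(cache=True, fastmath=True)
def relayout_pad(src, dst):
    """(B,32,32,ch) channels-last -> channels-first interior of (B,ch,34,34)."""
    B, H, W, C = src.shape
    for n in range(B):
        for i in range(H):
            for j in range(W):
                for c in range(C):
                    dst[n, c, i + 1, j + 1] = src[n, i, j, c]


@njit(cache=True, fastmath=True)
def pad_interior(src, dst):
    """(B,C,H,W) -> interior of (B,C,H+2,W+2); margins assumed zero."""
    B, C, H, W = src.shape
    for n in range(B):
        for c in range(C):
            for i in range(H):
                for j in range(W):
                    dst[n, c, i + 1, j + 1] = src[n, c, i, j]


def warmup() -> None:
    """Trigger JIT compilation of all kernels on tiny inputs."""
    xp = np.zeros((1, 2, 6, 6), F32)
    w = np.zeros((2, 3, 3, 2), F32)
    b = np.zeros(2, F32)
    y = np.zeros((1, 2, 4, 4), F32)
    conv2d_cf(xp, w, b, y)
    conv2d_dw(xp, y, w.copy(), b.copy())
    mean, var = bn_stats(y)
    outp = np.zeros((1, 2, 6, 6), F32)
    bnrelu_fwd(y, b + 1, b, outp)
    s1, s2 = bnrelu_bwd_sums(y, y, b + 1, b, mean, var + 1)
    bnrelu_bwd_dx(y, y, b + 1, b, mean, var + 1, b + 1, s1, s2, 0.1,
                  np.zeros_like(y))
    x32 = np.zeros((1, 2, 4, 4), F32)
    y16 = np.zeros((1, 2, 2, 2), F32)
    arg = np.zeros((1, 2, 2, 2), np.uint8)
    maxpool_fwd(x32, y16, arg)
    maxpool_bwd(y16, arg, x32)
    relayout_pad(np.zeros((1, 4, 4, 2), F32), np.zeros((1, 2, 6, 6), F32))
    pad_interior(x32, np.zeros((1, 2, 6, 6), F32))
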