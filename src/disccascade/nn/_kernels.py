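"""Numba direct-convolution kernels for the high-resolution, low-channel case.

At the outer levels of a U-shaped network the 3x3 convolutions touch many
pixels but few channels, so an im2col GEMM is dominated by patch-matrix
copies rather than arithmetic.  These kernels compute the convolution (and
its input/weight gradients) directly with implicit zero padding, reading the
input once.  Weight layout is ``(3, 3, C_in, C_out)`` — a free reshape of the
``(9*C_in, C_out)`` GEMM layout.  Falls back gracefully when numba is
unavailable (``HAVE_NUMBA``).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speed dependency
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco


@njit(fastmath=True, cache=True)
def conv3x3_fwd(x, w, b, y):  # pragma: no cover - jitted
    n_, h_, w_g, ci_ = x.shape
    co_ = y.shape[3]
    for n in range(n_):
        for h in range(h_):
            for wv in range(w_g):
                acc = np.zeros(co_, dtype=np.float32)
                for di in range(3):
                    hh = h + di - 1
                    if hh < 0 or hh >= h_:
                        continue
                    for dj in range(3):
                        ww = wv + dj - 1
                        if ww < 0 or ww >= w_g:
                            continue
                        for ci in range(ci_):
                            xv = x[n, hh, ww, ci]
                            if xv != 0.0:
                                for co in range(co_):
                                    acc[co] += xv * w[di, dj, ci, co]
                for co in range(co_):
                    y[n, h, wv, co] = acc[co] + b[co]


@njit(fastmath=True, cache=True)
def conv3x3_dx(g, w, dx):  # pragma: no cover - jitted
    n_, h_, w_g, co_ = g.shape
    ci_ = dx.shape[3]
    for n in range(n_):
        for p in range(h_):
            for q in range(w_g):
                for di in range(3):
                    hh = p - (di - 1)
                    if hh < 0 or hh >= h_:
                        continue
                    for dj in range(3):
                        ww = q - (dj - 1)
                        if ww < 0 or ww >= w_g:
                            continue
                        for ci in range(ci_):
                            acc = np.float32(0.0)
                            for co in range(co_):
                                acc += g[n, hh, ww, co] * w[di, dj, ci, co]
                            dx[n, p, q, ci] += acc


@njit(fastmath=True, cache=True)
def conv3x3_dw(x, g, dw):  # pragma: no cover - jitted
    n_, h_, w_g, ci_ = x.shape
    co_ = g.shape[3]
    for n in range(n_):
        for h in range(h_):
            for wv in range(w_g):
                for di in range(3):
                    hh = h + di - 1
                    if hh < 0 or hh >= h_:
                        continue
                    for dj in range(3):
                        ww = wv + dj - 1
                        if ww < 0 or ww >= w_g:
                            continue
                        for ci in range(ci_):
                            xv = x[n, hh, ww, ci]
                            if xv != 0.0:
                                for co in range(co_):
                                    dw[di, dj, ci, co] += xv * g[n, h, wv, co]
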