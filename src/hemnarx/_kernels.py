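"""Numba kernels for closed-loop NARX forward simulation and backprop.

Training backpropagates through the full unrolled closed-loop recursion
(the network's own outputs feed the output delay line), so the gradient at
day ``t`` accumulates contributions from every later day that still sees
``y_t`` in its delay line.  These kernels keep per-epoch cost negligible
for the small (hundreds of weights, 300-day) networks used here.

Activation ids: 0 sigmoid, 1 tanh, 2 linear, 3 relu.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ACT_IDS = {"sigmoid": 0, "tanh": 1, "linear": 2, "relu": 3}


@njit(cache=True)
def closed_loop_forward(Wh, wo, u, y_init, ny, nu, act_id):
    """Simulate the closed loop; returns (yhat, H, bad_day).

    ``H`` caches hidden activations for the backward pass.  ``bad_day`` is
    the first day with a non-finite output, or -1 if none.
    """
    T = u.shape[0]
    Nn = Wh.shape[0]
    yhat = np.zeros(T)
    H = np.zeros((T, Nn))
    yhat[:ny] = y_init
    for t in range(ny, T):
        for i in range(Nn):
            a = 0.0
            for j in range(ny):
                a += Wh[i, j] * yhat[t - 1 - j]
            for j in range(nu):
                idx = t - 1 - j
                if idx >= 0:
                    a += Wh[i, ny + j] * u[idx]
            if act_id == 0:
                h = 1.0 / (1.0 + np.exp(-a))
            elif act_id == 1:
                h = np.tanh(a)
            elif act_id == 2:
                h = a
            else:
                h = a if a > 0.0 else 0.0
            H[t, i] = h
        out = 0.0
        for i in range(Nn):
            out += wo[i] * H[t, i]
        yhat[t] = out
        if not np.isfinite(out):
            return yhat, H, t
    return yhat, H, -1


@njit(cache=True)
def closed_loop_backward(Wh, wo, u, y, yhat, H, ny, nu, act_id, res_scale, wmask):
    """Gradient of ``res_scale * sum_{t>=ny} wmask_t (yhat_t - y_t)^2``.

    Reverse-mode pass through the unrolled recursion: the adjoint of each
    predicted output collects its direct residual term plus contributions
    from the (up to ny) later steps whose delay lines contain it.  The first
    ny outputs are data, not predictions, and receive no adjoint.
    """
    T = u.shape[0]
    Nn = Wh.shape[0]
    gWh = np.zeros_like(Wh)
    gwo = np.zeros_like(wo)
    r = np.zeros(T)  # adjoint dL/dyhat
    delta = np.zeros(Nn)
    for t in range(T - 1, ny - 1, -1):
        rt = r[t] + res_scale * 2.0 * wmask[t] * (yhat[t] - y[t])
        if rt == 0.0:
            continue
        for i in range(Nn):
            h = H[t, i]
            if act_id == 0:
                dh = h * (1.0 - h)
            elif act_id == 1:
                dh = 1.0 - h * h
            elif act_id == 2:
                dh = 1.0
            else:
                dh = 1.0 if h > 0.0 else 0.0
            delta[i] = rt * wo[i] * dh
            gwo[i] += rt * h
        for j in range(ny):
            idx = t - 1 - j
            xj = yhat[idx]
            s = 0.0
            for i in range(Nn):
                gWh[i, j] += delta[i] * xj
                s += delta[i] * Wh[i, j]
            if idx >= ny:
                r[idx] += s
        for j in range(nu):
            idx = t - 1 - j
            if idx >= 0:
                xj = u[idx]
                for i in range(Nn):
                    gWh[i, ny + j] += delta[i] * xj
    return gWh, gwo
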