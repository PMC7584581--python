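"""Numba kernel for the delay-coupled phase-oscillator integration.

The coupling term sum_j c_ij sin(theta_j(t - tau_ij) - theta_i(t)) is
evaluated from circular sin/cos history buffers via the angle-difference
identity, so no per-edge trigonometry is needed inside the hot loop.
Delays are realized as per-edge integer step offsets into the buffers.
"""

from __future__ import annotations

import numba
import numpy as np

TWO_PI = 2.0 * np.pi


@numba.njit(cache=True)
def integrate_kuramoto(theta0, omega, k, indptr, indices, cvals, dsteps,
                       dt, n_steps, store_stride, n_transient_steps):
    """Heun integration of the delay-coupled Kuramoto system.

    Parameters are flat CSR arrays over directed edges (row i holds the
    sources j coupling into i), ``dsteps`` the per-edge delay in integer
    steps, ``omega`` the angular frequency (rad per time unit), ``dt`` the
    step, ``n_steps`` the total steps simulated, ``n_transient_steps`` the
    leading steps discarded, ``store_stride`` the output decimation.
    Returns the stored phase array (n, n_stored) wrapped to [0, 2 pi).
    """
    n = theta0.shape[0]
    maxd = 0
    for e in range(len(dsteps)):
        if dsteps[e] > maxd:
            maxd = dsteps[e]
    buf_len = maxd + 2
    sin_buf = np.empty((buf_len, n))
    cos_buf = np.empty((buf_len, n))
    # seed history with uncoupled backward rotation
    for b in range(buf_len):
        for i in range(n):
            ang = theta0[i] - omega * dt * b
            sin_buf[(0 - b) % buf_len, i] = np.sin(ang)
            cos_buf[(0 - b) % buf_len, i] = np.cos(ang)

    n_stored = (n_steps - n_transient_steps + store_stride - 1) // store_stride
    out = np.empty((n, n_stored))
    theta = theta0.copy()
    sin_p = np.empty(n)
    cos_p = np.empty(n)
    g1 = np.empty(n)
    g2 = np.empty(n)
    theta_pred = np.empty(n)
    out_col = 0
    for step in range(n_steps):
        if step >= n_transient_steps and (step - n_transient_steps) % store_stride == 0:
            for i in range(n):
                out[i, out_col] = theta[i] % TWO_PI
            out_col += 1
        cur = step % buf_len
        # stage 1: derivative at time t
        for i in range(n):
            si = sin_buf[cur, i]
            ci = cos_buf[cur, i]
            acc = 0.0
            for e in range(indptr[i], indptr[i + 1]):
                j = indices[e]
                slot = (step - dsteps[e]) % buf_len
                acc += cvals[e] * (sin_buf[slot, j] * ci - cos_buf[slot, j] * si)
            g1[i] = omega + k * acc
        for i in range(n):
            theta_pred[i] = theta[i] + dt * g1[i]
            sin_p[i] = np.sin(theta_pred[i])
            cos_p[i] = np.cos(theta_pred[i])
        # stage 2: derivative at time t + dt using predicted state
        for i in range(n):
            acc = 0.0
            for e in range(indptr[i], indptr[i + 1]):
                j = indices[e]
                d = dsteps[e]
                if d == 0:
                    sj = sin_p[j]
                    cj = cos_p[j]
                else:
                    slot = (step + 1 - d) % buf_len
                    sj = sin_buf[slot, j]
                    cj = cos_buf[slot, j]
                acc += cvals[e] * (sj * cos_p[i] - cj * sin_p[i])
            g2[i] = omega + k * acc
        nxt = (step + 1) % buf_len
        for i in range(n):
            theta[i] = theta[i] + 0.5 * dt * (g1[i] + g2[i])
            if theta[i] >= TWO_PI or theta[i] < 0.0:
                theta[i] = theta[i] % TWO_PI
            sin_buf[nxt, i] = np.sin(theta[i])
            cos_buf[nxt, i] = np.cos(theta[i])
    return out
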