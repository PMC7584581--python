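"""Numba kernel for the Balloon/Windkessel hemodynamic ODEs."""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def integrate_balloon(z, dt, kappa, gamma_f, tau_h, alpha, rho, v0, gain):
    """Heun integration of the four-state hemodynamic system per node.

    States: vasodilatory signal s, blood flow f, blood volume v,
    deoxyhemoglobin q; BOLD observation
    y = V0 (k1 (1 - q) + k2 (1 - q / v) + k3 (1 - v)).
    Input z is (n_nodes, n_t) at sampling interval dt (s).
    Returns (bold, ok_flag, bad_node, bad_t).
    """
    n, nt = z.shape
    k1 = 7.0 * rho
    k2 = 2.0
    k3 = 2.0 * rho - 0.2
    ialpha = 1.0 / alpha
    bold = np.empty((n, nt))
    for i in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(nt):
            bold[i, t] = v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v)
                               + k3 * (1.0 - v))
            zin = gain * z[i, t]
            # stage 1
            ds1 = zin - kappa * s - gamma_f * (f - 1.0)
            df1 = s
            fv1 = v ** ialpha
            dv1 = (f - fv1) / tau_h
            e1 = 1.0 - (1.0 - rho) ** (1.0 / f)
            dq1 = (f * e1 / rho - fv1 * q / v) / tau_h
            sp = s + dt * ds1
            fp = f + dt * df1
            vp = v + dt * dv1
            qp = q + dt * dq1
            zin2 = gain * (z[i, t + 1] if t + 1 < nt else z[i, t])
            # stage 2
            ds2 = zin2 - kappa * sp - gamma_f * (fp - 1.0)
            df2 = sp
            fv2 = vp ** ialpha
            dv2 = (fp - fv2) / tau_h
            e2 = 1.0 - (1.0 - rho) ** (1.0 / fp)
            dq2 = (fp * e2 / rho - fv2 * qp / vp) / tau_h
            s = s + 0.5 * dt * (ds1 + ds2)
            f = f + 0.5 * dt * (df1 + df2)
            v = v + 0.5 * dt * (dv1 + dv2)
            q = q + 0.5 * dt * (dq1 + dq2)
            if not (np.isfinite(s) and f > 0.0 and v > 0.0 and q > 0.0):
                return bold, False, i, t
    return bold, True, -1, -1
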