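"""Numba-compiled numeric kernels.

The 1-min forward-Euler integrator and the per-CGM-sample forecast cycle are
the hot loops of the package (parameter identification evaluates the forecast
cycle over a full training week hundreds of times), so they are compiled with
numba.  The pure-Python operations in :mod:`glucast.model`,
:mod:`glucast.deconvolution` and :mod:`glucast.forecaster` implement the same
arithmetic step by step; a regression test asserts both paths agree.

Parameter vector layout (see :mod:`glucast.params`):
``[SG, SI, Gb, V, Vi, W, ke, p2, Ag]``.
State vector layout: ``[G, X, S1, S2, I, Ra1, Ra]``.
Exogenous inputs are dense per-minute arrays: carbohydrate rate ``ucho``
(mg/min), insulin rate ``uins`` (mU/min), and the per-minute effective
``tmaxI`` / ``tmaxG`` (min) that encode meal-class shifts and, for the
virtual-patient truth, intra-day kinetic perturbations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import UU_PER_ML_PER_MU_PER_ML

_UU = UU_PER_ML_PER_MU_PER_ML


@njit(cache=True)
def step_into(x, p, ucho, uins, tmaxi, tmg, dt, out):
    """One forward-Euler step; negative states are clamped to zero."""
    g = x[0]
    xa = x[1]
    s1 = x[2]
    s2 = x[3]
    i = x[4]
    ra1 = x[5]
    ra = x[6]
    dg = -(p[0] + xa) * g + p[0] * p[2] + ra / (p[3] * p[5])
    dxa = -p[7] * xa + p[7] * p[1] * i
    ds1 = uins - s1 / tmaxi
    ds2 = (s1 - s2) / tmaxi
    di = -p[6] * i + _UU * s2 / (p[4] * p[5] * tmaxi)
    dra1 = -(ra1 - p[8] * ucho) / tmg
    dra = -(ra - ra1) / tmg
    out[0] = g + dt * dg
    out[1] = xa + dt * dxa
    out[2] = s1 + dt * ds1
    out[3] = s2 + dt * ds2
    out[4] = i + dt * di
    out[5] = ra1 + dt * dra1
    out[6] = ra + dt * dra
    for j in range(7):
        if out[j] < 0.0:
            out[j] = 0.0


@njit(cache=True)
def simulate_kernel(x0, p, ucho, uins, tmaxi, tmg, n_steps, dt):
    """Integrate ``n_steps`` 1-min Euler steps; returns (n_steps+1, 7)."""
    traj = np.empty((n_steps + 1, 7))
    x = x0.copy()
    traj[0] = x
    work = np.empty(7)
    for k in range(n_steps):
        step_into(x, p, ucho[k], uins[k], tmaxi[k], tmg[k], dt, work)
        x[:] = work
        traj[k + 1] = x
    return traj


@njit(cache=True)
def _slope3(t0, t1, t2, y0, y1, y2):
    """OLS slope of three (t, y) points."""
    tm = (t0 + t1 + t2) / 3.0
    ym = (y0 + y1 + y2) / 3.0
    num = (t0 - tm) * (y0 - ym) + (t1 - tm) * (y1 - ym) + (t2 - tm) * (y2 - ym)
    den = (t0 - tm) ** 2 + (t1 - tm) ** 2 + (t2 - tm) ** 2
    return num / den


@njit(cache=True)
def forecaster_kernel(g_cgm, t_cgm, p, tmaxg_base, ucho, uins, tmaxi, tmg,
                      ph, q1, q2, n_filter, announce):
    """Run the full per-sample forecast cycle over a CGM series.

    ``g_cgm``/``t_cgm`` are the (imputed, regular-grid) CGM values and their
    absolute times in minutes; the input arrays are indexed by absolute minute
    and must cover ``t_cgm[-1] + ph`` minutes.  Returns per-sample arrays:
    forecast glucose at ``t + ph`` (NaN before warm start), fused glucose,
    raw deconvolution estimate, filtered estimate (floored), first-compartment
    estimate, and the final model state.
    """
    n = g_cgm.shape[0]
    g_fore = np.full(n, np.nan)
    fused_g = np.full(n, np.nan)
    ra_hat = np.zeros(n)
    ra_tilde = np.zeros(n)
    ra1_tilde = np.zeros(n)
    filt_raw = np.zeros(n)  # unfloored filter recursion state

    x = np.zeros(7)
    x[0] = g_cgm[0]
    work = np.empty(7)
    xprop = np.empty(7)
    t_offset = t_cgm[0]

    for j in range(1, n):
        # (1) advance the model over the minutes since the previous sample
        m_j = int(round(t_cgm[j] - t_cgm[j - 1]))
        t_prev = int(round(t_cgm[j - 1] - t_offset))
        for s in range(m_j):
            t = t_prev + s
            step_into(x, p, ucho[t], uins[t], tmaxi[t], tmg[t], 1.0, work)
            x[:] = work

        # (2) deconvolution of the CGM signal
        if j >= 2:
            slope = _slope3(t_cgm[j - 2], t_cgm[j - 1], t_cgm[j],
                            g_cgm[j - 2], g_cgm[j - 1], g_cgm[j])
        else:
            slope = (g_cgm[j] - g_cgm[j - 1]) / (t_cgm[j] - t_cgm[j - 1])
        if slope > 1.0:
            slope = 1.0
        elif slope < -1.0:
            slope = -1.0
        rh = (slope + (p[0] + x[1]) * g_cgm[j] - p[0] * p[2]) * p[3] * p[5]
        ra_hat[j] = rh

        acc = rh
        for i in range(1, n_filter):
            if j - i >= 1:
                acc += filt_raw[j - i]
        fr = acc / n_filter
        filt_raw[j] = fr
        rt = fr if fr > 0.0 else 0.0
        ra_tilde[j] = rt

        if j >= 3:
            sl = _slope3(t_cgm[j - 2], t_cgm[j - 1], t_cgm[j],
                         ra_tilde[j - 2], ra_tilde[j - 1], ra_tilde[j])
        elif j == 2:
            sl = (ra_tilde[j] - ra_tilde[j - 1]) / (t_cgm[j] - t_cgm[j - 1])
        else:
            sl = 0.0
        r1 = sl * tmaxg_base + rt
        if r1 < 0.0:
            r1 = 0.0
        ra1_tilde[j] = r1

        # (3) weighted fusion of gut states and glucose
        x[6] = q1 * rt + (1.0 - q1) * x[6]
        x[5] = q1 * r1 + (1.0 - q1) * x[5]
        x[0] = q2 * g_cgm[j] + (1.0 - q2) * x[0]
        fused_g[j] = x[0]

        # (4) open-loop propagation over the prediction horizon
        if j >= 2:
            for c in range(7):
                xprop[c] = x[c]
            t_j = int(round(t_cgm[j] - t_offset))
            for s in range(ph):
                t = t_j + s
                uc = ucho[t] if announce else 0.0
                step_into(xprop, p, uc, uins[t], tmaxi[t], tmg[t], 1.0, work)
                xprop[:] = work
            g_fore[j] = xprop[0]

    return g_fore, fused_g, ra_hat, ra_tilde, ra1_tilde, x
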