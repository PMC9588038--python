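"""Compiled numerical core: tendency evaluation and the RK4 integrator.

The right-hand side is written once, in array form, and compiled with numba
for the long spin-up and scenario integrations.  The public wrappers in
:mod:`diazocomp.core` unpack the dataclasses into the flat arrays used here.

Parameter vector layout (see ``EcosystemParams._PACK_ORDER``)::

    0 J_O_max   1 C_d       2 k_N       3 k_P       4 k_P_d     5 T_min
    6 mu_max    7 theta_o   8 theta_d   9 theta_det 10 k_graze  11 r_NP
    12 m_P      13 a_Z      14 e_Z      15 m_Z      16 q_Z      17 remin_s
    18 remin_d  19 w_sink   20 m_deep   21 f_denit  22 k_denit  23 kh_s
    24 kh_d     25 clip_eps 26 holling  27 denit_enabled
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def rhs(y, p, area, temp, jio, kv, fe, dmask, hs, hd):
    """Tendencies for state ``y`` of shape (n_col, 2, 6).

    Returns ``(dy, fixation, denit, grazing)`` with fixation as a surface
    volumetric rate, denitrification as a deep volumetric rate (both
    mmol N m⁻³ d⁻¹) and grazing fluxes per prey, shape (n_col, 3).
    """
    n = y.shape[0]
    dy = np.zeros_like(y)

    # --- horizontal exchange: relaxation towards the layer mean ----------
    atot = area.sum()
    for layer in range(2):
        kh = p[23] if layer == 0 else p[24]
        if kh > 0.0:
            for tr in range(6):
                mean = (area * y[:, layer, tr]).sum() / atot
                dy[:, layer, tr] += kh * (mean - y[:, layer, tr])

    # --- vertical exchange ----------------------------------------------
    for tr in range(6):
        ex = kv * (y[:, 1, tr] - y[:, 0, tr])        # mmol m-2 d-1
        dy[:, 0, tr] += ex / hs
        dy[:, 1, tr] -= ex / hd

    # --- surface biology --------------------------------------------------
    N = np.maximum(y[:, 0, 0], 0.0)
    P = np.maximum(y[:, 0, 1], 0.0)
    Po = np.maximum(y[:, 0, 2], 0.0)
    Pd = np.maximum(y[:, 0, 3], 0.0)
    Zc = np.maximum(y[:, 0, 4], 0.0)
    Dt = np.maximum(y[:, 0, 5], 0.0)

    jo_max = p[0] * fe
    jd_max = p[1] * p[0] * fe
    lim_N = N / (p[2] + N)
    lim_P = P / (p[3] + P)
    lim_Pd = P / (p[4] + P)
    J_O = np.minimum(jio, np.minimum(jo_max * lim_N, jo_max * lim_P))
    J_D = np.where(temp >= p[5], np.minimum(jio, jd_max * lim_Pd), 0.0)

    growth_O = J_O * Po
    growth_D = J_D * Pd
    # diazotrophs draw ambient NO3 in proportion to its availability and fix
    # dinitrogen to cover the remaining Redfield demand
    nup_D = growth_D * lim_N
    fixation = growth_D - nup_D

    sat = np.ones(n)
    if p[26] > 0.0:
        sat = 1.0 + (p[7] * Po + p[8] * Pd + p[9] * Dt) / p[10]
    g_Po = p[6] * Zc * p[7] * Po / sat
    g_Pd = p[6] * Zc * p[8] * Pd / sat
    g_Dt = p[6] * Zc * p[9] * Dt / sat
    g_tot = g_Po + g_Pd + g_Dt

    excr = p[14] * g_tot
    z_growth = p[13] * g_tot
    egest = (1.0 - p[13] - p[14]) * g_tot
    z_loss = p[15] * Zc + p[16] * Zc * Zc
    sink = (p[19] / hs) * Dt
    remin_s = p[17] * Dt

    dy[:, 0, 2] += growth_O - g_Po - p[12] * Po
    dy[:, 0, 3] += growth_D - g_Pd - p[12] * Pd
    dy[:, 0, 4] += z_growth - z_loss
    dy[:, 0, 5] += (p[12] * (Po + Pd) + egest + z_loss
                    - g_Dt - remin_s - sink)
    dy[:, 0, 0] += -growth_O - nup_D + excr + remin_s
    dy[:, 0, 1] += (-growth_O - growth_D + excr + remin_s) / p[11]
    dy[:, 1, 5] += sink * hs / hd

    # --- deep box ----------------------------------------------------------
    Nd = np.maximum(y[:, 1, 0], 0.0)
    Dtd = np.maximum(y[:, 1, 5], 0.0)
    remin_d = p[18] * Dtd
    denit = p[27] * dmask * p[21] * remin_d * Nd / (Nd + p[22])
    dy[:, 1, 0] += remin_d - denit
    dy[:, 1, 1] += remin_d / p[11]
    dy[:, 1, 5] -= remin_d
    for tr in range(2, 5):
        living = np.maximum(y[:, 1, tr], 0.0)
        dy[:, 1, tr] -= p[20] * living
        dy[:, 1, 5] += p[20] * living

    grazing = np.empty((n, 3))
    grazing[:, 0] = g_Po
    grazing[:, 1] = g_Pd
    grazing[:, 2] = g_Dt
    return dy, fixation, denit, grazing


@njit(cache=True)
def integrate_kernel(y, p, area, temp, jio, kv, fe, dmask, hs, hd,
                     nyears, spy, dT, kv_scale):
    """Integrate ``nyears`` years with ``spy`` RK4 steps per 365-day year.

    ``dT`` and ``kv_scale`` have shape (nyears, n_col) and perturb the
    surface temperature / vertical exchange year by year (scenario forcing).

    Returns ``(y, traj, fix_ann, den_ann, clipped, status)`` where ``traj``
    holds annual-mean states, ``fix_ann``/``den_ann`` annual-mean volumetric
    fixation and denitrification per column, ``clipped`` the total clipped
    negative mass (mmol m⁻³, volume-weighted sum over boxes in units of
    mmol) and ``status`` is non-zero if a tracer went negative beyond the
    clipping tolerance.
    """
    n = y.shape[0]
    dt = 365.0 / spy
    traj = np.zeros((nyears, n, 2, 6))
    fix_ann = np.zeros((nyears, n))
    den_ann = np.zeros((nyears, n))
    clipped = 0.0
    eps = p[25]
    vol = np.empty((n, 2))
    vol[:, 0] = area * hs
    vol[:, 1] = area * hd

    for yr in range(nyears):
        temp_y = temp + dT[yr]
        kv_y = kv * kv_scale[yr]
        for _ in range(spy):
            k1, f1, d1, _g = rhs(y, p, area, temp_y, jio, kv_y, fe, dmask, hs, hd)
            k2, f2, d2, _g = rhs(y + 0.5 * dt * k1, p, area, temp_y, jio, kv_y, fe, dmask, hs, hd)
            k3, f3, d3, _g = rhs(y + 0.5 * dt * k2, p, area, temp_y, jio, kv_y, fe, dmask, hs, hd)
            k4, f4, d4, _g = rhs(y + dt * k3, p, area, temp_y, jio, kv_y, fe, dmask, hs, hd)
            traj[yr] += y / spy
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            fix_ann[yr] += (f1 + 2.0 * f2 + 2.0 * f3 + f4) / (6.0 * spy)
            den_ann[yr] += (d1 + 2.0 * d2 + 2.0 * d3 + d4) / (6.0 * spy)
            # clip small negative excursions, flag anything larger
            for i in range(n):
                for l in range(2):
                    for tr in range(6):
                        v = y[i, l, tr]
                        if v < 0.0:
                            if v < -eps:
                                return y, traj, fix_ann, den_ann, clipped, 1
                            clipped += -v * vol[i, l]
                            y[i, l, tr] = 0.0
    return y, traj, fix_ann, den_ann, clipped, 0
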