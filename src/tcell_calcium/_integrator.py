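"""Compiled adaptive Runge–Kutta core.

A Dormand–Prince 5(4) stepper with embedded error control, JIT-compiled
with numba, driving the 7-variable cell model.  Differential-evolution
fitting needs tens of thousands of protocol integrations, so the inner
loop must be cheap; output times are hit exactly by clamping the step
size (no interpolation error), and the integration is restarted at
every protocol segment boundary.

The parameter vector layout (plain float64) is produced by
``CompiledModel.as_vector`` in :mod:`tcell_calcium.cell_model`; the
Python right-hand side there is the readable reference implementation,
and the two are held equal by tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate_segments", "N_STATE", "STATUS_OK",
           "STATUS_FLOOR", "STATUS_UNDERFLOW"]

N_STATE = 7
STATUS_OK = 0
STATUS_FLOOR = 1
STATUS_UNDERFLOW = 2


@njit(cache=True, fastmath=False)
def _hill(x, k, n):
    if x <= 0.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(n * (np.log(k) - np.log(x))))


@njit(cache=True, fastmath=False)
def _rhs(t, y, pv, T, C_ext, sblk, pblk, cblk, floor, dy):
    C = y[0] if y[0] > floor else floor
    CER = y[1] if y[1] > floor else floor
    P = y[2]
    rho_crac = y[3]
    g_i = y[4]
    h_i = y[5]
    g_p = y[6]

    slope = pv[0]
    V0 = pv[1]

    # single-protein currents (A)
    if cblk:
        I_crac = 0.0
    else:
        vbar_c = slope * np.log(C_ext / C) - pv[2]
        I_crac = pv[12] * (V0 - vbar_c) * 1e-3
    if sblk:
        I_serca = 0.0
    else:
        I_serca = pv[34] * _hill(C, pv[35], pv[36])
    vbar_cer = slope * np.log(CER / C) - pv[3]
    I_ip3r = pv[18] * g_i * h_i * (-vbar_cer) * 1e-3
    if I_ip3r > 0.0:
        I_ip3r = 0.0
    I_pmca = 0.0 if pblk else pv[29] * g_p

    B_C = pv[8] * pv[9] / ((C + pv[9]) * (C + pv[9]))
    B_CER = pv[10] * pv[11] / ((CER + pv[11]) * (CER + pv[11]))

    er_exchange = pv[37] * I_serca + pv[28] * I_ip3r
    dy[0] = -(pv[4] * pv[33] * I_pmca + pv[4] * rho_crac * I_crac
              + pv[5] * er_exchange) * pv[7] / (1.0 + B_C)
    dy[1] = pv[6] * er_exchange * pv[7] / (1.0 + B_CER)
    dy[2] = pv[38] * _hill(C, pv[40], pv[41]) * T - pv[39] * P

    h_er = _hill(CER, pv[15], pv[16])
    rho_bar = pv[13] + (pv[14] - pv[13]) * (1.0 - h_er)
    dy[3] = (rho_bar - rho_crac) / pv[17]

    dy[4] = (pv[19] * _hill(C, pv[20], pv[21]) - g_i) / pv[26]
    C_inh = pv[23] * _hill(P, pv[25], pv[24])
    if C_inh <= 0.0:
        h_inf = 0.0
    else:
        h_inf = 1.0 / (1.0 + np.exp(pv[22] * (np.log(C) - np.log(C_inh))))
    dy[5] = (h_inf - h_i) / pv[27]

    dy[6] = (_hill(C, pv[30], pv[31]) - g_p) / pv[32]


# Dormand–Prince 5(4) tableau
_C2, _C3, _C4, _C5 = 0.2, 0.3, 0.8, 8.0 / 9.0
_A21 = 0.2
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (19372.0 / 6561.0, -25360.0 / 2187.0,
                          64448.0 / 6561.0, -212.0 / 729.0)
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0,
                                46732.0 / 5247.0, 49.0 / 176.0,
                                -5103.0 / 18656.0)
_B1, _B3, _B4, _B5, _B6 = (35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
                           -2187.0 / 6784.0, 11.0 / 84.0)
# 4th-order weights for the error estimate
_E1, _E3, _E4, _E5, _E6, _E7 = (35.0 / 384.0 - 5179.0 / 57600.0,
                                500.0 / 1113.0 - 7571.0 / 16695.0,
                                125.0 / 192.0 - 393.0 / 640.0,
                                -2187.0 / 6784.0 + 92097.0 / 339200.0,
                                11.0 / 84.0 - 187.0 / 2100.0,
                                -1.0 / 40.0)


@njit(cache=True, fastmath=False)
def integrate_segments(pv, seg_starts, seg_T, seg_Cext, seg_sblk, seg_pblk,
                       seg_cblk, t_end, out_times, y0, rtol, atol,
                       max_step, floor):
    """Integrate over all protocol segments, sampling at out_times.

    Returns ``(Y, status, t_stop)`` where Y is (n_out, 7); on failure
    the rows beyond the failure time are left as the last valid state.
    """
    n_out = out_times.shape[0]
    Y = np.empty((n_out, N_STATE))
    y = y0.copy()
    ynew = np.empty(N_STATE)
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    k5 = np.empty(N_STATE)
    k6 = np.empty(N_STATE)
    k7 = np.empty(N_STATE)
    ytmp = np.empty(N_STATE)

    i_out = 0
    n_seg = seg_starts.shape[0]
    for i_seg in range(n_seg):
        t = seg_starts[i_seg]
        t_stop = t_end if i_seg == n_seg - 1 else seg_starts[i_seg + 1]
        T = seg_T[i_seg]
        Cext = seg_Cext[i_seg]
        sb = seg_sblk[i_seg]
        pb = seg_pblk[i_seg]
        cb = seg_cblk[i_seg]

        # sample at the segment start (right-continuous state)
        while i_out < n_out and out_times[i_out] <= t:
            Y[i_out] = y
            i_out += 1

        h = 1e-3 if max_step > 1e-3 else max_step
        _rhs(t, y, pv, T, Cext, sb, pb, cb, floor, k1)  # FSAL seed
        while t < t_stop:
            # clamp the step to the next output time and the segment end
            h_lim = t_stop - t
            if i_out < n_out and out_times[i_out] - t < h_lim:
                h_lim = out_times[i_out] - t
            if h > h_lim:
                h_try = h_lim
            else:
                h_try = h
            if h_try < 1e-12:
                h_try = 1e-12

            for j in range(N_STATE):
                ytmp[j] = y[j] + h_try * _A21 * k1[j]
            _rhs(t + _C2 * h_try, ytmp, pv, T, Cext, sb, pb, cb, floor, k2)
            for j in range(N_STATE):
                ytmp[j] = y[j] + h_try * (_A31 * k1[j] + _A32 * k2[j])
            _rhs(t + _C3 * h_try, ytmp, pv, T, Cext, sb, pb, cb, floor, k3)
            for j in range(N_STATE):
                ytmp[j] = y[j] + h_try * (_A41 * k1[j] + _A42 * k2[j]
                                          + _A43 * k3[j])
            _rhs(t + _C4 * h_try, ytmp, pv, T, Cext, sb, pb, cb, floor, k4)
            for j in range(N_STATE):
                ytmp[j] = y[j] + h_try * (_A51 * k1[j] + _A52 * k2[j]
                                          + _A53 * k3[j] + _A54 * k4[j])
            _rhs(t + _C5 * h_try, ytmp, pv, T, Cext, sb, pb, cb, floor, k5)
            for j in range(N_STATE):
                ytmp[j] = y[j] + h_try * (_A61 * k1[j] + _A62 * k2[j]
                                          + _A63 * k3[j] + _A64 * k4[j]
                                          + _A65 * k5[j])
            _rhs(t + h_try, ytmp, pv, T, Cext, sb, pb, cb, floor, k6)
            for j in range(N_STATE):
                ynew[j] = y[j] + h_try * (_B1 * k1[j] + _B3 * k3[j]
                                          + _B4 * k4[j] + _B5 * k5[j]
                                          + _B6 * k6[j])
            _rhs(t + h_try, ynew, pv, T, Cext, sb, pb, cb, floor, k7)

            # scaled RMS error of the embedded 4th-order difference
            err = 0.0
            for j in range(N_STATE):
                e = h_try * (_E1 * k1[j] + _E3 * k3[j] + _E4 * k4[j]
                             + _E5 * k5[j] + _E6 * k6[j] + _E7 * k7[j])
                ya = abs(y[j])
                yb = abs(ynew[j])
                sc = atol + rtol * (ya if ya > yb else yb)
                r = e / sc
                err += r * r
            err = np.sqrt(err / N_STATE)

            if err <= 1.0:  # accept
                t = t + h_try
                for j in range(N_STATE):
                    y[j] = ynew[j]
                    k1[j] = k7[j]  # FSAL
                while i_out < n_out and out_times[i_out] <= t + 1e-12:
                    Y[i_out] = y
                    i_out += 1
                if y[0] <= floor or y[1] <= floor:
                    for i in range(i_out, n_out):
                        Y[i] = y
                    return Y, STATUS_FLOOR, t
                fac = 0.9 * err ** -0.2 if err > 0.0 else 5.0
                if fac > 5.0:
                    fac = 5.0
                h = h_try * fac
            else:  # reject
                fac = 0.9 * err ** -0.2
                if fac < 0.2:
                    fac = 0.2
                h = h_try * fac
                if h < 1e-12:
                    for i in range(i_out, n_out):
                        Y[i] = y
                    return Y, STATUS_UNDERFLOW, t
            if h > max_step:
                h = max_step

    while i_out < n_out:
        Y[i_out] = y
        i_out += 1
    return Y, STATUS_OK, t_end
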