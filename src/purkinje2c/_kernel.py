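"""Compiled fixed-step integration kernel for the two-compartment model.

One step (25 us default), in the source model's operational order:

1. gate and Markov updates at the old voltage (exponential relaxation for
   H-H gates, backward Euler for the 13-state Na scheme);
2. current evaluation with the fresh gates at the old voltage;
3. linearised-implicit voltage update: ohmic currents contribute frozen
   conductance/reversal pairs, non-ohmic terms (GHK Ca flux, pumps,
   exchangers) enter as frozen sources, and the two membrane equations plus
   the axial coupling are solved as a 2x2 linear system (backward-Euler-like,
   unconditionally stable at the conductances reached during spikes);
4. ion-pool updates (explicit Euler) and catch clamps;
5. reversal-potential refresh (E_Na from [Na]_i, dendritic E_K from [K]_o).

All state lives in flat float64 arrays indexed by the constants below so the
whole run stays inside one njit function.
"""

import math

import numpy as np

from ._compat import njit
from . import kinetics as K
from .constants import FARADAY, NA_OUT, RTF_MV

# --- parameter vector indices ----------------------------------------------
(
    P_G_NAR, P_G_KFAST, P_G_KMID, P_G_KSLOW, P_G_CAPS, P_G_BKS, P_G_SK,
    P_G_HS, P_G_LEAKS,
    P_G_CAT, P_G_CAE, P_G_CAPD, P_G_KA, P_G_KD, P_G_KM, P_G_DR, P_G_BKD,
    P_G_K2, P_G_KV12, P_G_HD, P_G_LEAKD, P_G_ERG,
    P_E_K_S, P_E_L_S, P_E_H_S, P_E_L_D, P_E_H_D, P_E_CA_D,
    P_D_PUMP_S, P_D_PUMP_D, P_GEX_S, P_GPUMP_S, P_GEX_D, P_GPUMP_D, P_K_NA,
    P_CM_S, P_CM_D, P_GA_S, P_GA_D, P_SOMA_DIAM,
    P_DEPTH_S, P_BETA_CA, P_CA_FLOOR, P_DEPTH_D, P_KT, P_KD, P_TAU_R,
    P_CA_REST,
    P_NA_FLOOR, P_E_NA_FLOOR,
    P_QK, P_WID, P_KO_MIN, P_KO_MAX,
    P_ALC_ON, P_ALC_Y, P_ALC_M, P_ALC_ONSET_S,
    P_K_IN_D,
    NPARAM,
) = range(60)

# --- state vector indices ---------------------------------------------------
(
    S_V_S, S_V_D,
    S_M_KFAST, S_H_KFAST, S_M_KMID, S_M_KSLOW, S_M_CAPS, S_M_HS,
    S_M_BKS, S_H_BKS, S_Z_BKS,
    S_MK0,  # 13 Markov occupancies occupy S_MK0 .. S_MK0+12
) = range(12)
S_M_CAT = S_MK0 + 13
(
    S_M_CAT_, S_H_CAT, S_M_CAE, S_H_CAE, S_M_CAPD, S_M_HD, S_M_KV12,
    S_M_KA, S_H_KA, S_M_KM, S_M_KD, S_H_KD, S_M_DR, S_M_BKD, S_Z_BKD,
    S_M_K2, S_Z_K2, S_M_ERG, S_H_ERG,
    S_CA_S, S_CA_D, S_NA_I, S_K_O, S_E_NA, S_E_K_D,
    NSTATE,
) = range(S_M_CAT, S_M_CAT + 26)

# --- recorded channels ------------------------------------------------------
(
    R_V_S, R_V_D, R_CA_S, R_CA_D, R_NA_I, R_K_O, R_O_NA, R_IPUMP_S,
    NREC,
) = range(9)

MARKOV_OPEN_IDX = S_MK0 + 5

STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(inline="always")
def _relax(x, inf, tau, dt):
    return x + (1.0 - math.exp(-dt / tau)) * (inf - x)


@njit
def run_kernel(P, S, hist, hist_state, n_steps, dt, stride, out):
    """Advance the model ``n_steps`` steps, recording every ``stride`` steps.

    ``hist`` is the Na-lag ring buffer (tau/dt samples, pre-filled with 0);
    ``hist_state[0]`` its write position. ``out`` has shape
    (n_steps//stride + 1, NREC); row 0 is the initial state. Returns
    (status, step_of_failure): a non-finite voltage aborts the run.
    """
    scr_a = np.empty((13, 13))
    scr_m = np.empty((13, 14))

    f_const = FARADAY
    rtf = RTF_MV

    # initial record
    pos = hist_state[0]
    i_pump_s0, _, _ = _soma_pump(S[S_V_S], S[S_NA_I], P[P_D_PUMP_S], P[P_K_NA])
    _record(out, 0, S, i_pump_s0)

    rec_row = 1
    for k in range(n_steps):
        t_ms = k * dt

        # ---- protocol: alcohol ramp of the four pump densities ----
        d_pump_s = P[P_D_PUMP_S]
        d_pump_d = P[P_D_PUMP_D]
        g_pump_s = P[P_GPUMP_S]
        g_pump_d = P[P_GPUMP_D]
        if P[P_ALC_ON] != 0.0:
            t_s = t_ms * 1e-3
            d_pump_s = max(0.0, d_pump_s - P[P_ALC_Y] * t_s)
            if t_s > P[P_ALC_ONSET_S]:
                t_late = t_s - P[P_ALC_ONSET_S]
                d_pump_d = max(0.0, d_pump_d - P[P_ALC_M] * t_late)
                g_pump_s = max(0.0, g_pump_s - P[P_ALC_M] * t_late)
                g_pump_d = max(0.0, g_pump_d - P[P_ALC_M] * t_late)

        v_s = S[S_V_S]
        v_d = S[S_V_D]
        ca_s = S[S_CA_S]
        ca_d = S[S_CA_D]

        # ---- 1. gate updates at old V, old Ca ----
        inf, tau = K.soma_kfast_m(v_s)
        S[S_M_KFAST] = _relax(S[S_M_KFAST], inf, tau, dt)
        inf, tau = K.soma_kfast_h(v_s)
        S[S_H_KFAST] = _relax(S[S_H_KFAST], inf, tau, dt)
        inf, tau = K.soma_kmid_m(v_s)
        S[S_M_KMID] = _relax(S[S_M_KMID], inf, tau, dt)
        inf, tau = K.soma_kslow_m(v_s)
        S[S_M_KSLOW] = _relax(S[S_M_KSLOW], inf, tau, dt)
        inf, tau = K.soma_cap_m(v_s)
        S[S_M_CAPS] = _relax(S[S_M_CAPS], inf, tau, dt)
        inf, tau = K.soma_h_m(v_s)
        S[S_M_HS] = _relax(S[S_M_HS], inf, tau, dt)
        inf, tau = K.soma_bk_m(v_s)
        S[S_M_BKS] = _relax(S[S_M_BKS], inf, tau, dt)
        inf, tau = K.soma_bk_h(v_s)
        S[S_H_BKS] = _relax(S[S_H_BKS], inf, tau, dt)
        inf, tau = K.soma_bk_z(ca_s)
        S[S_Z_BKS] = _relax(S[S_Z_BKS], inf, tau, dt)

        occ = S[S_MK0:S_MK0 + 13]
        K.markov_backward_euler(occ, v_s, dt, scr_a, scr_m)

        inf, tau = K.dend_cat_m(v_d)
        S[S_M_CAT] = _relax(S[S_M_CAT], inf, tau, dt)
        inf, tau = K.dend_cat_h(v_d)
        S[S_H_CAT] = _relax(S[S_H_CAT], inf, tau, dt)
        inf, tau = K.dend_cae_m(v_d)
        S[S_M_CAE] = _relax(S[S_M_CAE], inf, tau, dt)
        inf, tau = K.dend_cae_h(v_d)
        S[S_H_CAE] = _relax(S[S_H_CAE], inf, tau, dt)
        inf, tau = K.dend_cap_m(v_d)
        S[S_M_CAPD] = _relax(S[S_M_CAPD], inf, tau, dt)
        inf, tau = K.dend_h_m(v_d)
        S[S_M_HD] = _relax(S[S_M_HD], inf, tau, dt)
        inf, tau = K.dend_kv12_m(v_d)
        S[S_M_KV12] = _relax(S[S_M_KV12], inf, tau, dt)
        inf, tau = K.dend_ka_m(v_d)
        S[S_M_KA] = _relax(S[S_M_KA], inf, tau, dt)
        inf, tau = K.dend_ka_h(v_d)
        S[S_H_KA] = _relax(S[S_H_KA], inf, tau, dt)
        inf, tau = K.dend_km_m(v_d)
        S[S_M_KM] = _relax(S[S_M_KM], inf, tau, dt)
        inf, tau = K.dend_kd_m(v_d)
        S[S_M_KD] = _relax(S[S_M_KD], inf, tau, dt)
        inf, tau = K.dend_kd_h(v_d)
        S[S_H_KD] = _relax(S[S_H_KD], inf, tau, dt)
        inf, tau = K.dend_dr_m(v_d)
        S[S_M_DR] = _relax(S[S_M_DR], inf, tau, dt)
        inf, tau = K.dend_bk_m(v_d)
        S[S_M_BKD] = _relax(S[S_M_BKD], inf, tau, dt)
        inf, tau = K.dend_bk_z(ca_d)
        S[S_Z_BKD] = _relax(S[S_Z_BKD], inf, tau, dt)
        inf, tau = K.dend_k2_m(v_d)
        S[S_M_K2] = _relax(S[S_M_K2], inf, tau, dt)
        inf, tau = K.dend_k2_z(ca_d)
        S[S_Z_K2] = _relax(S[S_Z_K2], inf, tau, dt)
        if P[P_G_ERG] > 0.0:
            inf, tau = K.erg_m(v_d)
            S[S_M_ERG] = _relax(S[S_M_ERG], inf, tau, dt)
            inf, tau = K.erg_h(v_d)
            S[S_H_ERG] = _relax(S[S_H_ERG], inf, tau, dt)

        # ---- 2. currents (new gates, old V) ----
        # soma: accumulate ohmic conductance and conductance-weighted reversal
        e_k_s = P[P_E_K_S]
        e_na = S[S_E_NA]
        g_sum_s = 0.0
        ge_sum_s = 0.0

        g = P[P_G_KFAST] * S[S_M_KFAST] ** 3 * S[S_H_KFAST]
        g_sum_s += g
        ge_sum_s += g * e_k_s
        g = P[P_G_KMID] * S[S_M_KMID] ** 4
        g_sum_s += g
        ge_sum_s += g * e_k_s
        g = P[P_G_KSLOW] * S[S_M_KSLOW] ** 4
        g_sum_s += g
        ge_sum_s += g * e_k_s
        g = P[P_G_BKS] * S[S_M_BKS] ** 3 * S[S_Z_BKS] ** 2 * S[S_H_BKS]
        g_sum_s += g
        ge_sum_s += g * e_k_s
        z_sk = K.soma_sk_z(ca_s)
        g = P[P_G_SK] * z_sk
        g_sum_s += g
        ge_sum_s += g * e_k_s
        g = P[P_G_HS] * S[S_M_HS]
        g_sum_s += g
        ge_sum_s += g * P[P_E_H_S]
        g = P[P_G_LEAKS]
        g_sum_s += g
        ge_sum_s += g * P[P_E_L_S]
        g_nar = P[P_G_NAR] * S[MARKOV_OPEN_IDX]
        g_sum_s += g_nar
        ge_sum_s += g_nar * e_na
        i_nar = g_nar * (v_s - e_na)

        i_caps = P[P_G_CAPS] * S[S_M_CAPS] * K.ghk_flux(v_s)
        i_pump_s, i_pump_s_na, i_pump_s_k = _soma_pump(
            v_s, S[S_NA_I], d_pump_s, P[P_K_NA]
        )
        i0_s = i_caps + i_pump_s + 1000.0 * (g_pump_s - P[P_GEX_S])

        # dendrite
        e_k_d = S[S_E_K_D]
        e_ca = P[P_E_CA_D]
        g_sum_d = 0.0
        ge_sum_d = 0.0

        g_cat = P[P_G_CAT] * S[S_M_CAT] * S[S_H_CAT]
        g_sum_d += g_cat
        ge_sum_d += g_cat * e_ca
        g_cae = P[P_G_CAE] * S[S_M_CAE] * S[S_H_CAE]
        g_sum_d += g_cae
        ge_sum_d += g_cae * e_ca
        g_capd = P[P_G_CAPD] * S[S_M_CAPD]
        g_sum_d += g_capd
        ge_sum_d += g_capd * e_ca
        i_ca_d = (g_cat + g_cae + g_capd) * (v_d - e_ca)

        g = P[P_G_HD] * S[S_M_HD]
        g_sum_d += g
        ge_sum_d += g * P[P_E_H_D]
        g = P[P_G_LEAKD]
        g_sum_d += g
        ge_sum_d += g * P[P_E_L_D]

        g_ka = P[P_G_KA] * S[S_M_KA] ** 4 * S[S_H_KA]
        g_kd = P[P_G_KD] * S[S_M_KD] * S[S_H_KD]
        g_km = P[P_G_KM] * S[S_M_KM]
        g_dr = P[P_G_DR] * S[S_M_DR] ** 4
        g_bkd = P[P_G_BKD] * S[S_M_BKD] * S[S_Z_BKD] ** 2
        g_k2 = P[P_G_K2] * S[S_M_K2] * S[S_Z_K2] ** 2
        g_kv = P[P_G_KV12] * S[S_M_KV12] ** 4
        g_k_all = g_ka + g_kd + g_km + g_dr + g_bkd + g_k2 + g_kv
        g_sum_d += g_k_all
        ge_sum_d += g_k_all * e_k_d
        i_k_gated = g_k_all * (v_d - e_k_d)

        if P[P_G_ERG] > 0.0:
            g_erg = P[P_G_ERG] * S[S_M_ERG] * S[S_H_ERG]
            g_sum_d += g_erg
            ge_sum_d += g_erg * e_k_d

        i_pump_d, i_pump_d_na, i_pump_d_k = _dend_pump(S[S_K_O], d_pump_d)
        i0_d = i_pump_d + 1000.0 * (g_pump_d - P[P_GEX_D])

        # ---- 3. implicit 2x2 voltage update ----
        a11 = P[P_CM_S] / dt + g_sum_s + P[P_GA_S]
        a12 = -P[P_GA_S]
        b1 = P[P_CM_S] / dt * v_s + ge_sum_s - i0_s
        a21 = -P[P_GA_D]
        a22 = P[P_CM_D] / dt + g_sum_d + P[P_GA_D]
        b2 = P[P_CM_D] / dt * v_d + ge_sum_d - i0_d
        det = a11 * a22 - a12 * a21
        v_s_new = (b1 * a22 - a12 * b2) / det
        v_d_new = (a11 * b2 - a21 * b1) / det

        # ---- 4. ion pools (explicit Euler at old V) + clamps ----
        ca_s_new = ca_s + dt * (
            10.0 * (-i_caps) / (2.0 * f_const * P[P_DEPTH_S])
            - P[P_BETA_CA] * ca_s
        )
        if ca_s_new < P[P_CA_FLOOR]:
            ca_s_new = P[P_CA_FLOOR]
        S[S_CA_S] = ca_s_new

        chan = 10.0 * (-i_ca_d) / (2.0 * f_const * P[P_DEPTH_D])
        if chan < 0.0:
            chan = 0.0
        S[S_CA_D] = ca_d + dt * (
            chan
            - P[P_KT] * ca_d / (ca_d + P[P_KD])
            + (P[P_CA_REST] - ca_d) / P[P_TAU_R]
        )

        # Na book (soma): influx positive raises [Na]_i
        influx = (
            -i_nar
            + 3.0 * 1000.0 * P[P_GEX_S]
            - 3.0 * i_pump_s
            - 3.0 * 1000.0 * g_pump_s
        )
        pos = hist_state[0]
        lagged = hist[pos]
        hist[pos] = influx
        hist_state[0] = (pos + 1) % hist.shape[0]
        na = S[S_NA_I] + dt * 40.0 * lagged / (P[P_SOMA_DIAM] * f_const)
        if na < P[P_NA_FLOOR]:
            na = P[P_NA_FLOOR]
        S[S_NA_I] = na

        # K book (dendrite)
        i_k_in = 2.0 * (i_pump_d + 1000.0 * g_pump_d)
        ko = S[S_K_O] + dt * P[P_QK] * (i_k_gated - i_k_in) / (
            f_const * P[P_WID]
        )
        if ko > P[P_KO_MAX]:
            ko = P[P_KO_MAX]
        elif ko < P[P_KO_MIN]:
            ko = P[P_KO_MIN]
        S[S_K_O] = ko

        # ---- 5. reversal refresh ----
        e_na_new = rtf * math.log(NA_OUT / na)
        if e_na_new < P[P_E_NA_FLOOR]:
            e_na_new = P[P_E_NA_FLOOR]
        S[S_E_NA] = e_na_new
        S[S_E_K_D] = rtf * math.log(ko / P[P_K_IN_D])

        S[S_V_S] = v_s_new
        S[S_V_D] = v_d_new

        if not (math.isfinite(v_s_new) and math.isfinite(v_d_new)):
            return STATUS_NONFINITE, k

        if (k + 1) % stride == 0:
            _record(out, rec_row, S, i_pump_s)
            rec_row += 1

    return STATUS_OK, n_steps


@njit(inline="always")
def _soma_pump(v, na_i, d_pump, k_na):
    v80 = v + 80.0
    if -0.01 < v80 < 0.01:
        v80 = 0.01 if v80 >= 0.0 else -0.01
    x = k_na - na_i
    if x > 500.0:
        x = 500.0
    gate = 1.0 + math.exp(x)
    i = 1000.0 * d_pump * (v + 75.0) / (v80 * gate)
    return i, 3.0 * i, -2.0 * i


@njit(inline="always")
def _dend_pump(k_o, d_pump):
    i = 1000.0 * d_pump / (1.0 + 2.245 / k_o)
    return i, 3.0 * i, -2.0 * i


@njit(inline="always")
def _record(out, row, S, i_pump_s):
    out[row, R_V_S] = S[S_V_S]
    out[row, R_V_D] = S[S_V_D]
    out[row, R_CA_S] = S[S_CA_S]
    out[row, R_CA_D] = S[S_CA_D]
    out[row, R_NA_I] = S[S_NA_I]
    out[row, R_K_O] = S[S_K_O]
    out[row, R_O_NA] = S[MARKOV_OPEN_IDX]
    out[row, R_IPUMP_S] = i_pump_s
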