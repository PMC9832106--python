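"""Numba kernel for the closed-loop 0D circulation.

State vector (volumes, mL):
  0 RA, 1 RV, 2 pulmonary arteries, 3 pulmonary veins, 4 LA, 5 LV,
  6 systemic arteries, 7 portal venous compartment, 8 right liver lobe,
  9 left liver lobe, 10 vena cava.

All chamber pressures follow a time-varying elastance law
P = (Eb + Ea*e(t)) * (V - V0) with a piecewise-cosine activation e(t);
vascular compartments are linear, P = (V - V0)/C.  Valves are ideal
diodes smoothed with a soft-plus law so the vector field stays C^1 and a
fixed-step RK4 integration is exact to reproduce bit-for-bit.
"""

import numpy as np
from numba import njit

# indices into the packed constants vector
_NC = 45
(
    I_T, I_TS, I_TAS,
    I_EA_RA, I_EB_RA, I_EA_RV, I_EB_RV, I_EA_LA, I_EB_LA, I_EA_LV, I_EB_LV,
    I_V0_RA, I_V0_RV, I_V0_LA, I_V0_LV,
    I_C_SA, I_C_PA, I_C_PU, I_C_PVN, I_C_LR, I_C_LL, I_C_VC,
    I_V0_SA, I_V0_PA, I_V0_PU, I_V0_PVN, I_V0_LR, I_V0_LL, I_V0_VC,
    I_R_VALVE, I_EPS, I_R_PUL, I_R_PU_LA, I_R_VC_RA,
    I_G_OO, I_G_DO,
    I_G_HA_R, I_G_HA_L, I_G_PV_R, I_G_PV_L, I_G_HV_R, I_G_HV_L,
    I_KD, I_VD, I_VK,
) = range(_NC)

N_STATE = 11
N_FLOW = 15

FLOW_NAMES = (
    "tricuspid", "pulmonary_valve", "pulmonary", "pulm_vein_la", "mitral",
    "aortic", "other_organs", "digestive", "ha_right", "ha_left",
    "pv_right", "pv_left", "hv_right", "hv_left", "vc_ra",
)
PRESSURE_NAMES = ("RA", "RV", "PA", "PU", "LA", "LV", "SA", "PVN", "LR", "LL", "VC")
VOLUME_NAMES = PRESSURE_NAMES

# per-cycle observables: P_pv, P_vc, MAP, CO, Q_ha, Q_pv  (flows in mL/s)
N_OBS = 6


@njit(cache=True, fastmath=False)
def _activation(t, T, dur, delay):
    """Piecewise-cosine activation in [0, 1], active on [delay, delay+dur)."""
    tt = t % T
    x = tt - delay
    if x < 0.0 or x >= dur:
        return 0.0
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * x / dur))


@njit(cache=True, fastmath=False)
def _pressures(t, y, c, P):
    T = c[I_T]
    ev = _activation(t, T, c[I_TS], 0.0)
    ea = _activation(t, T, c[I_TAS], T - c[I_TAS])
    P[0] = (c[I_EB_RA] + c[I_EA_RA] * ea) * (y[0] - c[I_V0_RA])
    kd, vd, vk = c[I_KD], c[I_VD], c[I_VK]
    P[1] = (c[I_EB_RV] + c[I_EA_RV] * ev) * (y[1] - c[I_V0_RV]) \
        + kd * np.expm1((y[1] - c[I_V0_RV] - vk) / vd)
    P[2] = (y[2] - c[I_V0_PA]) / c[I_C_PA]
    P[3] = (y[3] - c[I_V0_PU]) / c[I_C_PU]
    P[4] = (c[I_EB_LA] + c[I_EA_LA] * ea) * (y[4] - c[I_V0_LA])
    P[5] = (c[I_EB_LV] + c[I_EA_LV] * ev) * (y[5] - c[I_V0_LV]) \
        + kd * np.expm1((y[5] - c[I_V0_LV] - vk) / vd)
    P[6] = (y[6] - c[I_V0_SA]) / c[I_C_SA]
    P[7] = (y[7] - c[I_V0_PVN]) / c[I_C_PVN]
    P[8] = (y[8] - c[I_V0_LR]) / c[I_C_LR]
    P[9] = (y[9] - c[I_V0_LL]) / c[I_C_LL]
    P[10] = (y[10] - c[I_V0_VC]) / c[I_C_VC]


@njit(cache=True, fastmath=False)
def _valve(dp, g, eps):
    return g * 0.5 * (dp + np.sqrt(dp * dp + eps * eps))


@njit(cache=True, fastmath=False)
def _flows(P, c, Q):
    gv = 1.0 / c[I_R_VALVE]
    eps = c[I_EPS]
    Q[0] = _valve(P[0] - P[1], gv, eps)          # tricuspid
    Q[1] = _valve(P[1] - P[2], gv, eps)          # pulmonary valve
    Q[2] = (P[2] - P[3]) / c[I_R_PUL]            # pulmonary bed
    Q[3] = (P[3] - P[4]) / c[I_R_PU_LA]          # pulmonary veins -> LA
    Q[4] = _valve(P[4] - P[5], gv, eps)          # mitral
    Q[5] = _valve(P[5] - P[6], gv, eps)          # aortic
    Q[6] = (P[6] - P[10]) * c[I_G_OO]            # other organs
    Q[7] = (P[6] - P[7]) * c[I_G_DO]             # digestive organs
    Q[8] = (P[6] - P[8]) * c[I_G_HA_R]           # hepatic artery, right lobe
    Q[9] = (P[6] - P[9]) * c[I_G_HA_L]           # hepatic artery, left lobe
    Q[10] = (P[7] - P[8]) * c[I_G_PV_R]          # portal vein, right lobe
    Q[11] = (P[7] - P[9]) * c[I_G_PV_L]          # portal vein, left lobe
    Q[12] = (P[8] - P[10]) * c[I_G_HV_R]         # hepatic vein, right lobe
    Q[13] = (P[9] - P[10]) * c[I_G_HV_L]         # hepatic vein, left lobe
    Q[14] = (P[10] - P[0]) / c[I_R_VC_RA]        # vena cava -> RA


@njit(cache=True, fastmath=False)
def _rhs(t, y, c, P, Q, dy):
    _pressures(t, y, c, P)
    _flows(P, c, Q)
    dy[0] = Q[14] - Q[0]
    dy[1] = Q[0] - Q[1]
    dy[2] = Q[1] - Q[2]
    dy[3] = Q[2] - Q[3]
    dy[4] = Q[3] - Q[4]
    dy[5] = Q[4] - Q[5]
    dy[6] = Q[5] - Q[6] - Q[7] - Q[8] - Q[9]
    dy[7] = Q[7] - Q[10] - Q[11]
    dy[8] = Q[8] + Q[10] - Q[12]
    dy[9] = Q[9] + Q[11] - Q[13]
    dy[10] = Q[6] + Q[12] + Q[13] - Q[14]


@njit(cache=True, fastmath=False)
def simulate_kernel(c, y0, steps, max_cycles, rtol):
    """Integrate cycle by cycle until every cycle-averaged observable is
    periodic to ``rtol``; then resolve one further cycle for the trace.

    Returns (trace_t, trace_V, trace_P, trace_Q, obs, y_end, n_cycles,
    residual, status) with status 0 = converged, 1 = cycle budget
    exhausted, 2 = non-finite state.
    """
    T = c[I_T]
    dt = T / steps
    y = y0.copy()
    P = np.empty(N_STATE)
    Q = np.empty(N_FLOW)
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    yt = np.empty(N_STATE)

    obs_prev = np.zeros(N_OBS)
    obs = np.zeros(N_OBS)
    residual = np.inf
    status = 1
    n_cycles = 0

    for cycle in range(max_cycles):
        for i in range(N_OBS):
            obs[i] = 0.0
        for s in range(steps):
            t = s * dt
            _rhs(t, y, c, P, Q, k1)
            # accumulate observables at the step start (rectangle rule on a
            # periodic signal)
            obs[0] += P[7]
            obs[1] += P[10]
            obs[2] += P[6]
            obs[3] += Q[5]
            obs[4] += Q[8] + Q[9]
            obs[5] += Q[10] + Q[11]
            for i in range(N_STATE):
                yt[i] = y[i] + 0.5 * dt * k1[i]
            _rhs(t + 0.5 * dt, yt, c, P, Q, k2)
            for i in range(N_STATE):
                yt[i] = y[i] + 0.5 * dt * k2[i]
            _rhs(t + 0.5 * dt, yt, c, P, Q, k3)
            for i in range(N_STATE):
                yt[i] = y[i] + dt * k3[i]
            _rhs(t + dt, yt, c, P, Q, k4)
            for i in range(N_STATE):
                y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        n_cycles = cycle + 1
        finite = True
        for i in range(N_STATE):
            if not np.isfinite(y[i]):
                finite = False
        if not finite:
            status = 2
            break
        for i in range(N_OBS):
            obs[i] /= steps
        if cycle > 0:
            residual = 0.0
            for i in range(N_OBS):
                scale = abs(obs_prev[i])
                if scale < 0.1:
                    scale = 0.1
                r = abs(obs[i] - obs_prev[i]) / scale
                if r > residual:
                    residual = r
            if residual < rtol:
                status = 0
        for i in range(N_OBS):
            obs_prev[i] = obs[i]
        if status == 0:
            break

    # resolve the reported cycle
    trace_t = np.empty(steps + 1)
    trace_V = np.empty((steps + 1, N_STATE))
    trace_P = np.empty((steps + 1, N_STATE))
    trace_Q = np.empty((steps + 1, N_FLOW))
    if status == 2:
        trace_t[:] = np.nan
        trace_V[:] = np.nan
        trace_P[:] = np.nan
        trace_Q[:] = np.nan
        return trace_t, trace_V, trace_P, trace_Q, obs, y, n_cycles, residual, status

    for i in range(N_OBS):
        obs[i] = 0.0
    for s in range(steps):
        t = s * dt
        _rhs(t, y, c, P, Q, k1)
        trace_t[s] = t
        for i in range(N_STATE):
            trace_V[s, i] = y[i]
            trace_P[s, i] = P[i]
        for i in range(N_FLOW):
            trace_Q[s, i] = Q[i]
        obs[0] += P[7]
        obs[1] += P[10]
        obs[2] += P[6]
        obs[3] += Q[5]
        obs[4] += Q[8] + Q[9]
        obs[5] += Q[10] + Q[11]
        for i in range(N_STATE):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        _rhs(t + 0.5 * dt, yt, c, P, Q, k2)
        for i in range(N_STATE):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        _rhs(t + 0.5 * dt, yt, c, P, Q, k3)
        for i in range(N_STATE):
            yt[i] = y[i] + dt * k3[i]
        _rhs(t + dt, yt, c, P, Q, k4)
        for i in range(N_STATE):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
    for i in range(N_OBS):
        obs[i] /= steps
    t = steps * dt
    _rhs(t, y, c, P, Q, k1)
    trace_t[steps] = t
    for i in range(N_STATE):
        trace_V[steps, i] = y[i]
        trace_P[steps, i] = P[i]
    for i in range(N_FLOW):
        trace_Q[steps, i] = Q[i]
    n_cycles += 1
    return trace_t, trace_V, trace_P, trace_Q, obs, y, n_cycles, residual, status
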