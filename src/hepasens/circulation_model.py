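"""Closed-loop 0D cardiovascular model with a hepatic sub-circuit.

The circulation is a single closed loop: right heart -> pulmonary bed ->
left heart -> systemic arteries, which split into an "other organs"
branch, a digestive branch feeding the portal vein, and a hepatic
arterial branch; both hepatic inflows perfuse two liver lobes in
parallel that drain through the hepatic veins into the vena cava and
back to the right atrium.  A virtual hepatectomy removes liver mass from
the right lobe first and rescales each lobe's intrahepatic resistances
inversely with its remaining mass fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from ._core import simulate_kernel
from .params import (
    CirculationTrace,
    ConvergenceError,
    CycleOutputs,
    IntegrationError,
    ModelConfig,
    ParameterVector,
)

MLS_TO_LMIN = 60.0 / 1000.0


@dataclass(frozen=True)
class LobarResistances:
    """Per-lobe hydraulic resistances of the hepatic circuit.

    ``np.inf`` marks a branch whose lobe has been fully resected.
    """

    R_pv_right: float
    R_pv_left: float
    R_ha_right: float
    R_ha_left: float
    R_hv_right: float
    R_hv_left: float
    right_mass: float   # remaining mass as fraction of the original total
    left_mass: float

    def whole_liver(self) -> tuple[float, float, float]:
        """Parallel-equivalent whole-liver (R_pv, R_ha, R_hv)."""

        def par(r1, r2):
            g = (0.0 if np.isinf(r1) else 1.0 / r1) + (0.0 if np.isinf(r2) else 1.0 / r2)
            return np.inf if g == 0.0 else 1.0 / g

        return (
            par(self.R_pv_right, self.R_pv_left),
            par(self.R_ha_right, self.R_ha_left),
            par(self.R_hv_right, self.R_hv_left),
        )


def baseline_lobar(params: ParameterVector, config: ModelConfig) -> LobarResistances:
    """Distribute the whole-liver resistances over the two lobes.

    Each lobe of mass fraction m carries resistance R/m so that the
    parallel combination recovers the whole-liver value.
    """
    mr, ml = config.right_lobe_fraction, config.left_lobe_fraction
    return LobarResistances(
        R_pv_right=params.R_pv / mr, R_pv_left=params.R_pv / ml,
        R_ha_right=params.R_ha / mr, R_ha_left=params.R_ha / ml,
        R_hv_right=params.R_hv / mr, R_hv_left=params.R_hv / ml,
        right_mass=mr, left_mass=ml,
    )


def apply_hepatectomy(params: ParameterVector, config: ModelConfig) -> LobarResistances:
    """Lobar resistances after resecting the fraction ``params.hpx`` of
    total liver mass, right lobe first.

    A lobe reduced to fraction r of the original total mass sees each of
    its resistances scaled by (original lobe fraction)/r, i.e. inversely
    with remaining mass; a fully resected lobe is an open circuit.
    """
    hpx = params.hpx
    if not (0.0 <= hpx < 1.0):
        raise ValueError(f"hpx must lie in [0, 1), got {hpx}")
    mr, ml = config.right_lobe_fraction, config.left_lobe_fraction
    right_rem = max(mr - hpx, 0.0)
    left_rem = ml - max(hpx - mr, 0.0)
    base = baseline_lobar(params, config)

    def scaled(r_base: float, m0: float, rem: float) -> float:
        if rem <= 0.0:
            return np.inf
        return r_base * (m0 / rem)

    return LobarResistances(
        R_pv_right=scaled(base.R_pv_right, mr, right_rem),
        R_pv_left=scaled(base.R_pv_left, ml, left_rem),
        R_ha_right=scaled(base.R_ha_right, mr, right_rem),
        R_ha_left=scaled(base.R_ha_left, ml, left_rem),
        R_hv_right=scaled(base.R_hv_right, mr, right_rem),
        R_hv_left=scaled(base.R_hv_left, ml, left_rem),
        right_mass=right_rem, left_mass=left_rem,
    )


def _pack_constants(params: ParameterVector, config: ModelConfig,
                    lobar: LobarResistances) -> np.ndarray:
    c = np.zeros(_core._NC)
    mr, ml = config.right_lobe_fraction, config.left_lobe_fraction
    c[_core.I_T] = config.period_s
    c[_core.I_TS] = config.systole_s
    c[_core.I_TAS] = config.atrial_systole_s
    c[_core.I_EA_RA] = params.Ea_RA
    c[_core.I_EB_RA] = params.Eb_RA
    c[_core.I_EA_RV] = config.Ea_RV
    c[_core.I_EB_RV] = config.Eb_RV
    c[_core.I_EA_LA] = config.Ea_LA
    c[_core.I_EB_LA] = config.Eb_LA
    c[_core.I_EA_LV] = params.Ea_LV
    c[_core.I_EB_LV] = params.Eb_LV
    c[_core.I_V0_RA] = config.V0_RA
    c[_core.I_V0_RV] = config.V0_RV
    c[_core.I_V0_LA] = config.V0_LA
    c[_core.I_V0_LV] = config.V0_LV
    c[_core.I_C_SA] = config.C_sa
    c[_core.I_C_PA] = config.C_pa
    c[_core.I_C_PU] = config.C_pu
    c[_core.I_C_PVN] = config.C_pvn
    c[_core.I_C_LR] = config.C_liver * mr
    c[_core.I_C_LL] = config.C_liver * ml
    c[_core.I_C_VC] = config.C_vc
    c[_core.I_V0_SA] = config.V0_sa
    c[_core.I_V0_PA] = config.V0_pa
    c[_core.I_V0_PU] = config.V0_pu
    c[_core.I_V0_PVN] = config.V0_pvn
    c[_core.I_V0_LR] = config.V0_liver * mr
    c[_core.I_V0_LL] = config.V0_liver * ml
    c[_core.I_V0_VC] = config.V0_vc
    c[_core.I_R_VALVE] = config.R_valve
    c[_core.I_EPS] = config.valve_smoothing_mmHg
    c[_core.I_R_PUL] = config.R_pul
    c[_core.I_R_PU_LA] = config.R_pu_la
    c[_core.I_R_VC_RA] = config.R_vc_ra
    c[_core.I_KD] = config.diastolic_stiffness_mmHg
    c[_core.I_VD] = config.diastolic_volume_scale_mL
    c[_core.I_VK] = config.diastolic_knee_mL

    def g(r: float) -> float:
        return 0.0 if np.isinf(r) else 1.0 / r

    c[_core.I_G_OO] = 1.0 / params.R_OO
    c[_core.I_G_DO] = 1.0 / params.R_DO
    c[_core.I_G_HA_R] = g(lobar.R_ha_right)
    c[_core.I_G_HA_L] = g(lobar.R_ha_left)
    c[_core.I_G_PV_R] = g(lobar.R_pv_right)
    c[_core.I_G_PV_L] = g(lobar.R_pv_left)
    c[_core.I_G_HV_R] = g(lobar.R_hv_right)
    c[_core.I_G_HV_L] = g(lobar.R_hv_left)
    return c


def initial_state(config: ModelConfig) -> np.ndarray:
    """Plausible resting volumes; the vena cava absorbs the volume budget
    so that the closed-loop total equals ``config.total_volume_mL``."""
    mr, ml = config.right_lobe_fraction, config.left_lobe_fraction
    y = np.zeros(_core.N_STATE)
    y[0] = config.V0_RA + 40.0
    y[1] = config.V0_RV + 110.0
    y[2] = config.V0_pa + config.C_pa * 15.0
    y[3] = config.V0_pu + config.C_pu * 8.0
    y[4] = config.V0_LA + 40.0
    y[5] = config.V0_LV + 110.0
    y[6] = config.V0_sa + config.C_sa * 90.0
    y[7] = config.V0_pvn + config.C_pvn * 10.0
    y[8] = config.V0_liver * mr + config.C_liver * mr * 8.0
    y[9] = config.V0_liver * ml + config.C_liver * ml * 8.0
    y[10] = config.total_volume_mL - y.sum()
    if y[10] <= 0:
        raise ValueError("total_volume_mL too small for the configured compartments")
    return y


def _run(params, config, lobar, y0):
    c = _pack_constants(params, config, lobar)
    out = simulate_kernel(c, np.asarray(y0, dtype=float), config.steps_per_cycle,
                          config.max_cycles, config.periodicity_rtol)
    return out


def simulate_to_periodic(params: ParameterVector, config: ModelConfig | None = None,
                         *, lobar: LobarResistances | None = None,
                         y0: np.ndarray | None = None,
                         phase: str = "pre") -> CirculationTrace:
    """Simulate to periodic steady state and return the final cycle.

    Raises :class:`ConvergenceError` if the cycle budget is exhausted and
    :class:`IntegrationError` if the state becomes non-finite.
    """
    config = config or ModelConfig()
    if lobar is None:
        lobar = baseline_lobar(params, config)
    if y0 is None:
        y0 = initial_state(config)
    t, V, P, Q, obs, y_end, ncyc, residual, status = _run(params, config, lobar, y0)
    if status == 2:
        raise IntegrationError(f"non-finite state after {ncyc} cycles ({phase}-hpx)")
    if status == 1:
        raise ConvergenceError(
            f"no periodic steady state within {config.max_cycles} cycles "
            f"({phase}-hpx); last residual {residual:.3e}",
            residual=residual, phase=phase)
    trace = CirculationTrace(
        time_s=t,
        pressures={n: P[:, i] for i, n in enumerate(_core.PRESSURE_NAMES)},
        volumes={n: V[:, i] for i, n in enumerate(_core.VOLUME_NAMES)},
        flows={n: Q[:, i] for i, n in enumerate(_core.FLOW_NAMES)},
        phase=phase, n_cycles_run=int(ncyc), state_end=y_end,
    )
    return trace


def cycle_averages(trace: CirculationTrace) -> CycleOutputs:
    """Time-weighted means of the six clinical outputs over one cycle.

    The trace must span exactly one cardiac period (the contract of
    :func:`simulate_to_periodic`).  The portocaval gradient is the
    difference of the portal and caval mean pressures; flows are
    converted to L/min.
    """
    t = trace.time_s
    if len(t) < 3:
        raise ValueError("trace shorter than one cardiac period")
    span = t[-1] - t[0]

    def mean(x):
        return float(np.trapezoid(x, t) / span)

    p_pv = mean(trace.pressures["PVN"])
    p_vc = mean(trace.pressures["VC"])
    return CycleOutputs(
        P_pv=p_pv,
        PCG=p_pv - p_vc,
        MAP=mean(trace.pressures["SA"]),
        CO=mean(trace.flows["aortic"]) * MLS_TO_LMIN,
        Q_ha=mean(trace.flows["ha_right"] + trace.flows["ha_left"]) * MLS_TO_LMIN,
        Q_pv=mean(trace.flows["pv_right"] + trace.flows["pv_left"]) * MLS_TO_LMIN,
        phase=trace.phase,
        P_vc=p_vc,
    )


def run_virtual_hepatectomy(params: ParameterVector, config: ModelConfig | None = None,
                            *, y0: np.ndarray | None = None,
                            ) -> tuple[CycleOutputs, CycleOutputs]:
    """Simulate the pre-hpx state, resect, and re-simulate from the
    pre-hpx terminal state (an instantaneous intra-operative change)."""
    config = config or ModelConfig()
    pre_trace = simulate_to_periodic(params, config, phase="pre", y0=y0)
    pre = cycle_averages(pre_trace)
    post_lobar = apply_hepatectomy(params, config)
    post_trace = simulate_to_periodic(params, config, lobar=post_lobar,
                                      y0=pre_trace.state_end, phase="post")
    post = cycle_averages(post_trace)
    return pre, post


def evaluate_many(X: np.ndarray, config: ModelConfig | None = None,
                  *, warm_start: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vector driver for sampling studies: rows of ``X`` in the canonical
    input order -> arrays of pre- and post-hpx outputs (columns in
    OUTPUT_NAMES order plus mean caval pressure appended) and a boolean
    success mask.  Failed rows carry NaN.

    ``warm_start`` seeds each pre-hpx run with the previous successful
    terminal state to shorten the transient; results remain identical to
    cold starts to within the periodicity tolerance, and a fixed
    row-order makes the sweep deterministic.
    """
    config = config or ModelConfig()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    pre = np.full((n, 7), np.nan)
    post = np.full((n, 7), np.nan)
    ok = np.zeros(n, dtype=bool)
    y0_default = initial_state(config)
    y0 = y0_default
    for i in range(n):
        try:
            p = ParameterVector.from_array(X[i])
            pre_trace = simulate_to_periodic(p, config, phase="pre",
                                             y0=y0 if warm_start else y0_default)
            pre_out = cycle_averages(pre_trace)
            post_lobar = apply_hepatectomy(p, config)
            post_trace = simulate_to_periodic(p, config, lobar=post_lobar,
                                              y0=pre_trace.state_end, phase="post")
            post_out = cycle_averages(post_trace)
        except (ValueError, ConvergenceError, IntegrationError):
            continue
        pre[i, :6] = pre_out.as_array()
        pre[i, 6] = pre_out.P_vc
        post[i, :6] = post_out.as_array()
        post[i, 6] = post_out.P_vc
        ok[i] = True
        if warm_start:
            y0 = pre_trace.state_end
    return pre, post, ok
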