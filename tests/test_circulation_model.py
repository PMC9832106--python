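"""Closed-loop circulation model: conservation, periodicity, the
virtual-hepatectomy operator and directional physiology checks."""

import numpy as np
import pytest

from hepasens import circulation_model as cm
from hepasens.params import (
    CirculationTrace, ConvergenceError, ModelConfig, ParameterVector,
    default_parameters,
)


class TestSimulation:
    def test_volume_conservation(self, baseline_trace, config):
        tv = baseline_trace.total_volume()
        assert np.ptp(tv) / tv.mean() < 1e-6
        assert tv.mean() == pytest.approx(config.total_volume_mL, rel=1e-9)

    def test_periodic_steady_state(self, baseline_trace, base_params, config):
        """Restarting from the terminal state changes the cycle averages
        by less than the periodicity tolerance."""
        again = cm.simulate_to_periodic(base_params, config,
                                        y0=baseline_trace.state_end)
        a = cm.cycle_averages(baseline_trace).as_array()
        b = cm.cycle_averages(again).as_array()
        assert np.all(np.abs(a - b) / np.maximum(np.abs(a), 0.1)
                      < 2 * config.periodicity_rtol)

    def test_no_active_contraction_stops_the_pump(self, config):
        """With every chamber's contraction amplitude removed the
        circulation runs down toward hydrostatic equilibrium."""
        p = default_parameters().replace(Ea_LV=1e-12, Ea_RA=1e-12)
        cfg = config.replace(Ea_RV=0.0, Ea_LA=0.0, max_cycles=200,
                             periodicity_rtol=1e-4)
        out = cm.cycle_averages(cm.simulate_to_periodic(p, cfg))
        assert abs(out.CO) < 0.15
        assert abs(out.Q_pv) < 0.05

    def test_determinism_bit_identical(self, base_params, config):
        t1 = cm.simulate_to_periodic(base_params, config)
        t2 = cm.simulate_to_periodic(base_params, config)
        assert np.array_equal(t1.state_end, t2.state_end)
        for k in t1.pressures:
            assert np.array_equal(t1.pressures[k], t2.pressures[k])

    def test_nonconvergence_raises_with_residual(self, base_params, config):
        with pytest.raises(ConvergenceError) as exc:
            cm.simulate_to_periodic(base_params, config.replace(max_cycles=2))
        assert np.isfinite(exc.value.residual)

    def test_flow_continuity_at_liver(self, baseline_trace):
        """Cycle-averaged hepatic outflow equals portal + arterial inflow
        within 1 % at periodicity."""
        f = baseline_trace.flows
        inflow = np.mean(f["pv_right"] + f["pv_left"] + f["ha_right"] + f["ha_left"])
        outflow = np.mean(f["hv_right"] + f["hv_left"])
        assert outflow == pytest.approx(inflow, rel=0.01)


class TestCycleAverages:
    @staticmethod
    def _trace(t, p_pvn, p_vc, q_ao):
        zeros = np.zeros_like(t)
        pressures = {k: zeros for k in
                     ("RA", "RV", "PA", "PU", "LA", "LV", "SA", "LR", "LL")}
        pressures["PVN"] = p_pvn
        pressures["VC"] = p_vc
        flows = {k: zeros for k in
                 ("tricuspid", "pulmonary_valve", "pulmonary", "pulm_vein_la",
                  "mitral", "other_organs", "digestive", "ha_right", "ha_left",
                  "pv_right", "pv_left", "hv_right", "hv_left", "vc_ra")}
        flows["aortic"] = q_ao
        return CirculationTrace(time_s=t, pressures=pressures,
                                volumes={k: zeros for k in pressures},
                                flows=flows, phase="pre")

    def test_constant_signals_and_portocaval_gradient(self):
        t = np.linspace(0.0, 1.0, 201)
        out = cm.cycle_averages(self._trace(
            t, np.full_like(t, 10.0), np.full_like(t, 4.0), np.zeros_like(t)))
        assert out.P_pv == pytest.approx(10.0)
        assert out.PCG == pytest.approx(6.0)

    def test_sinusoid_with_offset_averages_to_offset(self):
        t = np.linspace(0.0, 2.0, 801)   # two full periods
        q0 = 50.0
        q = q0 + 30.0 * np.sin(2 * np.pi * t)
        out = cm.cycle_averages(self._trace(t, np.zeros_like(t) + 1,
                                            np.zeros_like(t), q))
        assert out.CO == pytest.approx(q0 * 60 / 1000, rel=1e-6)

    def test_short_trace_rejected(self):
        t = np.array([0.0, 0.1])
        with pytest.raises(ValueError, match="shorter"):
            cm.cycle_averages(self._trace(t, t, t, t))


class TestHepatectomy:
    def test_identity_when_nothing_resected(self, base_params, config):
        lob = cm.apply_hepatectomy(base_params.replace(hpx=0.0), config)
        base = cm.baseline_lobar(base_params, config)
        assert lob == base

    def test_full_right_lobe_resection_removes_branch(self, base_params, config):
        p = base_params.replace(hpx=config.right_lobe_fraction)
        lob = cm.apply_hepatectomy(p, config)
        assert np.isinf(lob.R_pv_right)
        # whole-liver resistance collapses onto the left lobe
        r_pv, r_ha, r_hv = lob.whole_liver()
        assert r_pv == pytest.approx(p.R_pv / config.left_lobe_fraction)
        assert r_ha == pytest.approx(p.R_ha / config.left_lobe_fraction)

    def test_partial_right_resection_scales_inverse_mass(self, base_params, config):
        # resect half the right lobe of a 0.6/0.4 split: factor 0.6/0.3 = 2
        p = base_params.replace(hpx=0.3)
        lob = cm.apply_hepatectomy(p, config)
        base = cm.baseline_lobar(p, config)
        assert lob.R_pv_right == pytest.approx(2.0 * base.R_pv_right)
        assert lob.R_hv_right == pytest.approx(2.0 * base.R_hv_right)
        assert lob.R_pv_left == pytest.approx(base.R_pv_left)

    def test_spillover_into_left_lobe(self, base_params, config):
        p = base_params.replace(hpx=0.7)
        lob = cm.apply_hepatectomy(p, config)
        assert np.isinf(lob.R_pv_right)
        assert lob.left_mass == pytest.approx(0.3)
        assert lob.R_pv_left == pytest.approx(
            (p.R_pv / config.left_lobe_fraction) * (0.4 / 0.3))

    def test_no_liver_remaining_rejected(self):
        with pytest.raises(ValueError):
            default_parameters().replace(hpx=1.0)


class TestVirtualHepatectomy:
    def test_zero_resection_post_equals_pre(self, base_params, config):
        pre, post = cm.run_virtual_hepatectomy(
            base_params.replace(hpx=1e-12), config)
        a, b = pre.as_array(), post.as_array()
        assert np.all(np.abs(a - b) / np.maximum(np.abs(a), 0.1)
                      < 5 * config.periodicity_rtol)

    def test_larger_resection_raises_portal_pressures(self, base_params, config):
        """Portal pressure and portocaval gradient rise with the resected
        fraction while cardiac output barely moves."""
        posts = []
        for hpx in (0.1, 0.3, 0.5, 0.7):
            _, post = cm.run_virtual_hepatectomy(base_params.replace(hpx=hpx), config)
            posts.append(post)
        ppv = [o.P_pv for o in posts]
        pcg = [o.PCG for o in posts]
        assert all(b > a for a, b in zip(ppv, ppv[1:]))
        assert all(b > a for a, b in zip(pcg, pcg[1:]))
        co = [o.CO for o in posts]
        assert (max(co) - min(co)) / max(co) < 0.10

    def test_failure_is_tagged_with_phase(self, base_params, config):
        with pytest.raises(ConvergenceError) as exc:
            cm.run_virtual_hepatectomy(base_params, config.replace(max_cycles=2))
        assert exc.value.phase == "pre"


class TestMonotonicityProbes:
    def test_systemic_resistance_raises_map(self, base_params, config,
                                            baseline_outputs):
        up = cm.cycle_averages(cm.simulate_to_periodic(
            base_params.replace(R_OO=2 * base_params.R_OO), config))
        assert up.MAP > baseline_outputs.MAP

    def test_arterial_resistance_lowers_hepatic_flow(self, base_params, config,
                                                     baseline_outputs):
        up = cm.cycle_averages(cm.simulate_to_periodic(
            base_params.replace(R_ha=2 * base_params.R_ha), config))
        assert up.Q_ha < baseline_outputs.Q_ha


def test_parameter_vector_invariants():
    with pytest.raises(ValueError):
        default_parameters().replace(R_pv=-0.1)
    with pytest.raises(ValueError):
        default_parameters().replace(Ea_LV=0.0)
    x = default_parameters().as_array()
    assert ParameterVector.from_array(x) == default_parameters()
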