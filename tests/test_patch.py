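"""Patch-clamp circuit simulation, capacitive correction, dual-sine extraction."""

import numpy as np
import pytest

from prestinlab import (
    BarrierParams,
    BoltzmannParams,
    DomainError,
    PatchModel,
    Protocol,
    Trace,
    barrier_current,
    capacitive_current,
    cm_model,
    correct_capacitive,
    dual_sine_capacitance,
    fit_nlc,
    hold_steady_state,
    membrane_charge,
    simulate_recording,
)
from prestinlab.nlc import CVCurve
from prestinlab.synth import WT_BOLTZMANN

#: a nearly-ideal linear cell: negligible NLC, 20 pF
LINEAR_CELL = BoltzmannParams(1e-9, 0.0, 0.8, 20.0)
F1 = 390.625  # Hz; 256 samples per cycle at dt = 10 us


class TestCircuitModel:
    def test_membrane_charge_strictly_increasing(self, wt_boltzmann):
        v = np.linspace(-300, 300, 2000)
        assert np.all(np.diff(membrane_charge(v, wt_boltzmann)) > 0)

    def test_capacitance_is_charge_derivative(self, wt_boltzmann):
        v = np.linspace(-200, 150, 3501)
        dq = np.gradient(membrane_charge(v, wt_boltzmann), v)
        assert np.allclose(dq, cm_model(v, wt_boltzmann), rtol=1e-4, atol=1e-4)

    def test_invalid_resistances_rejected(self):
        with pytest.raises(DomainError):
            PatchModel(r_series=0.0)

    def test_unknown_protocol_kind_rejected(self):
        with pytest.raises(DomainError):
            Protocol(kind="zap")


class TestSimulateRecording:
    def test_step_response_is_single_exponential(self):
        # q_max ~ 0, no leak: tau = R_s * C_lin (voltage-clamp charging)
        model = PatchModel(r_series=5.0, r_membrane=1e9, boltzmann=LINEAR_CELL)
        prot = Protocol(kind="step", levels=(20.0,), step_duration=0.01,
                        v_hold=0.0, dt=1e-6)
        sim = simulate_recording(model, prot)
        k0 = int(0.01 / prot.dt)
        tau = 5.0 * 20.0 * 1e-6  # MOhm * pF -> s
        ts = sim.time[k0:k0 + 5000] - sim.time[k0]
        predicted = 20.0 / 5.0 * 1e3 * np.exp(-ts / tau)  # pA
        resid = np.abs(sim.current.samples[k0:k0 + 5000] - predicted)
        assert resid.max() < 0.005 * predicted[0]

    def test_hold_reaches_algebraic_steady_state(self, wt_boltzmann):
        barrier = BarrierParams(g=700.0, q=0.75, delta=0.467, p_rel=1.0)
        model = PatchModel(r_series=5.0, r_membrane=500.0,
                           boltzmann=wt_boltzmann, barrier=barrier)
        prot = Protocol(kind="hold", v_hold=-60.0, duration=0.01, dt=1e-5)
        sim = simulate_recording(model, prot)
        _, i_ss = hold_steady_state(model, -60.0)
        assert sim.current.samples[-1] == pytest.approx(i_ss, rel=1e-3)

    def test_resistive_divider_without_leak_channel(self):
        model = PatchModel(r_series=5.0, r_membrane=500.0, boltzmann=LINEAR_CELL)
        _, i_ss = hold_steady_state(model, -101.0)
        assert i_ss == pytest.approx(-101.0 / (5.0 + 500.0) * 1e3, rel=1e-9)

    def test_ramp_capacitive_bump_area_equals_qmax(self, wt_boltzmann):
        # ramp deep enough that the Boltzmann occupancy runs ~0 -> ~1
        model = PatchModel(r_series=5.0, r_membrane=1e9, boltzmann=wt_boltzmann)
        prot = Protocol(kind="ramp", v_start=-400.0, v_end=220.0,
                        duration=0.62, settle=0.02, dt=1e-5)
        sim = simulate_recording(model, prot)
        icap = capacitive_current(wt_boltzmann, sim.v_membrane)
        vm = sim.v_membrane.samples
        # excess over the linear charging current, integrated over the ramp
        excess = icap.samples - wt_boltzmann.c_lin * np.gradient(vm, prot.dt) * 1e-3
        area_pC = np.trapezoid(excess, sim.time)  # pA*s = pC
        assert area_pC * 1e3 == pytest.approx(wt_boltzmann.q_max, rel=0.01)
        # bump peaks near v_h
        assert vm[np.argmax(excess)] == pytest.approx(wt_boltzmann.v_h, abs=2.0)

    def test_coarse_sampling_of_fast_circuit_rejected(self):
        # tau ~ 10 us << dt = 2 ms: V_m slews > 5 mV per substep at the cap
        model = PatchModel(r_series=0.5, r_membrane=500.0, boltzmann=LINEAR_CELL)
        prot = Protocol(kind="step", levels=(150.0,), step_duration=0.1,
                        v_hold=-150.0, dt=2e-3)
        with pytest.raises(DomainError, match="smaller"):
            simulate_recording(model, prot, max_substeps=2)


class TestCapacitiveCurrent:
    def test_constant_voltage_gives_zero(self, wt_boltzmann):
        tr = Trace(np.full(1000, -50.0), dt=1e-5)
        assert np.allclose(capacitive_current(wt_boltzmann, tr).samples, 0.0)

    def test_linear_ramp_of_linear_cell_is_constant(self):
        v = Trace(np.linspace(0, 100, 10001), dt=1e-5)  # 1000 mV/s
        icap = capacitive_current(LINEAR_CELL, v).samples
        assert np.allclose(icap, 20.0 * 1000.0 * 1e-3, rtol=1e-6)

    def test_ramp_integral_equals_total_charge(self, wt_boltzmann):
        v = np.linspace(-160.0, 110.0, 27001)
        tr = Trace(v, dt=1e-5)
        icap = capacitive_current(wt_boltzmann, tr)
        q_fC = np.trapezoid(icap.samples, tr.time) * 1e3
        expected = membrane_charge(110.0, wt_boltzmann) - \
            membrane_charge(-160.0, wt_boltzmann)
        assert q_fC == pytest.approx(expected, rel=5e-3)


class TestCorrectCapacitive:
    def test_leak_free_residual_below_one_percent(self, wt_boltzmann):
        model = PatchModel(r_series=5.0, r_membrane=1e9, boltzmann=wt_boltzmann)
        prot = Protocol(kind="ramp", v_start=-160.0, v_end=110.0,
                        duration=0.27, settle=0.02, dt=2e-6)
        sim = simulate_recording(model, prot)
        corrected = correct_capacitive(sim.current, model, prot)
        peak = np.abs(capacitive_current(wt_boltzmann, sim.v_membrane).samples).max()
        assert np.abs(corrected.samples).max() < 0.01 * peak

    def test_simulated_leak_recovered_pointwise(self, wt_boltzmann):
        barrier = BarrierParams(g=46.3 * 15, q=0.75, delta=0.467, p_rel=1.0)
        model = PatchModel(r_series=10.0, r_membrane=500.0,
                           boltzmann=wt_boltzmann, barrier=barrier)
        prot = Protocol(kind="ramp", v_start=-160.0, v_end=110.0,
                        duration=0.27, settle=0.02, dt=2e-6)
        sim = simulate_recording(model, prot)
        corrected = correct_capacitive(sim.current, model, prot)
        vm = sim.v_membrane.samples
        true_ionic = barrier_current(vm, barrier) + 1e3 * vm / 500.0
        err = np.abs(corrected.samples - true_ionic)
        assert err.max() < 0.02 * np.abs(true_ionic).max()

    def test_wrong_vh_leaves_dipolar_residual(self, wt_boltzmann):
        # correcting with V_h shifted +20 mV: residual is the difference of
        # two displaced NLC bumps - one positive and one negative lobe
        model = PatchModel(r_series=5.0, r_membrane=1e9, boltzmann=wt_boltzmann)
        prot = Protocol(kind="ramp", v_start=-160.0, v_end=110.0,
                        duration=0.27, settle=0.02, dt=1e-5)
        sim = simulate_recording(model, prot)
        wrong = BoltzmannParams(wt_boltzmann.q_max, wt_boltzmann.v_h + 20.0,
                                wt_boltzmann.z, wt_boltzmann.c_lin)
        wrong_model = PatchModel(r_series=5.0, r_membrane=1e9, boltzmann=wrong)
        resid = correct_capacitive(sim.current, wrong_model, prot).samples
        core = resid[int(0.04 / prot.dt):-100]  # avoid corner artifacts
        # scale against the NLC bump (peak excess capacitive current)
        vt = 25.52
        bump = wt_boltzmann.q_max * wt_boltzmann.z / (4 * vt) * 1000.0 * 1e-3  # pA
        assert core.max() > 0.15 * bump and core.min() < -0.15 * bump

    def test_length_mismatch_rejected(self, wt_boltzmann):
        model = PatchModel(boltzmann=wt_boltzmann)
        prot = Protocol(kind="ramp", duration=0.1, dt=1e-5)
        with pytest.raises(DomainError):
            correct_capacitive(Trace(np.zeros(100) + np.arange(100), dt=1e-5),
                               model, prot)


class TestDualSine:
    def test_constant_capacitance_recovered_within_one_percent(self):
        model = PatchModel(r_series=5.0, r_membrane=500.0, boltzmann=LINEAR_CELL)
        prot = Protocol(kind="dual_sine", v_hold=0.0, duration=0.1024, dt=1e-5, f1=F1)
        sim = simulate_recording(model, prot)
        ds = dual_sine_capacitance(sim.current, sim.command, F1)
        cm = np.nanmean(ds.c_m[ds.valid][2:])
        assert cm == pytest.approx(20.0, rel=0.01)
        assert np.nanmean(ds.r_s[ds.valid][2:]) == pytest.approx(5.0, rel=0.01)
        assert np.nanmean(ds.r_m[ds.valid][2:]) == pytest.approx(500.0, rel=0.01)

    def test_estimate_invariant_to_series_resistance(self):
        prot = Protocol(kind="dual_sine", v_hold=0.0, duration=0.1024, dt=1e-5, f1=F1)
        cms = []
        for rs in (5.0, 2.5):
            model = PatchModel(r_series=rs, r_membrane=500.0, boltzmann=LINEAR_CELL)
            sim = simulate_recording(model, prot)
            ds = dual_sine_capacitance(sim.current, sim.command, F1)
            cms.append(np.nanmean(ds.c_m[ds.valid][2:]))
        assert cms[0] == pytest.approx(cms[1], rel=0.01)

    def test_end_to_end_nlc_recovery(self, wt_boltzmann):
        model = PatchModel(r_series=5.0, r_membrane=500.0, boltzmann=wt_boltzmann)
        prot = Protocol(kind="dual_sine", base="ramp", v_start=-150.0,
                        v_end=100.0, duration=0.512, settle=0.0256,
                        dt=1e-5, f1=F1)
        sim = simulate_recording(model, prot)
        ds = dual_sine_capacitance(sim.current, sim.command, F1)
        keep = ds.valid & (ds.t_mid > prot.settle + 0.01)
        res = fit_nlc(CVCurve(ds.v_m_dc[keep], ds.c_m[keep]))
        assert res.params.v_h == pytest.approx(wt_boltzmann.v_h, abs=2.0)
        assert res.params.z == pytest.approx(wt_boltzmann.z, abs=0.02)
        assert res.params.q_max == pytest.approx(wt_boltzmann.q_max, rel=0.02)

    def test_pure_resistor_flagged_invalid(self):
        # no capacitive phase shift: Y(f1) ~ Y(2f1), the solve is
        # ill-conditioned and every window must be flagged
        dt, n = 1e-5, 25600
        t = np.arange(n) * dt
        v = 10 * np.sin(2 * np.pi * F1 * t) + 10 * np.sin(4 * np.pi * F1 * t)
        i = v / 10.0 * 1e3  # pure 10 MOhm resistor, pA
        ds = dual_sine_capacitance(Trace(i, dt=dt), Trace(v, dt=dt), F1)
        assert not ds.valid.any()

    def test_non_integer_cycle_rejected(self):
        tr = Trace(np.zeros(4096) + np.arange(4096), dt=1e-5)
        with pytest.raises(DomainError, match="integer"):
            dual_sine_capacitance(tr, tr, f1=333.0)

    def test_grid_mismatch_rejected(self):
        a = Trace(np.zeros(2560) + np.arange(2560), dt=1e-5)
        b = Trace(np.zeros(2560) + np.arange(2560), dt=2e-5)
        with pytest.raises(DomainError):
            dual_sine_capacitance(a, b, F1)


class TestChargeConservation:
    def test_closed_voltage_loop_moves_no_net_charge(self, wt_boltzmann):
        # ramp up then back down: net nonlinear charge ~ 0
        dt = 1e-5
        up = np.linspace(-160.0, 110.0, 13500)
        v = np.concatenate([up, up[::-1]])
        icap = capacitive_current(wt_boltzmann, Trace(v, dt=dt))
        net_fC = np.trapezoid(icap.samples, np.arange(v.size) * dt) * 1e3
        total_moved = wt_boltzmann.q_max
        assert abs(net_fC) < 0.005 * total_moved
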