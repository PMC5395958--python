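"""Two-state Boltzmann NLC model: closed forms, fitting, derived quantities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import grid_fit_nlc
from prestinlab import (
    BoltzmannParams,
    CVCurve,
    DomainError,
    FitError,
    NonlinearCapacitance,
    channel_count,
    cm_model,
    fit_nlc,
    specific_charge,
    unitary_from_whole_cell,
)
from prestinlab.constants import ELEMENTARY_CHARGE, thermal_voltage_mV
from prestinlab.synth import GeneratorSpec, gen_cv_curve

V_GRID = np.linspace(-160.0, 110.0, 136)


class TestCmModel:
    def test_peak_at_vh_equals_quarter_charge_slope(self):
        # at V = v_h the occupancy is 1/2, so NLC = q_max z/(4 kT/e0)
        p = BoltzmannParams(302.0, -40.0, 0.81, 20.0)
        vt = thermal_voltage_mV(p.temperature)
        assert cm_model(p.v_h, p) == pytest.approx(p.c_lin + p.q_max * p.z / (4 * vt))

    def test_fig_like_parameters_give_2p4_pF_peak(self):
        # 302 fC and z = 0.81 at 296.15 K -> peak NLC ~2.40 pF above baseline
        p = BoltzmannParams(302.0, -96.0, 0.81, 20.0)
        assert cm_model(p.v_h, p) - p.c_lin == pytest.approx(2.3963, abs=5e-4)

    def test_zero_charge_reduces_to_linear_capacitance(self):
        p = BoltzmannParams(0.0, -96.0, 0.81, 18.5)
        assert np.allclose(cm_model(V_GRID, p), p.c_lin)

    def test_capacitance_never_below_linear_and_max_at_vh(self, wt_boltzmann):
        v = np.linspace(-500, 500, 5001)
        cm = cm_model(v, wt_boltzmann)
        assert np.all(cm >= wt_boltzmann.c_lin)
        assert v[np.argmax(cm)] == pytest.approx(wt_boltzmann.v_h, abs=0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        q=st.floats(1.0, 2000.0),
        vh=st.floats(-200.0, 100.0),
        z=st.floats(0.2, 2.0),
        delta=st.floats(0.1, 300.0),
    )
    def test_symmetric_about_vh(self, q, vh, z, delta):
        p = BoltzmannParams(q, vh, z, 15.0)
        assert cm_model(vh + delta, p) == pytest.approx(
            cm_model(vh - delta, p), rel=1e-12)

    def test_charge_conservation_of_derivative_form(self, wt_boltzmann):
        # integral of C(V) over a wide window = c_lin*dV + q_max within 0.5%
        v = np.linspace(-500.0, 500.0, 20001)
        total = np.trapezoid(cm_model(v, wt_boltzmann), v)
        expected = wt_boltzmann.c_lin * 1000.0 + wt_boltzmann.q_max
        assert total == pytest.approx(expected, rel=5e-3)

    def test_nonfinite_voltage_rejected(self, wt_boltzmann):
        with pytest.raises(DomainError):
            cm_model(np.array([0.0, np.nan]), wt_boltzmann)

    @pytest.mark.parametrize("kw", [
        dict(q_max=-1.0), dict(z=0.0), dict(z=-0.5), dict(c_lin=0.0),
        dict(temperature=-1.0),
    ])
    def test_invalid_parameters_rejected(self, kw):
        base = dict(q_max=300.0, v_h=-96.0, z=0.8, c_lin=15.0)
        base.update(kw)
        with pytest.raises(DomainError):
            BoltzmannParams(**base)


class TestDerivedQuantities:
    def test_specific_charge(self):
        assert specific_charge(BoltzmannParams(0.0, 0, 0.8, 15.0)) == 0.0
        assert specific_charge(BoltzmannParams(304.8, 0, 0.8, 15.0)) == pytest.approx(20.32)
        assert specific_charge(BoltzmannParams(302.0, 0, 0.8, 20.0)) == pytest.approx(15.1)

    def test_channel_count_identity_and_scaling(self):
        # a cell whose total charge is exactly one unit of z e0 holds N = 1
        z = 0.8
        q_fC = z * ELEMENTARY_CHARGE / 1e-15
        p1 = BoltzmannParams(q_fC, 0, z, 15.0)
        assert channel_count(p1) == pytest.approx(1.0, rel=1e-12)
        p302 = BoltzmannParams(302.0, 0, 0.81, 15.0)
        assert channel_count(p302) == pytest.approx(2.33e6, rel=2e-3)
        p2 = BoltzmannParams(604.0, 0, 0.81, 15.0)
        assert channel_count(p2) == pytest.approx(2 * channel_count(p302), rel=1e-12)

    def test_channel_count_requires_charge(self):
        with pytest.raises(DomainError):
            channel_count(BoltzmannParams(0.0, 0, 0.8, 15.0))

    def test_unitary_current_from_whole_cell(self):
        p = BoltzmannParams(302.0, 0, 0.81, 15.0)  # N ~2.33e6
        assert unitary_from_whole_cell(0.0, p) == 0.0
        i = unitary_from_whole_cell(23.3, p)
        assert i == pytest.approx(0.010, abs=2e-4)  # fA
        assert unitary_from_whole_cell(-23.3, p) == -i


class TestFit:
    def test_noiseless_self_consistency(self, wt_boltzmann):
        spec = GeneratorSpec(seed=0, noise_sd_cv=0.0)
        res = fit_nlc(gen_cv_curve(spec))
        for name in ("q_max", "v_h", "z", "c_lin"):
            got, true = getattr(res.params, name), getattr(wt_boltzmann, name)
            assert got == pytest.approx(true, rel=1e-3, abs=1e-3 * abs(true))
        assert res.sse < 1e-12

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_nlc(CVCurve(np.arange(5.0), np.full(5, 15.0) + np.arange(5) * 0.01))

    def test_monotone_curve_fails_loudly(self):
        v = np.linspace(-100, 100, 30)
        with pytest.raises(FitError, match="monotone"):
            fit_nlc(CVCurve(v, 15.0 + 0.01 * v))

    def test_peak_outside_range_warns_in_diagnostics(self):
        p = BoltzmannParams(304.8, -125.0, 0.74, 15.0)
        v = np.linspace(-120.0, 110.0, 80)
        rng = np.random.default_rng(0)
        curve = CVCurve(v, cm_model(v, p) + rng.normal(0, 2e-3, v.size))
        with pytest.warns(RuntimeWarning, match="outside the sampled"):
            res = fit_nlc(curve)
        assert any("outside" in w for w in res.warnings)

    def test_matches_grid_search_oracle(self):
        spec = GeneratorSpec(seed=11)
        rng = np.random.default_rng(42)
        for _ in range(3):
            curve = gen_cv_curve(spec, rng=rng)
            res = fit_nlc(curve)
            q, vh, z, cl, sse_oracle = grid_fit_nlc(curve.v, curve.cm)
            # optimizer must do at least as well as the best grid node
            assert res.sse <= sse_oracle * (1 + 2e-3)
            assert res.params.v_h == pytest.approx(vh, abs=2.0)
            assert res.params.z == pytest.approx(z, abs=0.03)

    def test_z_rmse_consistent_with_oracle(self):
        # dispersion of the valence estimate agrees between the optimizer
        # and the brute-force fit on the same noisy replicates
        spec = GeneratorSpec(seed=0, noise_sd_cv=0.05)
        errs_fit, errs_grid = [], []
        for s in np.random.SeedSequence(314).spawn(10):
            curve = gen_cv_curve(spec, rng=np.random.default_rng(s))
            errs_fit.append(fit_nlc(curve).params.z - 0.74)
            errs_grid.append(grid_fit_nlc(curve.v, curve.cm)[2] - 0.74)
        rmse_fit = float(np.sqrt(np.mean(np.square(errs_fit))))
        rmse_grid = float(np.sqrt(np.mean(np.square(errs_grid))))
        assert rmse_fit <= rmse_grid * 1.5 + 1e-4
        assert rmse_fit == pytest.approx(rmse_grid, abs=0.01)

    def test_results_surface(self, wt_boltzmann):
        curve = gen_cv_curve(GeneratorSpec(seed=2))
        res = NonlinearCapacitance.from_curve(curve).fit()
        s = res.summary()
        assert "V_h" in s and "Q_sp" in s
        d = res.to_dict()
        assert set(d) >= {"q_max_fC", "v_h_mV", "z", "c_lin_pF", "stderr"}
        assert res.bse["v_h"] > 0
        assert res.predict(np.array([res.params.v_h])).max() <= res.params.c_lin + \
            res.params.q_max  # loose sanity: finite prediction

    def test_from_dataframe(self):
        import pandas as pd

        curve = gen_cv_curve(GeneratorSpec(seed=3))
        df = pd.DataFrame({"v_mV": curve.v, "cm_pF": curve.cm})
        res = NonlinearCapacitance.from_dataframe(df).fit()
        assert res.params.v_h == pytest.approx(-96.26, abs=2.0)
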