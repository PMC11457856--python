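"""Per-breath mechanics, energetics, VEI, PV-curve and calibration checks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ventwave as vw
from conftest import make_recording
from ventwave.core import CMH2O_ML_TO_J


def _constructed_breath(pip=28.0, peep=8.0, vt=10.0, fs=200.0,
                        Ti=0.5, period=1.0):
    """Square-pressure breath: volume ramps 0 -> vt over inspiration and
    back to 0 over expiration; (P - PEEP) is constant during inspiration."""
    n = int(period * fs)
    dt = 1.0 / fs
    t = np.arange(n) * dt
    # volume flat for the first sample (pressure still at PEEP there), then
    # a linear ramp to vt at Ti and back down: the inspiratory integral of
    # (P - PEEP) dV is exactly (PIP - PEEP) * vt
    vol = np.interp(t, [0.0, dt, Ti, period - dt], [0.0, 0.0, vt, 0.0])
    press = np.where((t >= dt) & (t <= Ti), pip, peep)
    flow = np.gradient(vol, t) * 60 / 1000
    rec = make_recording(t, press, flow, vol, fs, weight=1.0)
    i_end = int(Ti * fs)
    seg = vw.BreathSegment(0, i_end, n - 1, 0.0, t[i_end], t[-1])
    return rec, seg


class TestBreathMechanics:
    def test_ratio_arithmetic_example(self):
        """V_T 10 mL, PIP 28, PEEP 8 at 1 kg: dP = 20, C_dyn = 0.5 mL/cmH2O/kg."""
        rec, seg = _constructed_breath()
        m = vw.breath_mechanics(rec, seg, weight=1.0)
        assert m.dP == pytest.approx(20.0)
        assert m.V_T == pytest.approx(10.0, rel=1e-9)
        assert m.C_dyn_mlkg == pytest.approx(0.5, rel=1e-9)

    def test_zero_volume_breath_flagged_degenerate(self):
        rec, seg = _constructed_breath(vt=0.0)
        m = vw.breath_mechanics(rec, seg, weight=1.0)
        assert m.degenerate and m.C_dyn == 0.0

    def test_nonpositive_driving_pressure_raises(self):
        fs = 200.0
        t = np.arange(200) / fs
        rec = make_recording(t, np.full_like(t, 8.0), np.ones_like(t),
                             t * 10, fs)
        seg = vw.BreathSegment(0, 100, 199, 0.0, 0.5, 0.995)
        with pytest.raises(ValueError, match="driving pressure"):
            vw.breath_mechanics(rec, seg)

    def test_simulator_cdyn_recovers_ground_truth(self, rec_clean, segs_clean,
                                                  default_lung):
        """Noise-free plateau-reaching breath: C_dyn within 5% of C_rs."""
        m = vw.breath_mechanics(rec_clean, segs_clean[3])
        assert m.C_dyn == pytest.approx(default_lung.C_rs, rel=0.05)


class TestEquationOfMotionFit:
    def test_exact_recovery_on_model_data(self):
        """Data generated exactly from P = V/C + R*Q + P0 (no circuit)."""
        fs, C, R, p0 = 200.0, 1.2, 0.04, 8.0
        t = np.arange(400) / fs
        q = np.where(t < 0.5, 80.0 * np.exp(-t / 0.1), -60.0 * np.exp(-(t - 0.5) / 0.08))
        v = np.concatenate([[0], np.cumsum((q[1:] + q[:-1]) / 2) / fs])
        p = v / C + R * q + p0
        rec = make_recording(t, p, q * 60 / 1000, v, fs)
        seg = vw.BreathSegment(0, 100, 399, 0.0, 0.5, 1.995)
        fit = vw.fit_equation_of_motion(rec, seg)
        assert fit.C_fit == pytest.approx(C, rel=1e-8)
        assert fit.R_fit == pytest.approx(R, rel=1e-8)
        assert fit.P0 == pytest.approx(p0, rel=1e-8)

    def test_simulator_recovery_with_circuit(self, rec_clean, segs_clean,
                                             default_lung):
        """With circuit dynamics present: C within 5%, R within 15%."""
        fit = vw.fit_equation_of_motion(rec_clean, segs_clean[4])
        assert fit.C_fit == pytest.approx(default_lung.C_rs, rel=0.05)
        assert fit.R_fit == pytest.approx(default_lung.R_aw, rel=0.15)

    def test_rank_deficient_design_raises(self):
        fs = 200.0
        t = np.arange(200) / fs
        q = 50.0 * np.sin(2 * np.pi * t)
        v = 2.0 * q  # volume proportional to flow: degenerate design
        p = 10.0 + 0.1 * q
        rec = make_recording(t, p, q * 60 / 1000, v, fs)
        seg = vw.BreathSegment(0, 100, 199, 0.0, 0.5, 0.995)
        with pytest.raises(ValueError, match="rank-deficient"):
            vw.fit_equation_of_motion(rec, seg)


class TestEnergetics:
    def test_hand_integration_example(self):
        """(P - PEEP) = 20 cmH2O while volume rises 10 mL: E = 200 cmH2O*mL
        = 0.019613 J; at 60/min and 1 kg, MP_tidal = 1.177 J/min/kg."""
        rec, seg = _constructed_breath(pip=28.0, peep=8.0, vt=10.0)
        e = vw.energy_per_breath(rec, seg)
        assert e == pytest.approx(200.0 * CMH2O_ML_TO_J, rel=1e-9)
        assert e == pytest.approx(0.0196133, rel=1e-4)
        assert vw.mp_tidal(e, 60.0, 1.0) == pytest.approx(1.17680, rel=1e-3)
        # atmosphere-referenced variant integrates absolute pressure
        e_atm = vw.energy_per_breath(rec, seg, reference="atmosphere")
        assert e_atm == pytest.approx(280.0 * CMH2O_ML_TO_J, rel=1e-9)

    def test_zero_volume_zero_energy(self):
        rec, seg = _constructed_breath(vt=0.0)
        assert vw.energy_per_breath(rec, seg) == 0.0

    def test_quasi_static_limit_approaches_elastic_energy(self):
        """Slow inflation of a low-resistance lung: E -> V_T^2 / (2 C_rs)."""
        s = vw.VentilatorSettings(bias_flow=1.0, set_PIP=22.0, set_PEEP=8.0,
                                  Ti=4.0, rate=10.0, circuit_compliance=0.01)
        lung = vw.LungModelParams(C_rs=1.5, R_aw=0.002, weight=3.0)
        rec = vw.simulate_ventilation(s, lung, 12.0)
        seg = vw.segment_breaths(rec, flow_tolerance=0.02)[0]
        e = vw.energy_per_breath(rec, seg)
        m = vw.breath_mechanics(rec, seg)
        elastic = m.V_T ** 2 / (2 * lung.C_rs) * CMH2O_ML_TO_J
        assert e == pytest.approx(elastic, rel=0.03)

    def test_energy_at_least_elastic_minimum(self, rec_clean, segs_clean,
                                             default_lung):
        """Resistive breaths always dissipate: E >= V_T^2/(2 C_rs)."""
        for seg in segs_clean[1:6]:
            e = vw.energy_per_breath(rec_clean, seg)
            m = vw.breath_mechanics(rec_clean, seg)
            assert e >= m.V_T ** 2 / (2 * default_lung.C_rs) * CMH2O_ML_TO_J * (1 - 1e-6)


class TestMERS:
    def test_hand_arithmetic(self):
        """dP 20, V_T 10 mL, PEEP 8 at 1 kg: 180 cmH2O*mL = 0.017652 J/kg."""
        assert vw.me_rs(10.0, 20.0, 8.0, 1.0) == pytest.approx(0.0176520, rel=1e-4)

    def test_zero_peep_reduces_to_elastic_term(self):
        assert vw.me_rs(10.0, 20.0, 0.0, 1.0) == pytest.approx(
            0.5 * 20 * 10 * CMH2O_ML_TO_J, rel=1e-12)

    @given(st.floats(1.0, 50.0), st.floats(1.0, 40.0), st.floats(0.0, 12.0))
    def test_linear_in_tidal_volume(self, vt, dp, peep):
        one = vw.me_rs(vt, dp, peep, 1.0)
        two = vw.me_rs(2 * vt, dp, peep, 1.0)
        assert two == pytest.approx(2 * one, rel=1e-9)


class TestVEI:
    def test_direct_arithmetic(self):
        r = vw.vei(20.0, 60.0, 50.0)
        assert r.VEI == pytest.approx(3800.0 / 60000.0, rel=1e-12)

    @given(st.floats(5.0, 40.0), st.floats(20.0, 100.0), st.floats(30.0, 90.0))
    def test_reciprocal_scaling(self, dp, rate, paco2):
        base = vw.vei(dp, rate, paco2).VEI
        assert vw.vei(2 * dp, rate, paco2).VEI == pytest.approx(base / 2, rel=1e-9)
        assert vw.vei(dp, 2 * rate, paco2).VEI == pytest.approx(base / 2, rel=1e-9)
        assert vw.vei(dp, rate, 2 * paco2).VEI == pytest.approx(base / 2, rel=1e-9)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            vw.vei(0.0, 60.0, 50.0)
        with pytest.raises(ValueError):
            vw.vei(20.0, -5.0, 50.0)


class TestPVCurve:
    def test_linear_curve_tlc(self):
        """V = 2P mL at 1 kg: TLC = 70 mL/kg."""
        p = np.arange(0.0, 36.0, 5.0)
        curve = vw.StaticPVCurve(p, 2.0 * p)
        res = vw.analyze_pv_curve(curve, weight=1.0)
        assert res.TLC_mlkg == pytest.approx(70.0)
        assert not res.extrapolated
        for chord in res.chord_compliance_mlkg.values():
            assert chord == pytest.approx(2.0)

    def test_quasi_static_maneuver_matches_compliance_model(self):
        """Equilibrated pressure steps of the simulated lung: TLC within 2%
        of C_rs * 35 for the linear model."""
        lung = vw.LungModelParams(C_rs=1.5, R_aw=0.025, weight=3.0)
        steps = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0])
        vols = []
        for pstep in steps:
            s = vw.VentilatorSettings(bias_flow=6.0, set_PIP=pstep,
                                      set_PEEP=0.0, Ti=4.0, rate=10.0,
                                      circuit_compliance=0.1)
            rec = vw.simulate_ventilation(s, lung, 6.0)
            vols.append(rec.volume.max())
        res = vw.analyze_pv_curve(vw.StaticPVCurve(steps, np.array(vols)),
                                  weight=lung.weight)
        assert res.TLC_mlkg == pytest.approx(lung.C_rs * 35.0 / lung.weight,
                                             rel=0.02)

    def test_extrapolation_flagged(self):
        curve = vw.StaticPVCurve(np.array([0.0, 10.0, 20.0]),
                                 np.array([0.0, 20.0, 40.0]))
        res = vw.analyze_pv_curve(curve, weight=1.0)
        assert res.extrapolated
        assert res.TLC_mlkg == pytest.approx(70.0)

    def test_non_monotone_limb_raises(self):
        curve = vw.StaticPVCurve(np.array([0.0, 10.0, 20.0, 35.0]),
                                 np.array([0.0, 30.0, 20.0, 60.0]))
        with pytest.raises(ValueError, match="non-monotone"):
            vw.analyze_pv_curve(curve, weight=1.0)


class TestDeltaVLCalibration:
    def test_linear_scaling(self):
        sig = np.array([0.0, 500.0, 1000.0])
        scaled, s = vw.calibrate_delta_VL(sig, dZ_ref=1000.0, V_ref=40.0)
        assert s == pytest.approx(0.04)
        np.testing.assert_allclose(scaled, [0.0, 20.0, 40.0])

    def test_zero_signal_maps_to_zero(self):
        scaled, _ = vw.calibrate_delta_VL(np.zeros(5), 100.0, 40.0)
        assert np.all(scaled == 0.0)

    def test_nonpositive_reference_raises(self):
        with pytest.raises(ValueError):
            vw.calibrate_delta_VL(np.ones(5), 0.0, 40.0)
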