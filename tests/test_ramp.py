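"""Ramp analysis: input resistance, IV extraction/subtraction, reversals,
driving force, junction correction, rupture detection, V_m."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import chloridephys as cp
from chloridephys.constants import nernst_chloride
from chloridephys.containers import IVCurve, MembraneProperties, Recording
from chloridephys.ephys_sim import build_command
from chloridephys.errors import AnalysisError, ProtocolError
from chloridephys.params import CURRENT_CLAMP
from chloridephys.ramp import measure_vm

from conftest import equilibrated_cl

finite_mv = st.floats(min_value=-120.0, max_value=40.0)


def make_vc_recording(currents_flat, protocol):
    """Wrap a flat current trace into a Recording on the given protocol."""
    t, v = build_command(protocol)
    n = v.size
    sweeps = [currents_flat[s * n:(s + 1) * n] for s in range(protocol.n_sweeps)]
    return Recording(sweeps=sweeps, command=v, time_base=t, protocol=protocol)


def make_cc_recording(v_trace, duration, fs=1000.0):
    prot = cp.ProtocolSpec(mode=CURRENT_CLAMP, inter_ramp_interval=duration,
                           n_sweeps=1, sampling_rate=fs, filter_cutoff=0.0)
    n = int(round(duration * fs))
    return Recording(sweeps=[v_trace], command=np.zeros(n),
                     time_base=np.arange(n) / fs, protocol=prot)


class TestInputResistance:
    @pytest.mark.parametrize("g_leak,expected", [
        (2.5, 400.0),        # dV=-5 mV, dI=-12.5 pA
        (9.26, 1000.0 / 9.26),  # dI=-46.3 pA -> ~108 MOhm, the shunted scale
    ])
    def test_ohms_law_from_pulse(self, g_leak, expected):
        cell = cp.CellParams(g_leak=g_leak, e_leak=-50.0, cl_dynamics=False)
        rec = cp.simulate_voltage_clamp(cell, cp.ProtocolSpec(n_sweeps=2))
        assert cp.compute_input_resistance(rec) == pytest.approx(expected, rel=0.01)

    def test_low_confidence_warning_in_heavy_noise(self):
        cell = cp.CellParams(g_leak=0.01, e_leak=-50.0, cl_dynamics=False)
        rec = cp.simulate_voltage_clamp(cell, cp.ProtocolSpec(n_sweeps=1),
                                        noise_sd=50.0, seed=1)
        with pytest.warns(UserWarning, match="noise floor"):
            cp.compute_input_resistance(rec)

    def test_current_clamp_recording_rejected(self):
        rec = cp.simulate_current_clamp(cp.CellParams(cl_dynamics=False),
                                        duration=1.0, sampling_rate=2000.0,
                                        filter_cutoff=500.0)
        with pytest.raises(ProtocolError):
            cp.compute_input_resistance(rec)


class TestExtractIV:
    def test_linear_conductance_gives_straight_line(self):
        cell = cp.CellParams(g_leak=2.0, e_leak=-60.0, cl_dynamics=False)
        rec = cp.simulate_voltage_clamp(cell, cp.ProtocolSpec(n_sweeps=1))
        iv = cp.extract_iv(rec, "basal")
        slope, intercept = np.polyfit(iv.voltages, iv.currents, 1)
        assert slope == pytest.approx(2.0, rel=1e-3)
        assert -intercept / slope == pytest.approx(-60.0, abs=0.01)

    def test_averaging_two_identical_ramps(self):
        cell = cp.CellParams(g_leak=2.0, e_leak=-60.0, cl_dynamics=False)
        rec1 = cp.simulate_voltage_clamp(cell, cp.ProtocolSpec(n_sweeps=1))
        rec2 = cp.simulate_voltage_clamp(cell, cp.ProtocolSpec(n_sweeps=2))
        iv1, iv2 = cp.extract_iv(rec1, "basal"), cp.extract_iv(rec2, "basal")
        assert iv2.n_ramps_averaged == 2
        assert np.allclose(iv1.currents, iv2.currents)

    def test_noise_reduction_scales_with_ramp_count(self):
        cell = cp.CellParams(g_leak=2.0, e_leak=-60.0, cl_dynamics=False)
        prot1 = cp.ProtocolSpec(n_sweeps=1, filter_cutoff=0.0)
        prot9 = cp.ProtocolSpec(n_sweeps=9, filter_cutoff=0.0)
        true_line = lambda v: 2.0 * (v + 60.0)
        sd1 = np.std([
            cp.extract_iv(cp.simulate_voltage_clamp(cell, prot1, noise_sd=5.0,
                                                    seed=s), "basal").currents
            - true_line(cp.extract_iv(cp.simulate_voltage_clamp(
                cell, prot1, noise_sd=5.0, seed=s), "basal").voltages)
            for s in range(5)
        ])
        iv9 = [cp.extract_iv(cp.simulate_voltage_clamp(cell, prot9, noise_sd=5.0,
                                                       seed=s), "basal")
               for s in range(5)]
        sd9 = np.std([iv.currents - true_line(iv.voltages) for iv in iv9])
        assert sd9 / sd1 == pytest.approx(1.0 / 3.0, rel=0.3)

    def test_missing_window_raises_named_error(self, noiseless_control_recording):
        with pytest.raises(ProtocolError, match="glycine"):
            cp.extract_iv(noiseless_control_recording, "gaba", gaba_label="glycine")


class TestSubtractIV:
    def test_identical_curves_cancel(self):
        v = np.linspace(-100, -30, 141)
        iv = IVCurve(v, 2.0 * (v + 60.0))
        diff = cp.subtract_iv(iv, iv)
        assert np.allclose(diff.currents, 0.0)
        assert diff.source == "subtracted"

    def test_linearity_recovers_pure_agonist_conductance(self):
        v = np.linspace(-100, -30, 141)
        basal = IVCurve(v, 2.0 * (v + 60.0))
        gaba = IVCurve(v, 2.0 * (v + 60.0) + 4.0 * (v + 55.0), source="gaba")
        diff = cp.subtract_iv(gaba, basal)
        assert np.allclose(diff.currents, 4.0 * (v + 55.0))

    def test_disjoint_ranges_raise(self):
        a = IVCurve(np.linspace(-100, -80, 21), np.zeros(21))
        b = IVCurve(np.linspace(-60, -30, 31), np.zeros(31))
        with pytest.raises(AnalysisError):
            cp.subtract_iv(a, b)

    def test_subtracted_root_matches_simulated_chloride_reversal(
            self, noiseless_185l_recording):
        rec = noiseless_185l_recording
        iv = cp.subtract_iv(cp.extract_iv(rec, "gaba"), cp.extract_iv(rec, "basal"))
        e_gaba = cp.find_reversal(iv, holding=-50.0)
        fs = rec.protocol.sampling_rate
        i_mid = int(round((rec.protocol.ramp_onset
                           + rec.protocol.ramp_duration / 2) * fs))
        cl_at_ramp = rec.aux["cl_in"][3][i_mid]  # GABA ramp is in sweep 3
        e_cl = nernst_chloride(cl_at_ramp, 151.0)
        assert e_gaba == pytest.approx(e_cl, abs=0.5)


class TestFindReversal:
    def test_two_point_symmetric_interpolation(self):
        iv = IVCurve(np.array([-70.0, -50.0]), np.array([-2.0, 2.0]))
        assert cp.find_reversal(iv) == pytest.approx(-60.0)

    def test_exact_zero_sample_is_returned(self):
        iv = IVCurve(np.array([-70.0, -63.6, -50.0]), np.array([-2.0, 0.0, 2.0]))
        assert cp.find_reversal(iv) == pytest.approx(-63.6)

    def test_dense_noiseless_line_recovers_root_exactly(self):
        v = np.linspace(-100.0, -30.0, 1401)
        iv = IVCurve(v, 3.7 * (v + 63.6))
        assert cp.find_reversal(iv) == pytest.approx(-63.6, abs=1e-9)

    def test_no_sign_change_raises_out_of_range(self):
        v = np.linspace(-100.0, -30.0, 141)
        iv = IVCurve(v, 2.0 * (v + 10.0))  # reversal at -10 mV, outside ramp
        with pytest.raises(AnalysisError, match="outside"):
            cp.find_reversal(iv)

    def test_multiple_crossings_flagged_and_nearest_holding_reported(self):
        v = np.linspace(-100.0, -30.0, 15)
        cur = np.sin((v + 65.0) / 8.0)  # crossings near -90, -65, -40
        iv = IVCurve(v, cur)
        with pytest.warns(UserWarning, match="crossings"):
            value, diag = cp.find_reversal(iv, holding=-50.0, smooth=1,
                                           full_output=True)
        assert diag.ambiguous and diag.n_crossings == 3
        assert value == pytest.approx(-65.0 + np.pi * 8.0, abs=0.5)  # ~-39.9


class TestDrivingForce:
    @pytest.mark.parametrize("e_gaba,v_rev,expected", [
        (-58.7, -63.6, 4.9),    # depolarising GABA driving force, control
        (-52.5, -52.1, -0.4),   # collapsed driving force, tonic shunt
    ])
    def test_reported_study_values(self, e_gaba, v_rev, expected):
        assert cp.driving_force(e_gaba, v_rev) == pytest.approx(expected, abs=1e-12)

    @given(x=finite_mv)
    def test_equal_potentials_give_zero(self, x):
        assert cp.driving_force(x, x) == 0.0

    @given(e=finite_mv, v=finite_mv)
    def test_antisymmetry(self, e, v):
        assert cp.driving_force(e, v) + cp.driving_force(v, e) == pytest.approx(0.0,
                                                                                abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(AnalysisError):
            cp.driving_force(np.nan, -60.0)


class TestJunctionCorrection:
    def test_offset_subtracted_from_absolute_potentials_only(self):
        props = MembraneProperties(r_n=400.0, v_rev=-63.6, e_gaba=-58.7)
        out = cp.correct_junction_potential(props, offset=3.75)
        assert out.v_rev == pytest.approx(-67.35)
        assert out.e_gaba == pytest.approx(-62.45)
        assert out.driving_force == pytest.approx(props.driving_force)
        assert out.junction_corrected

    def test_zero_offset_identity_on_values(self):
        props = MembraneProperties(v_rev=-60.0, e_gaba=-55.0)
        out = cp.correct_junction_potential(props, offset=0.0)
        assert out.v_rev == props.v_rev and out.e_gaba == props.e_gaba

    def test_double_correction_rejected(self):
        props = cp.correct_junction_potential(MembraneProperties(v_rev=-60.0))
        with pytest.raises(AnalysisError):
            cp.correct_junction_potential(props)


class TestRuptureDetection:
    def setup_method(self):
        self.prot = cp.ProtocolSpec(n_sweeps=3, filter_cutoff=0.0)
        rng = np.random.default_rng(0)
        n = int(self.prot.total_duration * self.prot.sampling_rate)
        self.noise = rng.normal(0.0, 10.0, n)

    def test_flat_noisy_baseline_clean(self):
        rec = make_vc_recording(self.noise.copy(), self.prot)
        assert not cp.detect_rupture(rec)

    def test_large_step_flagged_at_onset(self):
        t0 = 8.0
        trace = self.noise.copy()
        trace[int(t0 * 10000):] -= 500.0
        rec = make_vc_recording(trace, self.prot)
        flag = cp.detect_rupture(rec)
        assert flag.ruptured
        assert flag.onset == pytest.approx(t0, abs=0.005)

    def test_slow_drift_below_threshold_clean(self):
        t = np.arange(self.noise.size) / 10000.0
        rec = make_vc_recording(self.noise + 3.0 * t, self.prot)
        assert not cp.detect_rupture(rec)


class TestMeasureVm:
    def test_constant_trace(self):
        rec = make_cc_recording(np.full(200 * 1000, -51.2), 200.0)
        est = measure_vm(rec, stabilization=120.0)
        assert est.value == pytest.approx(-51.2)
        assert est.drift_slope == pytest.approx(0.0, abs=1e-9)

    def test_exponential_approach_reports_plateau(self):
        fs, dur, tau = 1000.0, 300.0, 20.0
        t = np.arange(int(dur * fs)) / fs
        v = -35.9 + (-50.0 + 35.9) * np.exp(-t / tau)
        est = measure_vm(make_cc_recording(v, dur), stabilization=150.0)
        assert est.value == pytest.approx(-35.9, abs=0.5)

    def test_noisy_trace_returns_sample_mean(self):
        rng = np.random.default_rng(3)
        v = -35.9 + rng.normal(0.0, 2.0, int(200 * 1000))
        est = measure_vm(make_cc_recording(v, 200.0), stabilization=100.0)
        assert est.value == pytest.approx(-35.9, abs=3 * 2.0 / np.sqrt(100 * 1000))

    def test_short_recording_rejected(self):
        rec = make_cc_recording(np.full(1000, -50.0), 1.0)
        with pytest.raises(ProtocolError):
            measure_vm(rec, stabilization=120.0)


class TestOracleEquivalence:
    def test_basal_reversal_matches_conductance_weighted_mean(self):
        """Noiseless simulated cells: the analysed V_rev equals the analytic
        sum(g*E)/sum(g) of the open conductances within 0.1 mV."""
        for g_glyr, e_cl_target in ((0.0, -58.0), (4.0, -52.0), (12.0, -50.0)):
            cell = cp.CellParams(g_leak=2.33, e_leak=-63.6, g_glyr=g_glyr,
                                 cl_in_init=equilibrated_cl(e_cl_target),
                                 cl_dynamics=False)
            rec = cp.simulate_voltage_clamp(cell, cp.ProtocolSpec(n_sweeps=1))
            v_rev = cp.find_reversal(cp.extract_iv(rec, "basal"), holding=-50.0)
            expected = ((cell.g_leak * cell.e_leak + g_glyr * e_cl_target)
                        / (cell.g_leak + g_glyr))
            assert v_rev == pytest.approx(expected, abs=0.1)


class TestRampAnalysisModel:
    def test_full_fit_on_shunted_cell(self, noiseless_185l_recording):
        res = cp.RampAnalysis(noiseless_185l_recording).fit()
        p = res.properties
        assert p.r_n == pytest.approx(108.0, rel=0.05)
        assert abs(p.driving_force) < 1.0
        assert not res.excluded
        assert "R_N" in res.summary()

    def test_ruptured_recording_excluded(self):
        prot = cp.ProtocolSpec(n_sweeps=3, filter_cutoff=0.0)
        rng = np.random.default_rng(1)
        n = int(prot.total_duration * prot.sampling_rate)
        trace = rng.normal(0.0, 10.0, n)
        trace[n // 2:] -= 800.0
        res = cp.RampAnalysis(make_vc_recording(trace, prot)).fit()
        assert res.excluded and res.rupture.ruptured
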