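"""Calcium imaging: background, calibration, conversion, gating, ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import chloridephys as cp
from chloridephys.containers import CalibrationConstants, FluorescenceExperiment
from chloridephys.errors import (CalibrationError, ProtocolError,
                                 SaturationError)
from chloridephys.fluor_sim import fura_ratio_from_ca
from chloridephys.imaging import (derive_calibration, estimate_background,
                                  fura2_concentration, og_ratio,
                                  resting_calcium, viability_gate)


def manual_experiment(f340, f380, events):
    return FluorescenceExperiment(frame_times=np.arange(len(f340), dtype=float),
                                  channels={"F340": np.asarray(f340, float),
                                            "F380": np.asarray(f380, float)},
                                  events=events)


class TestBackground:
    def test_constant_quench_window(self):
        n = 40
        f = np.full(n, 120.0)
        f[-15:] = 50.0
        expt = manual_experiment(f, f, {"Mn_quench": (25.0, 39.0)})
        bg = estimate_background(expt)
        assert bg["F340"] == pytest.approx(50.0)
        assert bg["F380"] == pytest.approx(50.0)

    def test_injected_background_recovered_within_noise(self):
        expt = cp.make_fura_experiment(background=(55.0, 42.0), noise_sd=2.0,
                                       seed=4)
        bg = estimate_background(expt)
        n_quench = int(np.sum(expt.window_mask("Mn_quench")))
        se = 2.0 / np.sqrt(n_quench)
        assert bg["F340"] == pytest.approx(55.0, abs=4 * se)
        assert bg["F380"] == pytest.approx(42.0, abs=4 * se)

    def test_missing_quench_window_raises(self):
        expt = manual_experiment(np.ones(30), np.ones(30), {})
        with pytest.raises(ProtocolError):
            estimate_background(expt)


class TestCalibration:
    def test_exact_recovery_from_noiseless_plateaus(self):
        cal_true = CalibrationConstants(r_min=0.3, r_max=3.0, f380_min=200.0,
                                        f380_max=80.0)
        expt = cp.make_fura_experiment(cal=cal_true, noise_sd=0.0)
        cal = derive_calibration(expt)
        assert cal.r_min == pytest.approx(0.3, abs=1e-9)
        assert cal.r_max == pytest.approx(3.0, abs=1e-9)
        assert cal.beta == pytest.approx(200.0 / 80.0, abs=1e-9)

    def test_noisy_recovery_within_sampling_error(self):
        expt = cp.make_fura_experiment(noise_sd=2.0, seed=9)
        cal = derive_calibration(expt)
        assert cal.r_min == pytest.approx(0.3, abs=0.05)
        assert cal.r_max == pytest.approx(3.0, abs=0.2)

    def test_swapped_windows_raise(self):
        expt = cp.make_fura_experiment(noise_sd=0.0)
        ev = dict(expt.events)
        ev["ionomycin_0Ca"], ev["ionophore_10Ca"] = (ev["ionophore_10Ca"],
                                                     ev["ionomycin_0Ca"])
        expt.events = ev
        with pytest.raises(CalibrationError):
            derive_calibration(expt)


class TestFura2Concentration:
    def test_ratio_at_rmin_gives_zero(self):
        cal = CalibrationConstants()
        assert fura2_concentration(cal.r_min, cal) == 0.0

    def test_midpoint_with_equal_f380_returns_kd(self):
        cal = CalibrationConstants(r_min=0.5, r_max=2.5, f380_min=100.0,
                                   f380_max=100.0)
        mid = (cal.r_min + cal.r_max) / 2.0
        assert fura2_concentration(mid, cal) == pytest.approx(225.0)

    def test_direct_product(self):
        # (r - r_min)/(r_max - r) = 2 and beta = 1.5 -> 225 * 1.5 * 2 = 675
        cal = CalibrationConstants(r_min=1.0, r_max=4.0, f380_min=150.0,
                                   f380_max=100.0)
        r = 3.0
        assert fura2_concentration(r, cal) == pytest.approx(675.0)

    def test_saturated_ratio_raises(self):
        cal = CalibrationConstants()
        with pytest.raises(SaturationError):
            fura2_concentration(cal.r_max, cal)

    def test_sub_rmin_ratio_clips_to_zero_with_note(self):
        cal = CalibrationConstants()
        notes = []
        assert fura2_concentration(cal.r_min - 0.05, cal, qc_notes=notes) == 0.0
        assert notes

    @given(st.lists(st.floats(min_value=0.31, max_value=2.9), min_size=2,
                    max_size=6, unique=True))
    def test_strictly_increasing_in_ratio(self, ratios):
        cal = CalibrationConstants()
        ratios = sorted(ratios)
        values = [fura2_concentration(r, cal) for r in ratios]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestViabilityGate:
    def _expt_with_step(self, step_sds):
        """Deterministic trace: baseline ratio SD known exactly, KCl peak at
        step_sds baseline SDs above the baseline mean."""
        n = 60
        f380 = np.ones(n)         # unit denominator: ratio == F340 exactly
        f340 = np.full(n, 2.0)
        f340[:40][::2] += 1.0     # baseline ratio alternates -> known SD
        base_r = f340[30:40].copy()
        sd = np.std(base_r)
        f340[40:50] = np.mean(base_r) + step_sds * sd
        f340[-10:] = 0.0
        f380[-10:] = 0.0
        return manual_experiment(f340, f380, {"KCl": (40.0, 49.0),
                                              "Mn_quench": (50.0, 59.0)})

    def test_flat_trace_not_viable(self):
        expt = self._expt_with_step(0.0)
        assert not viability_gate(expt)

    def test_large_response_viable(self):
        assert viability_gate(self._expt_with_step(20.0))

    def test_exact_threshold_passes(self):
        assert viability_gate(self._expt_with_step(5.0), threshold_sd=5.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_raising_threshold_never_rescues(self, seed):
        expt = cp.make_fura_experiment(kcl_ca=120.0, noise_sd=3.0, seed=seed)
        for lo, hi in ((2.0, 5.0), (5.0, 12.0)):
            if viability_gate(expt, threshold_sd=hi):
                assert viability_gate(expt, threshold_sd=lo)


class TestRestingCalcium:
    def test_noiseless_round_trip_exact(self):
        expt = cp.make_fura_experiment(resting_ca=80.0, noise_sd=0.0)
        res = resting_calcium(expt)
        assert res.viability
        assert res.resting_ca == pytest.approx(80.0, rel=1e-9)

    def test_forward_inverse_round_trip_across_range(self):
        """Simulate-then-calibrate is exact to 1e-6 relative from 10 nM to
        2 uM at zero noise."""
        cal = CalibrationConstants()
        ca_true = np.geomspace(10.0, 2000.0, 25)
        expt = cp.simulate_fluorescence(ca_true, cal=cal, noise_sd=0.0)
        derived = derive_calibration(expt)
        bg = estimate_background(expt)
        mask = expt.frame_times < ca_true.size
        r = ((expt.channels["F340"][mask] - bg["F340"])
             / (expt.channels["F380"][mask] - bg["F380"]))
        ca_est = fura2_concentration(r, derived)
        assert np.max(np.abs(ca_est - ca_true) / ca_true) < 1e-6

    def test_recovery_bias_small_under_noise(self):
        """Mean recovery bias < 5% at the study's ~79 nM resting level."""
        est = [resting_calcium(cp.make_fura_experiment(resting_ca=78.9,
                                                       noise_sd=2.0,
                                                       seed=s)).resting_ca
               for s in range(20)]
        assert np.mean(est) == pytest.approx(78.9, rel=0.05)

    def test_non_viable_cell_reports_no_concentration(self):
        expt = cp.make_fura_experiment(resting_ca=80.0, kcl_ca=80.0, noise_sd=0.5,
                                       seed=2)
        res = resting_calcium(expt)
        assert not res.viability and res.resting_ca is None

    def test_background_offset_invariance(self):
        a = cp.make_fura_experiment(resting_ca=80.0, background=(50.0, 40.0),
                                    noise_sd=0.0)
        b = cp.make_fura_experiment(resting_ca=80.0, background=(150.0, 140.0),
                                    noise_sd=0.0)
        ca_a = resting_calcium(a).resting_ca
        ca_b = resting_calcium(b).resting_ca
        assert ca_b == pytest.approx(ca_a, rel=1e-9)


class TestOgRatio:
    def _single_channel(self, gaba, kcl, bg=30.0):
        n = 70
        f = np.full(n, bg)
        f[20:30] += gaba
        f[40:50] += kcl
        f[-10:] = bg
        return FluorescenceExperiment(
            frame_times=np.arange(n, dtype=float), channels={"F": f},
            events={"GABA": (20.0, 29.0), "KCl": (40.0, 49.0),
                    "Mn_quench": (60.0, 69.0)})

    def test_equal_responses_give_unity(self):
        assert og_ratio(self._single_channel(100.0, 100.0)) == pytest.approx(1.0)

    def test_zero_gaba_response_gives_zero(self):
        assert og_ratio(self._single_channel(0.0, 100.0)) == pytest.approx(0.0)

    def test_small_gaba_response_scale(self):
        # 22 vs 100 a.u. -> 0.22, the hippocampal F_GABA/F_KCl scale
        assert og_ratio(self._single_channel(22.0, 100.0)) == pytest.approx(0.22)

    def test_nonpositive_kcl_response_raises(self):
        from chloridephys.errors import AnalysisError
        with pytest.raises(AnalysisError):
            og_ratio(self._single_channel(10.0, 0.0))


class TestCalciumAnalysisModel:
    def test_fura_mode_summary(self):
        res = cp.CalciumAnalysis(cp.make_fura_experiment(noise_sd=1.0,
                                                         seed=5)).fit()
        assert res.viability
        assert "resting Ca" in res.summary()

    def test_og_mode_reports_ratio(self):
        expt = cp.make_og_experiment(noise_sd=0.0)
        res = cp.CalciumAnalysis(expt, mode="og").fit()
        assert 0.1 < res.og_ratio < 0.5
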