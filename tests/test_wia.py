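"""Wave-intensity core: separation identities, PWS estimation, landmarks,
segmentation, %Td and phase deltas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from puwave.config import AnalysisConfig, MMHG_TO_PA
from puwave.errors import EstimationError, LandmarkError, ParameterError
from puwave.pipeline import analyze_recording
from puwave.simulate import preset_scenario, synthesize_beat
from puwave import wia

from conftest import beat_from_series, grid_scenario, water_hammer_beat


class TestNetWi:
    def test_zero_pressure_derivative_gives_zero(self):
        assert np.all(wia.compute_net_wi(np.zeros(10), np.ones(10)) == 0)

    def test_unit_arithmetic(self):
        out = wia.compute_net_wi(np.array([1000.0]), np.array([10.0]))
        assert out[0] == 1e4

    def test_reciprocal_changes_give_negative_intensity(self):
        out = wia.compute_net_wi(np.array([500.0]), np.array([-2.0]))
        assert out[0] < 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            wia.compute_net_wi(np.zeros(5), np.zeros(6))


@st.composite
def beat_inputs(draw):
    n = draw(st.integers(40, 120))
    rng = np.random.default_rng(draw(st.integers(0, 2 ** 20)))
    p = 80 + 30 * rng.random(n)
    u = rng.normal(0.2, 0.3, n)
    pws = draw(st.floats(0.5, 30.0))
    return p, u, pws


class TestSeparationIdentities:
    @settings(max_examples=60, deadline=None)
    @given(beat_inputs())
    def test_component_sums_and_signs_for_any_pws(self, inputs):
        """Pf+Pb=P, Uf+Ub=U to machine precision and WIf+WIb=net-WI for
        arbitrary (even wrong) pulse wave speed — an algebraic identity."""
        p, u, pws = inputs
        beat = beat_from_series(p, u)
        sep = wia.separate_components(beat, pws)
        np.testing.assert_allclose(sep.p_forward + sep.p_backward, p, atol=1e-9)
        np.testing.assert_allclose(sep.u_forward + sep.u_backward, u, atol=1e-9)
        net = wia.compute_net_wi(beat.dpdt_pa, beat.dudt)
        scale = np.max(np.abs(net)) + 1e-12
        np.testing.assert_allclose((sep.wi_forward + sep.wi_backward) / scale,
                                   net / scale, atol=1e-6)
        assert np.all(sep.wi_forward >= 0)
        assert np.all(sep.wi_backward <= 0)

    def test_still_water_splits_pressure_evenly(self):
        beat = beat_from_series(np.full(60, 90.0), np.zeros(60))
        sep = wia.separate_components(beat, 8.0)
        np.testing.assert_allclose(sep.p_forward, 45.0, atol=1e-12)
        np.testing.assert_allclose(sep.p_backward, 45.0, atol=1e-12)

    def test_nonpositive_pws_rejected(self):
        beat = beat_from_series(np.full(60, 90.0), np.zeros(60))
        with pytest.raises(ParameterError):
            wia.separate_components(beat, 0.0)


class TestPwsEstimation:
    def test_exact_water_hammer_identity(self):
        beat, _ = water_hammer_beat(c=8.0)
        pws, diag = wia.estimate_pws(beat, rho=1060.0)
        assert abs(pws - 8.0) < 0.001 * 8.0

    def test_recovery_with_early_reflection(self):
        scn = grid_scenario(pws=9.5, reflection=0.3, delay=0.07)
        rec, _ = synthesize_beat(scn)
        res = analyze_recording(rec)
        assert abs(res["pws"] - 9.5) / 9.5 < 0.01

    def test_zero_velocity_is_estimation_error(self):
        beat = beat_from_series(90 + np.sin(np.linspace(0, 3, 200)), np.zeros(200))
        with pytest.raises(EstimationError):
            wia.estimate_pws(beat)


class TestLandmarks:
    def test_acceleration_time_matches_simulated_ejection(self):
        scn = grid_scenario(pws=8.0, fcw_dur=0.1)  # AcT = lobe duration
        rec, truth = synthesize_beat(scn)
        res = analyze_recording(rec)
        assert abs(res["landmarks"]["act_s"] - truth.expected_act) < 0.004
        assert abs(truth.expected_act - 0.1) < 0.003

    def test_c_is_pressure_maximum(self):
        rec, _ = synthesize_beat(preset_scenario("cad_ht", noise_sd_p=0, noise_sd_u=0))
        from puwave.waveio import lowpass_filter, detect_beats, ensemble_average
        filt = lowpass_filter(rec)
        beat = ensemble_average(filt, detect_beats(filt))
        net = wia.compute_net_wi(beat.dpdt_pa, beat.dudt)
        lm = wia.detect_landmarks(net, beat)
        assert lm.c_idx == lm.b_idx + int(np.argmax(beat.pressure[lm.b_idx:]))
        assert lm.a_idx < lm.b_idx < lm.c_idx < lm.d_idx

    def test_nonpositive_net_wi_is_landmark_error(self):
        beat = beat_from_series(np.linspace(90, 80, 100), np.linspace(0.2, 0, 100))
        net = wia.compute_net_wi(beat.dpdt_pa, beat.dudt)
        with pytest.raises(LandmarkError):
            wia.detect_landmarks(-np.abs(net), beat)


def _full_analysis(scn):
    rec, truth = synthesize_beat(scn)
    return analyze_recording(rec), truth


class TestSegmentationAndTiming:
    def test_no_reflection_means_no_bcw(self):
        res, _ = _full_analysis(grid_scenario(pws=7.0, reflection=0.0))
        assert res["bcw_absent"]
        assert res["waves"]["BCW"]["relative_magnitude"] == 0.0
        assert res["pct_td"] is None

    def test_initial_wave_relative_magnitude_is_one(self):
        res, _ = _full_analysis(grid_scenario(pws=7.0, reflection=0.0))
        assert abs(res["waves"]["initial_FCW"]["relative_magnitude"] - 1.0) < 0.02

    def test_reflection_energy_scales_with_r_squared(self):
        """Cumulative BCW intensity relative to the initial wave equals R^2
        (delayed-copy reflection, near-disjoint windows)."""
        res, truth = _full_analysis(grid_scenario(pws=9.0, reflection=0.3, delay=0.09))
        assert res["waves"]["BCW"]["relative_magnitude"] == pytest.approx(0.09, abs=0.01)

    def test_relative_backward_onset_time(self):
        res, truth = _full_analysis(grid_scenario(pws=8.0, reflection=0.3, delay=0.06))
        assert res["pct_td"] == pytest.approx(truth.expected_pct_td, abs=0.04)

    def test_pct_td_is_td_over_act_exactly(self):
        res, _ = _full_analysis(grid_scenario(pws=8.0, reflection=0.3, delay=0.07))
        assert res["pct_td"] == pytest.approx(res["td_s"] / res["landmarks"]["act_s"],
                                              rel=1e-12)

    def test_amplitude_scaling_leaves_relative_magnitudes_invariant(self):
        base = grid_scenario(pws=8.0, reflection=0.25, delay=0.08, fcw_inc=45.0)
        scaled = grid_scenario(pws=8.0, reflection=0.25, delay=0.08, fcw_inc=90.0)
        r1, _ = _full_analysis(base)
        r2, _ = _full_analysis(scaled)
        for wave in ("BCW", "l_FDW"):
            assert r1["waves"][wave]["relative_magnitude"] == pytest.approx(
                r2["waves"][wave]["relative_magnitude"], rel=0.02)
        assert r1["s2_s1_ratio"] == pytest.approx(r2["s2_s1_ratio"], rel=0.05)


class TestPhaseDeltas:
    def test_constant_beat_has_zero_deltas(self):
        beat = beat_from_series(np.full(200, 90.0), np.zeros(200))
        sep = wia.separate_components(beat, 8.0)
        lm = wia.Landmarks(10, 60, 120, 180, 500.0)
        d = wia.phase_pressure_deltas(sep, lm)
        assert d.dpb_phase1 == d.dpf_phase1 == d.dpb_phase2 == d.dpf_phase2 == 0.0

    def test_group_presets_show_opposite_midsystolic_pf_changes(self):
        non, _ = _full_analysis(preset_scenario("non_cad"))
        cad, _ = _full_analysis(preset_scenario("cad_ht"))
        assert non["phase_deltas"]["dpf2"] < 0
        assert cad["phase_deltas"]["dpf2"] > 0
        assert cad["phase_deltas"]["dpb1"] > 0

    def test_deltas_invariant_to_pressure_offset(self):
        rec, _ = synthesize_beat(grid_scenario(pws=8.0, reflection=0.3, delay=0.07))
        res1 = analyze_recording(rec)
        from puwave.waveio import WaveformRecording
        rec2 = WaveformRecording(rec.time, rec.pressure + 25.0, rec.velocity,
                                 rec.sampling_rate)
        res2 = analyze_recording(rec2)
        for k in ("dpb1", "dpf1", "dpb2", "dpf2"):
            assert res1["phase_deltas"][k] == pytest.approx(
                res2["phase_deltas"][k], abs=0.05)
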