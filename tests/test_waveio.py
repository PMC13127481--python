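"""I/O dialect and signal-conditioning tests."""

import numpy as np
import pytest

from puwave.config import AnalysisConfig
from puwave.errors import DataError, DetectionError, FormatError, ParameterError
from puwave.simulate import preset_scenario, synthesize_beat, write_scenario
from puwave.waveio import (WaveformRecording, correct_velocity_delay, detect_beats,
                           differentiate, ensemble_average, lowpass_filter,
                           read_waveform_csv, write_waveform_csv)

from conftest import grid_scenario


def _recording(p, u, fs=500.0):
    n = len(p)
    return WaveformRecording(np.arange(n) / fs, p, u, sampling_rate=fs)


class TestCsvDialect:
    def test_declared_dialect_roundtrip_is_bit_identical(self, tmp_path):
        rec, truth = synthesize_beat(preset_scenario("non_cad", seed=3))
        csv_path, json_path = write_scenario(rec, truth, tmp_path, stem="s")
        r1 = read_waveform_csv(csv_path)
        assert r1.sampling_rate == 500.0
        write_waveform_csv(r1, tmp_path / "s2.csv")
        r2 = read_waveform_csv(tmp_path / "s2.csv")
        assert np.array_equal(r1.pressure, r2.pressure)
        assert np.array_equal(r1.velocity, r2.velocity)
        assert np.array_equal(r1.time, r2.time)
        # parsed series match the generated ones to the print precision
        np.testing.assert_allclose(r1.pressure, rec.pressure, atol=0)
        assert json_path.exists()

    def test_missing_column_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,pressure_mmHg\n" +
                        "\n".join(f"{i/500},{90+i%3}" for i in range(200)))
        with pytest.raises(FormatError, match="velocity"):
            read_waveform_csv(path)

    def test_nonuniform_grid_rejected(self, tmp_path):
        # time step alternating 1 ms / 3 ms
        t = np.cumsum(np.tile([1e-3, 3e-3], 100))
        path = tmp_path / "nu.csv"
        path.write_text("time_s,pressure_mmHg,velocity_m_s\n" +
                        "\n".join(f"{ti},{90.0},{0.0}" for ti in t))
        with pytest.raises(DataError, match="non-uniform"):
            read_waveform_csv(path)

    def test_nan_names_offending_row(self, tmp_path):
        rows = [f"{i/500},{90.0},{0.1}" for i in range(200)]
        rows[57] = f"{57/500},nan,{0.1}"
        path = tmp_path / "nan.csv"
        path.write_text("time_s,pressure_mmHg,velocity_m_s\n" + "\n".join(rows))
        with pytest.raises(DataError, match="57"):
            read_waveform_csv(path)


class TestLowpass:
    def test_dc_passes_unchanged(self):
        rec = _recording(np.full(1000, 90.0), np.zeros(1000))
        out = lowpass_filter(rec, 62.5)
        np.testing.assert_allclose(out.pressure, 90.0, atol=1e-9)

    def test_passband_gain_and_zero_phase(self):
        fs, f0 = 500.0, 5.0
        t = np.arange(5000) / fs
        x = np.sin(2 * np.pi * f0 * t)
        rec = _recording(90 + x, 0.1 * x, fs)
        out = lowpass_filter(rec, 62.5)
        mid = slice(500, 4500)  # avoid edges
        y = out.pressure[mid] - 90.0
        assert abs(np.ptp(y) / np.ptp(x[mid]) - 1) < 0.01
        # zero phase: cross-correlation peak at zero lag
        xc = np.correlate(y - y.mean(), x[mid] - x[mid].mean(), "full")
        assert abs(int(np.argmax(xc)) - (y.size - 1)) == 0

    def test_stopband_attenuation(self):
        fs = 500.0
        t = np.arange(5000) / fs
        x = np.sin(2 * np.pi * 200.0 * t)
        out = lowpass_filter(_recording(90 + x, np.zeros_like(x), fs), 62.5)
        assert np.ptp(out.pressure[500:4500] - 90) < 0.1 * np.ptp(x)

    def test_cutoff_at_nyquist_rejected(self):
        rec = _recording(np.full(1000, 90.0), np.zeros(1000))
        with pytest.raises(ParameterError):
            lowpass_filter(rec, 250.0)


class TestDelayCorrection:
    def test_zero_delay_is_identity(self):
        rec = _recording(np.full(1000, 90.0), np.linspace(0, 1, 1000))
        out = correct_velocity_delay(rec)
        np.testing.assert_array_equal(out.velocity, rec.velocity)

    def test_4ms_at_500hz_shifts_two_samples(self):
        u = np.arange(1000, dtype=float)
        rec = WaveformRecording(np.arange(1000) / 500, np.full(1000, 90.0), u,
                                500.0, velocity_delay=0.004)
        out = correct_velocity_delay(rec)
        np.testing.assert_array_equal(out.velocity[:-2], u[2:])
        assert out.velocity_delay == 0.0

    def test_excessive_delay_rejected(self):
        rec = WaveformRecording(np.arange(1000) / 500, np.full(1000, 90.0),
                                np.zeros(1000), 500.0, velocity_delay=0.06)
        with pytest.raises(ParameterError):
            correct_velocity_delay(rec)

    def test_filter_and_delay_correction_commute(self):
        rec, _ = synthesize_beat(grid_scenario(noise_p=0.3, noise_u=0.003))
        rec = WaveformRecording(rec.time, rec.pressure, rec.velocity,
                                rec.sampling_rate, velocity_delay=0.006)
        a = correct_velocity_delay(lowpass_filter(rec))
        b = lowpass_filter(correct_velocity_delay(rec))
        # both are LTI on the grid; only the boundary padding differs
        np.testing.assert_allclose(a.velocity[200:-200], b.velocity[200:-200], atol=1e-9)


class TestDifferentiate:
    def test_linear_ramp(self):
        x = np.arange(500) / 500.0 * 10.0  # 10 mmHg per second at 500 Hz
        d = differentiate(x, 500.0)
        np.testing.assert_allclose(d[2:-2], 10.0, rtol=1e-9)

    def test_constant_is_zero(self):
        assert np.all(differentiate(np.full(100, 5.0), 500.0) == 0)

    def test_sine_matches_analytic_derivative(self):
        t = np.arange(2500) / 500.0
        x = np.sin(2 * np.pi * 5 * t)
        d = differentiate(x, 500.0)
        exact = 2 * np.pi * 5 * np.cos(2 * np.pi * 5 * t)
        err = np.max(np.abs(d[5:-5] - exact[5:-5])) / np.max(np.abs(exact))
        assert err < 0.005

    def test_too_short_series_rejected(self):
        with pytest.raises(DataError):
            differentiate(np.array([1.0, 2.0]), 500.0)

    def test_derivative_of_cumulative_sum_reconstructs(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        x_s = np.convolve(x, np.ones(20) / 20, mode="same")  # smooth it
        integral = np.cumsum(x_s) / 500.0
        d = differentiate(integral, 500.0)
        # central difference of a cumsum equals the two-sample average
        np.testing.assert_allclose(d[1:-1], (x_s[1:-1] + x_s[2:]) / 2, atol=1e-9)


class TestBeats:
    def test_six_identical_beats_found_at_cycle_spacing(self):
        scn = grid_scenario(n_beats=6)  # 75 bpm -> 0.8 s cycles
        rec, _ = synthesize_beat(scn)
        beats = detect_beats(lowpass_filter(rec))
        assert beats.foot_indices.size == 6
        rr = np.diff(beats.foot_indices)
        assert np.all(np.abs(rr - 400) <= 1)

    def test_long_cycle_flagged_excluded(self):
        scn = grid_scenario(n_beats=6)
        rec, truth = synthesize_beat(scn)
        # simulate a pause: splice 30 % extra diastole into the 3rd cycle
        n = truth.cycle_samples
        lead = truth.lead_in_samples
        cut = lead + 3 * n
        pad = int(0.3 * n)
        p = np.concatenate([rec.pressure[:cut], np.full(pad, rec.pressure[cut - 1]),
                            rec.pressure[cut:]])
        u = np.concatenate([rec.velocity[:cut], np.full(pad, rec.velocity[cut - 1]),
                            rec.velocity[cut:]])
        rec2 = WaveformRecording(np.arange(p.size) / 500, p, u, 500.0)
        beats = detect_beats(lowpass_filter(rec2))
        assert not beats.included[2]
        assert 2 in beats.exclusion_reasons

    def test_constant_pressure_is_detection_error(self):
        rec = _recording(np.full(2000, 90.0), np.zeros(2000))
        with pytest.raises((DetectionError, DataError)):
            detect_beats(rec)


class TestEnsemble:
    def test_mean_of_identical_beats_is_a_single_beat(self):
        rec, truth = synthesize_beat(grid_scenario(n_beats=7))
        filt = lowpass_filter(rec)
        beats = detect_beats(filt)
        beat = ensemble_average(filt, beats, n_beats=5)
        f = beats.foot_indices[1]
        pre = beat.foot_offset
        seg = filt.pressure[f - pre:f - pre + beat.n_samples]
        np.testing.assert_allclose(beat.pressure, seg, atol=1e-9)

    def test_noise_reduced_by_sqrt_n(self):
        def residual_sd(nb, seed):
            rec, _ = synthesize_beat(
                grid_scenario(n_beats=nb + 3, noise_p=1.0, seed=seed))
            filt = lowpass_filter(rec)
            beat = ensemble_average(filt, detect_beats(filt), n_beats=nb)
            # detrended early-window baseline (diastolic ramp + quiet gap)
            seg = beat.pressure[5:40]
            x = np.arange(seg.size)
            fit = np.polyval(np.polyfit(x, seg, 1), x)
            return np.std(seg - fit)

        sds = [np.mean([residual_sd(nb, s) for s in range(6)]) for nb in (1, 5)]
        ratio = sds[0] / sds[1]
        assert abs(ratio - np.sqrt(5)) / np.sqrt(5) < 0.35

    def test_insufficient_beats_reports_count(self):
        rec, _ = synthesize_beat(grid_scenario(n_beats=3))
        filt = lowpass_filter(rec)
        beats = detect_beats(filt)
        with pytest.raises(DataError, match=r"\d+ usable beats"):
            ensemble_average(filt, beats, n_beats=5)
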