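"""Stimulus generators: calibration, determinism, shapes, errors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from monaural import stimuli as stim

FS = 48000.0


class TestPureTone:
    @pytest.mark.parametrize("level, rms_pa", [(100.0, 2.0), (40.0, 2e-3)])
    def test_rms_calibration(self, level, rms_pa):
        t = stim.make_pure_tone(1000.0, 0.1, level, 0.01, FS)
        core = t.samples[int(0.01 * FS):-int(0.01 * FS)]
        assert np.sqrt(np.mean(core**2)) == pytest.approx(rms_pa, rel=1e-3)

    @given(freq=st.floats(min_value=100.0, max_value=8000.0),
           level=st.floats(min_value=0.0, max_value=100.0))
    @settings(max_examples=25, derandomize=True)
    def test_calibration_within_005_db(self, freq, level):
        t = stim.make_pure_tone(freq, 0.1, level, 0.01, FS)
        assert t.measured_spl() == pytest.approx(level, abs=0.05)

    def test_rectangular_gating_peak(self):
        t = stim.make_pure_tone(1000.0, 0.1, 94.0, 0.0, FS)
        assert np.max(np.abs(t.samples)) == pytest.approx(
            t.rms() * np.sqrt(2.0), rel=1e-3)

    def test_ramps_never_increase_peak(self):
        flat = stim.make_pure_tone(500.0, 0.1, 70.0, 0.0, FS)
        ramped = stim.make_pure_tone(500.0, 0.1, 70.0, 0.02, FS)
        assert np.max(np.abs(ramped.samples)) <= np.max(np.abs(flat.samples)) \
            * (1 + 1e-12)

    @pytest.mark.parametrize("kwargs", [
        dict(freq=30000.0), dict(dur=-0.1), dict(ramp_dur=0.06),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        args = dict(freq=1000.0, dur=0.1, level_db=60.0, ramp_dur=0.005,
                    fs=FS)
        args.update(kwargs)
        with pytest.raises(ValueError):
            stim.make_pure_tone(**args)


class TestAmTone:
    def test_zero_modulation_equals_pure_tone(self):
        am = stim.make_am_tone(4000.0, 100.0, 0.0, 0.1, 60.0, 0.005, FS)
        pt = stim.make_pure_tone(4000.0, 0.1, 60.0, 0.005, FS)
        assert np.allclose(am.samples, pt.samples)

    def test_envelope_period_10_ms_at_100_hz(self):
        am = stim.make_am_tone(4000.0, 100.0, 1.0, 0.5, 60.0, 0.0025, FS)
        # envelope maxima of the analytic magnitude repeat every 10 ms
        env = np.abs(am.samples[int(0.1 * FS):int(0.4 * FS)])
        spec = np.abs(np.fft.rfft(env**2))
        f = np.fft.rfftfreq(len(env), 1 / FS)
        search = (f > 5.0) & (f < 200.0)
        peak = f[search][np.argmax(spec[search])]
        assert peak == pytest.approx(100.0, abs=1.0)

    @given(m=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=20, derandomize=True)
    def test_calibration_independent_of_depth(self, m):
        am = stim.make_am_tone(4000.0, 100.0, m, 0.2, 60.0, 0.005, FS)
        assert am.measured_spl() == pytest.approx(60.0, abs=0.05)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            stim.make_am_tone(4000.0, 100.0, 1.2, 0.1, 60.0, 0.005, FS)


class TestFrozenNoise:
    def test_same_seed_bit_identical(self):
        a = stim.make_frozen_noise(1.0, 40.0, seed=7)
        b = stim.make_frozen_noise(1.0, 40.0, seed=7)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(
            a.samples, stim.make_frozen_noise(1.0, 40.0, seed=8).samples)

    def test_calibration(self):
        n = stim.make_frozen_noise(3.0, 40.0)
        assert n.rms() == pytest.approx(2e-3, rel=2e-3)

    def test_third_octave_flatness(self):
        n = stim.make_frozen_noise(3.0, 40.0)
        spec = np.abs(np.fft.rfft(n.samples))**2
        f = np.fft.rfftfreq(len(n.samples), 1 / FS)
        centers = 1000.0 * 2.0 ** (np.arange(-10, 11) / 3.0)  # 99-10079 Hz
        levels = []
        for fc in centers:
            band = (f >= fc * 2**(-1 / 6)) & (f < fc * 2**(1 / 6))
            levels.append(10 * np.log10(np.mean(spec[band])))
        levels = np.array(levels)
        assert np.max(levels) - np.min(levels) < 2.0  # within +-1 dB


class TestClickTrain:
    def test_amplitude_at_70_db_pespl(self):
        t = stim.make_click_train(pe_spl=70.0)
        assert np.max(t.samples) == pytest.approx(0.1789, abs=5e-4)

    def test_exactly_ten_clicks_with_alternation(self):
        t = stim.make_click_train(rate=10.0, dur=1.0, fs=FS)
        active = np.abs(t.samples) > 0
        onsets = np.flatnonzero(active & ~np.concatenate([[False],
                                                          active[:-1]]))
        assert len(onsets) == 10
        # the 9th click is +A, the 10th is -A
        a = np.max(t.samples)
        assert t.samples[int(0.8 * FS)] == pytest.approx(a)
        assert t.samples[int(0.9 * FS)] == pytest.approx(-a)

    def test_click_duration_validation(self):
        with pytest.raises(ValueError):
            stim.make_click_train(click_dur=1e-6, fs=8000.0)
        with pytest.raises(ValueError):
            stim.make_click_train(rate=10.0, click_dur=0.2)


class TestComplexTone:
    def test_equal_component_peak_amplitudes(self):
        ct = stim.make_complex_tone([414.0, 650.0, 1000.0], 50.0, 1.0,
                                    0.005, FS)
        spec = np.abs(np.fft.rfft(ct.samples))
        f = np.fft.rfftfreq(len(ct.samples), 1 / FS)
        amps = [spec[np.argmin(np.abs(f - f0))] for f0 in (414, 650, 1000)]
        assert np.ptp(amps) / np.mean(amps) < 0.01

    def test_total_rms_calibrated(self):
        ct = stim.make_complex_tone([414.0, 650.0, 1000.0], 50.0, 0.3,
                                    0.005, FS)
        assert ct.measured_spl() == pytest.approx(50.0, abs=0.05)

    def test_single_component_equals_pure_tone(self):
        ct = stim.make_complex_tone([1000.0], 60.0, 0.1, 0.005, FS)
        pt = stim.make_pure_tone(1000.0, 0.1, 60.0, 0.005, FS)
        assert np.allclose(ct.samples, pt.samples)

    def test_empty_component_list_rejected(self):
        with pytest.raises(ValueError):
            stim.make_complex_tone([], 50.0, 0.1)


class TestLevelConvention:
    def test_half_amplitude_models_attenuated_6_db(self):
        t = stim.make_pure_tone(1000.0, 0.05, 70.0, 0.005, FS)
        for label in ("dau1997", "king2019", "osses2021"):
            s = stim.apply_model_level_convention(t, label)
            assert np.allclose(s.samples, 0.5 * t.samples)

    def test_pascal_convention_models_unchanged(self):
        t = stim.make_pure_tone(1000.0, 0.05, 70.0, 0.005, FS)
        s = stim.apply_model_level_convention(t, "zilany2014")
        assert np.array_equal(s.samples, t.samples)

    def test_double_application_rejected(self):
        t = stim.make_pure_tone(1000.0, 0.05, 70.0, 0.005, FS)
        s = stim.apply_model_level_convention(t, "dau1997")
        with pytest.raises(ValueError):
            stim.apply_model_level_convention(s, "dau1997")


class TestWavRoundTrip:
    def test_pressure_waveform_survives(self, tmp_path):
        t = stim.make_pure_tone(1000.0, 0.05, 70.0, 0.005, FS)
        path = tmp_path / "tone.wav"
        stim.write_wav(path, t)
        back = stim.read_wav(path, level_db=70.0)
        assert back.fs == FS
        assert np.allclose(back.samples, t.samples, atol=1e-7)
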