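"""Chain execution and the evaluation battery procedures."""

import numpy as np
import pytest

from monaural import chains, evaluation as ev
from monaural.maps import erb_n, greenwood_cf, q_erb
from monaural.stimuli import (apply_model_level_convention, make_click_train,
                              make_pure_tone)

FS = 48000.0


class TestRunChain:
    def test_deterministic(self, dau_cfg):
        tone = make_pure_tone(1000.0, 0.05, 60.0, 0.005, FS)
        y1 = chains.run_chain(tone, dau_cfg.with_cfs([1000.0]), "an")
        y2 = chains.run_chain(tone, dau_cfg.with_cfs([1000.0]), "an")
        assert np.array_equal(y1, y2)

    def test_cochlea_tap_is_gammatone_output(self, dau_cfg):
        from monaural.frontend import GammatoneSpec, gammatone_filterbank
        tone = make_pure_tone(1000.0, 0.05, 60.0, 0.005, FS)
        y = chains.run_chain(tone, dau_cfg.with_cfs([1000.0]), "cochlea")
        scaled = apply_model_level_convention(tone, "dau1997")
        ref = gammatone_filterbank(scaled, GammatoneSpec(cfs=[1000.0], fs=FS))
        assert np.allclose(y, ref)

    def test_unknown_tap_rejected(self, dau_cfg):
        tone = make_pure_tone(1000.0, 0.05, 60.0, 0.005, FS)
        with pytest.raises(ValueError):
            chains.run_chain(tone, dau_cfg, "cortex")

    def test_level_convention_applied_exactly_once(self, dau_cfg):
        tone = make_pure_tone(1000.0, 0.05, 60.0, 0.005, FS)
        pre = apply_model_level_convention(tone, "dau1997")
        direct = chains.run_chain(tone, dau_cfg.with_cfs([1000.0]), "cochlea")
        explicit = chains.run_chain(pre, dau_cfg.with_cfs([1000.0]),
                                    "cochlea")
        assert np.allclose(direct, explicit)
        other = apply_model_level_convention(tone, "king2019")
        with pytest.raises(ValueError):
            chains.run_chain(other, dau_cfg, "cochlea")

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            chains.preset("zilany2014")


class TestIOCurves:
    def test_linear_chain_has_unit_slope_at_all_offsets(self, dau_cfg):
        for freq in (500.0, 4000.0):
            curves = ev.io_curves(dau_cfg, freq,
                                  levels=np.arange(0.0, 100.1, 20.0))
            for c in curves.values():
                assert np.allclose(c.slopes(), 1.0, atol=1e-6)

    def test_broken_stick_chain_compresses_above_knee(self, king_cfg):
        curves = ev.io_curves(king_cfg, 4000.0,
                              levels=np.arange(50.0, 100.1, 10.0))
        assert np.allclose(curves["on"].slopes(), 0.3, atol=0.01)

    def test_reference_tone_maps_to_100_db(self, dau_cfg):
        g = ev.chain_reference_gain(dau_cfg)
        curves = ev.io_curves(dau_cfg, 1000.0, levels=[100.0])
        assert curves["on"].out_levels[0] == pytest.approx(100.0, abs=0.05)
        assert g == pytest.approx(100.0, abs=0.5)


class TestExcitationPattern:
    def test_peak_at_stimulus_cf_and_linearity(self, dau_cfg):
        from monaural.maps import erbspace
        cfs = erbspace(80.0, 8000.0)
        g = ev.chain_reference_gain(dau_cfg)
        p40 = ev.excitation_pattern(
            dau_cfg, make_pure_tone(500.0, 0.1, 40.0, 0.01, FS), cfs, g)
        p100 = ev.excitation_pattern(
            dau_cfg, make_pure_tone(500.0, 0.1, 100.0, 0.01, FS), cfs, g)
        assert abs(cfs[np.argmax(p40)] - 500.0) < erb_n(500.0)
        assert np.allclose(p100 - p40, 60.0, atol=1e-6)

    def test_consistent_with_io_curves(self, dau_cfg):
        from monaural.maps import cf_offsets_one_erb
        below, above = cf_offsets_one_erb(1000.0)
        tone = make_pure_tone(1000.0, 0.1, 70.0, 0.01, FS)
        g = ev.chain_reference_gain(dau_cfg)
        pattern = ev.excitation_pattern(dau_cfg, tone,
                                        [1000.0, below, above], g)
        curves = ev.io_curves(dau_cfg, 1000.0, levels=[70.0])
        io_levels = [curves["on"].out_levels[0],
                     curves["-1erb"].out_levels[0],
                     curves["+1erb"].out_levels[0]]
        assert np.allclose(pattern, io_levels, atol=1e-9)


class TestQEstimation:
    def test_linear_chain_tracks_broad_tuning(self, dau_q40):
        # Q_-3dB of a 1-ERB gammatone is ~13% above Q_ERB (the -3 dB
        # width is 0.887 ERB); the estimates must follow the broad
        # tuning curve, far below the sharp-tuning convention
        mid = [q for q in dau_q40 if 500.0 <= q.cf <= 4000.0]
        assert len(mid) >= 8
        for q in mid:
            assert q.q == pytest.approx(q_erb(q.cf, "broad") / 0.887,
                                        rel=0.10)
            assert q.q < 0.75 * q_erb(q.cf, "sharp")

    def test_level_invariance_of_linear_chain(self, dau_cfg, dau_q40,
                                              q_sections_cfs):
        from monaural.stimuli import make_frozen_noise
        noise100 = make_frozen_noise(3.0, 100.0)
        q100 = ev.estimate_q3db(dau_cfg, q_sections_cfs, noise100)
        for a, b in zip(dau_q40, q100):
            assert a.q == pytest.approx(b.q, rel=1e-6)

    def test_measured_bandwidth_near_09_erb(self, dau_q40):
        bw = np.mean([q.bw_erb for q in dau_q40])
        assert bw == pytest.approx(0.90, abs=0.03)


class TestCountFilters:
    def test_constant_q_bank_matches_geometric_covering(self):
        # independent oracle: for constant Q the greedy covering is a
        # geometric sequence; enumerate it directly
        q0 = 5.0
        ests = [ev.QEstimate(cf, cf / q0, 40.0)
                for cf in (100.0, 1000.0, 10000.0)]
        count, mean_bw = ev.count_filters(ests, 126.0, 8000.0)
        cf, n_oracle = 126.0, 0
        while True:
            n_oracle += 1
            upper = cf * (2 * q0 + 1) / (2 * q0)
            if upper >= 8000.0:
                break
            cf = upper * (2 * q0) / (2 * q0 - 1)
        assert count == n_oracle
        ref = np.mean([(cf / q0) / erb_n(cf) for cf in
                       [126.0 * ((2 * q0 + 1) / (2 * q0 - 1)) ** k
                        for k in range(count)]])
        assert mean_bw == pytest.approx(ref, rel=1e-6)


class TestRateLevel:
    def test_onset_at_least_steady_everywhere(self, dau_cfg, king_cfg):
        for cfg in (dau_cfg, king_cfg):
            rl = ev.rate_level_curves(
                cfg, levels=np.arange(0.0, 100.1, 25.0))
            assert np.all(rl.onset >= rl.steady - 1e-12)

    def test_dau_onset_saturates_above_50_db(self, dau_cfg):
        rl = ev.rate_level_curves(dau_cfg,
                                  levels=np.array([60.0, 80.0, 100.0]))
        assert np.ptp(rl.onset) / rl.onset.mean() < 0.01

    def test_king_steady_strictly_increasing(self, king_cfg):
        rl = ev.rate_level_curves(king_cfg,
                                  levels=np.arange(10.0, 100.1, 10.0))
        assert np.all(np.diff(rl.steady) > 0)


class TestSynchronyCapture:
    def test_off_cf_fluctuation_exceeds_on_cf(self, dau_cfg):
        r = ev.synchrony_fluctuation(dau_cfg)
        assert r.on_cf.sum() == 3 and (~r.on_cf).sum() == 4
        assert r.mean_off > r.mean_on

    def test_silent_channels_report_zero(self, dau_cfg):
        from monaural.stimuli import Stimulus
        silence = Stimulus(np.zeros(int(0.3 * FS)), FS, 0.0, 0.0, "silence")
        r = ev.synchrony_fluctuation(dau_cfg, stim=silence)
        assert np.allclose(r.metric, 0.0)


class TestMTF:
    def test_normalized_maximum_is_one(self, dau_cfg):
        mtf = ev.mtf_experiment(dau_cfg, fmods=[40.0, 70.0, 100.0])
        assert mtf.gains.max() == 1.0

    def test_bandpass_shape_for_all_chains(self, dau_cfg, osses_cfg,
                                           king_cfg):
        for cfg in (dau_cfg, osses_cfg, king_cfg):
            mtf = ev.mtf_experiment(cfg, fmods=[10.0, 40.0, 70.0, 130.0])
            assert mtf.gains[0] < 1.0 and mtf.gains[-1] < 1.0


class TestClickResponse:
    def test_broadband_nonnegative_and_polarity(self, dau_cfg, king_cfg):
        train = make_click_train(fs=FS)
        for cfg in (dau_cfg, king_cfg):
            r = ev.click_abr_response(cfg, train)
            assert np.all(r.waveform >= 0.0)
            assert r.p2p_neg > r.p2p_pos

    def test_dau_p2p_near_published_amplitudes(self, dau_cfg):
        r = ev.click_abr_response(dau_cfg, make_click_train(fs=FS))
        assert r.p2p_pos == pytest.approx(407.3, rel=0.15)
        assert r.p2p_neg == pytest.approx(437.4, rel=0.15)
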