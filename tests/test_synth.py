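import numpy as np
import pytest

from helpers import power_fraction_below
from trfaad.core import Condition, TimeSeriesBlock
from trfaad.errors import InvalidArgumentError
from trfaad.synth import (
    GroundTruth,
    SimulationConfig,
    _convolve_kernel,
    default_ground_truth,
    synthesize_envelope,
    synthesize_kernel,
    synthesize_probe_audio,
    synthesize_session,
    synthesize_trial,
)
from trfaad.trf import pearson_r

from conftest import small_sim_config


class TestEnvelope:
    def test_sample_count_and_nonnegativity(self):
        env = synthesize_envelope(180, 50, seed=1)
        assert env.n_samples == 9000
        assert np.all(env.data >= 0)

    def test_seed_determinism(self):
        a = synthesize_envelope(10, 50, seed=7)
        b = synthesize_envelope(10, 50, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_spectral_content_below_10hz(self):
        env = synthesize_envelope(60, 50, seed=3)
        assert power_fraction_below(env.data[0], 50, 10.0) > 0.8

    @pytest.mark.parametrize("duration,fs", [(-1, 50), (0, 50), (10, 0)])
    def test_invalid_arguments(self, duration, fs):
        with pytest.raises(InvalidArgumentError):
            synthesize_envelope(duration, fs, seed=0)

    def test_different_seeds_differ(self):
        a = synthesize_envelope(10, 50, seed=1)
        b = synthesize_envelope(10, 50, seed=2)
        assert not np.array_equal(a.data, b.data)


class TestKernel:
    def test_single_centered_peak(self):
        k = synthesize_kernel([(0.0, 1.0, 10.0)], (-0.1, 0.1), 500, [1.0])
        assert k.lags[np.argmax(k.coefs[:, 0])] == pytest.approx(0.0)

    def test_three_peak_morphology(self):
        k = synthesize_kernel(
            [(40, 0.5, 20), (100, -1.0, 25), (180, 0.8, 35)], (-0.1, 0.4), 500, [1.0]
        )
        kern = k.coefs[:, 0]
        # exactly one negative extremum, located at 100 ms
        from scipy.signal import argrelextrema

        minima = argrelextrema(kern, np.less)[0]
        minima = minima[kern[minima] < -1e-6]
        assert len(minima) == 1
        assert k.lags[minima[0]] * 1000 == pytest.approx(100, abs=2)

    def test_empty_spec_gives_zero_kernel(self):
        k = synthesize_kernel([], (-0.1, 0.1), 500, [1.0, 2.0])
        assert not np.any(k.coefs)

    def test_latency_outside_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthesize_kernel([(500.0, 1.0, 10.0)], (-0.1, 0.4), 500, [1.0])

    def test_zero_outside_four_widths(self):
        k = synthesize_kernel([(0.0, 1.0, 10.0)], (-0.5, 0.5), 500, [1.0])
        far = np.abs(k.lags) > 4 * 0.010
        assert not np.any(k.coefs[far, 0])

    def test_topography_scaling(self):
        k = synthesize_kernel([(50, 1.0, 10)], (0, 0.1), 500, [1.0, 0.5])
        np.testing.assert_allclose(k.coefs[:, 1], 0.5 * k.coefs[:, 0])


class TestTrial:
    def test_switac_schedule(self):
        cfg = small_sim_config(trial_duration=180, switch_window_1=(35, 55),
                               switch_window_2=(125, 145))
        truth = default_ground_truth(cfg)
        trial = synthesize_trial(cfg, truth, "SwitAC", seed=11)
        assert len(trial.schedule) == 3
        sw1, sw2 = trial.switch_times
        assert 35 <= sw1 <= 55
        assert 125 <= sw2 <= 145

    def test_sustac_single_segment(self):
        cfg = small_sim_config()
        truth = default_ground_truth(cfg)
        trial = synthesize_trial(cfg, truth, "SustAC", seed=3, attended_stream="s1")
        assert trial.schedule == [(0.0, cfg.trial_duration, "s1")]

    def test_high_snr_matches_direct_convolution(self):
        cfg = small_sim_config(
            n_scalp_channels=1, n_ceegrid_channels=0, snr_db=60,
            attention_gain=1e-6, trial_duration=30,
        )
        truth = default_ground_truth(cfg)
        truth.channel_topography[:] = 1.0
        truth.attended_kernel.coefs[:, 0] = truth.attended_kernel.coefs[:, 0]
        trial = synthesize_trial(cfg, truth, "SustAC", seed=5, attended_stream="s1")
        direct = _convolve_kernel(trial.streams["s1"].values, truth.attended_kernel)
        assert pearson_r(trial.eeg.data[0], direct[0]) > 0.99

    def test_unknown_condition_rejected(self):
        cfg = small_sim_config()
        truth = default_ground_truth(cfg)
        with pytest.raises(InvalidArgumentError):
            synthesize_trial(cfg, truth, "Nonsense", seed=0)

    def test_snr_contract(self):
        cfg = small_sim_config(snr_db=3.0, trial_duration=30)
        truth = default_ground_truth(cfg)
        trial = synthesize_trial(cfg, truth, "SustAC", seed=2, attended_stream="s1")
        # reconstruct the clean part from streams + truth
        n = trial.eeg.n_samples
        clean = np.zeros_like(trial.eeg.data)
        for name in ("s1", "s2"):
            env = trial.streams[name].values
            if name == "s1":
                clean += _convolve_kernel(env, truth.attended_kernel)
            else:
                clean += cfg.attention_gain * _convolve_kernel(env, truth.ignored_kernel)
        noise = trial.eeg.data - clean
        realized = 10 * np.log10(np.mean(clean**2) / np.mean(noise**2))
        assert abs(realized - 3.0) < 1.0

    def test_control_stream_independent(self):
        cfg = small_sim_config(snr_db=20, trial_duration=60)
        truth = default_ground_truth(cfg)
        trial = synthesize_trial(cfg, truth, "SustAC", seed=9)
        n = trial.eeg.n_samples
        rho = pearson_r(trial.eeg.data[0], trial.streams["control"].values)
        assert abs(rho) < 3 / np.sqrt(n)

    def test_attention_asymmetry_in_expectation(self):
        cfg = small_sim_config(
            n_scalp_channels=2, n_ceegrid_channels=0, snr_db=10,
            attention_gain=0.4, trial_duration=30,
        )
        truth = default_ground_truth(cfg)
        att_peaks, ign_peaks = [], []
        for seed in range(20):
            trial = synthesize_trial(cfg, truth, "SustAC", seed=seed,
                                     attended_stream="s1")
            eeg = trial.eeg.data[0]
            for name, out in (("s1", att_peaks), ("s2", ign_peaks)):
                env = trial.streams[name].values
                xc = np.correlate(eeg - eeg.mean(), env - env.mean(), mode="same")
                out.append(np.abs(xc).max())
        assert np.mean(att_peaks) > np.mean(ign_peaks)


class TestSession:
    def test_default_trial_counts(self):
        cfg = SimulationConfig(n_scalp_channels=4, n_ceegrid_channels=2, seed=1)
        session = synthesize_session(cfg, seed=1)
        assert len(session) == 25
        assert len(session.by_condition("SustAC")) == 8
        assert len(session.by_condition("SwitAC")) == 8
        assert len(session.by_condition("ConvAC")) == 9

    def test_seed_determinism(self):
        cfg = small_sim_config(trial_counts={"SustAC": 1, "SwitAC": 1, "ConvAC": 1})
        a = synthesize_session(cfg, seed=4)
        b = synthesize_session(cfg, seed=4)
        for ta, tb in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta.eeg.data, tb.eeg.data)
            assert ta.schedule == tb.schedule
            for name in ta.streams:
                np.testing.assert_array_equal(
                    ta.streams[name].values, tb.streams[name].values
                )

    def test_restricted_trial_counts(self):
        cfg = small_sim_config(trial_counts={"SustAC": 2, "SwitAC": 0, "ConvAC": 0})
        session = synthesize_session(cfg, seed=0)
        assert len(session) == 2
        assert all(t.condition == Condition.SustAC for t in session)

    def test_montage_split(self, mini_session):
        cfg, session = mini_session
        assert len(session.montage.scalp) == cfg.n_scalp_channels
        assert len(session.montage.ceegrid) == cfg.n_ceegrid_channels

    def test_convac_streams(self, mini_session):
        _, session = mini_session
        conv_trials = [session.trials[i] for i in session.by_condition("ConvAC")]
        for trial in conv_trials:
            assert set(trial.streams) == {"conv", "side", "control"}
            assert len(trial.schedule) == 1


class TestGroundTruth:
    def test_ignored_peak_not_larger(self):
        cfg = small_sim_config()
        truth = default_ground_truth(cfg)
        assert (
            np.abs(truth.ignored_kernel.coefs).max()
            <= np.abs(truth.attended_kernel.coefs).max() + 1e-12
        )

    def test_mismatched_lag_grids_rejected(self):
        k1 = synthesize_kernel([(50, 1, 10)], (0, 0.2), 500, [1.0])
        k2 = synthesize_kernel([(50, 1, 10)], (0, 0.3), 500, [1.0])
        with pytest.raises(InvalidArgumentError):
            GroundTruth(k1, k2, np.ones(1))

    def test_ceegrid_attenuation(self):
        cfg = small_sim_config(n_scalp_channels=6, n_ceegrid_channels=6)
        truth = default_ground_truth(cfg)
        scalp_mean = np.abs(truth.channel_topography[:6]).mean()
        grid_mean = np.abs(truth.channel_topography[6:]).mean()
        assert grid_mean < scalp_mean


class TestProbeAudio:
    def test_pure_tone_peak(self):
        from helpers import dominant_frequency

        tone = synthesize_probe_audio("pure_tone", f0=1000, duration=1, fs=44100)
        assert dominant_frequency(tone.data[0], 44100, fmin=10) == pytest.approx(
            1000, abs=2
        )

    def test_silence(self):
        s = synthesize_probe_audio("silence", duration=1, fs=44100)
        assert not np.any(s.data)

    def test_am_noise_envelope_modulation(self):
        from scipy.signal import hilbert, periodogram

        block = synthesize_probe_audio("am_noise", fm=4, duration=10, fs=8000)
        env = np.abs(hilbert(block.data[0]))
        f, p = periodogram(env - env.mean(), 8000)
        keep = (f > 0.5) & (f < 50)
        assert f[keep][np.argmax(p[keep])] == pytest.approx(4.0, abs=0.5)

    def test_aliasing_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthesize_probe_audio("pure_tone", f0=30000, duration=1, fs=44100)
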