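import numpy as np
import pytest

from canicoh import eeg, synth
from canicoh.eeg import (
    EEGRecording,
    EpochSet,
    bandpass_notch,
    decode_envelope,
    peak_power_frequency,
    preprocess_epochs,
    tf_power,
)
from canicoh.errors import (
    InsufficientDataError,
    InvalidArgumentError,
    InvalidInputError,
)

SR = 500.0


@pytest.fixture(scope="module")
def clean_recording():
    rng = np.random.default_rng(0)
    n = int(SR * 60)
    data = np.vstack([synth.one_over_f_noise(n, 1.0, rng) for _ in range(2)])
    events = [(int(SR * (2 + 3 * i)), "normal") for i in range(15)]
    return EEGRecording(channels=["Cz", "C3"], data=data, sample_rate=SR,
                        events=events)


class TestPreprocess:
    def test_clean_recording_keeps_all_trials(self, clean_recording):
        ep = preprocess_epochs(clean_recording, "Cz", species="dog",
                               epoch_dur_s=2.0)
        assert ep.n_kept == ep.n_trials == 15
        assert ep.t0_s == -1.0

    def test_spike_trial_dropped(self, clean_recording):
        """Constructed outlier: brute-force z confirms only that trial trips."""
        data = clean_recording.data.copy()
        onset = clean_recording.events[3][0]
        data[0, onset + 100 : onset + 120] += 10 * np.abs(data[0]).max()
        rec = EEGRecording(channels=["Cz", "C3"], data=data, sample_rate=SR,
                          events=clean_recording.events)
        ep = preprocess_epochs(rec, "Cz", species="dog", epoch_dur_s=2.0)
        assert list(np.where(~ep.kept_mask)[0]) == [3]
        # brute-force z on the returned trials agrees with the mask
        mu, sd = ep.trials.mean(), ep.trials.std()
        zmax = np.max(np.abs(ep.trials - mu) / sd, axis=1)
        assert np.array_equal(ep.kept_mask, zmax <= 6.0)

    def test_50hz_line_attenuated(self):
        t = np.arange(int(SR * 30)) / SR
        probe = np.sin(2 * np.pi * 50 * t) + 0.1 * np.sin(2 * np.pi * 10 * t)
        rec = EEGRecording(channels=["Cz"], data=probe[None, :], sample_rate=SR,
                          events=[(int(SR * 2), "x")])
        ep = preprocess_epochs(rec, "Cz", species="dog", epoch_dur_s=2.0,
                              z_cutoff=99.0)
        seg = ep.trials[0]
        spec = np.abs(np.fft.rfft(seg))
        freqs = np.fft.rfftfreq(seg.size, 1 / SR)
        line = spec[np.argmin(np.abs(freqs - 50.0))]
        keep = spec[np.argmin(np.abs(freqs - 10.0))]
        assert 20 * np.log10(keep / max(line, 1e-12)) >= 20.0

    def test_missing_channel_raises(self, clean_recording):
        with pytest.raises(InvalidInputError):
            preprocess_epochs(clean_recording, "Pz")

    def test_no_events_raises(self, clean_recording):
        rec = EEGRecording(channels=["Cz"], data=clean_recording.data[:1],
                          sample_rate=SR, events=[])
        with pytest.raises(InvalidInputError):
            preprocess_epochs(rec, "Cz")

    def test_human_average_reference(self):
        rng = np.random.default_rng(1)
        n = int(SR * 20)
        base = rng.standard_normal(n)
        # common-mode signal should vanish under average reference
        data = np.vstack([base + rng.standard_normal(n) * 0.1 for _ in range(4)])
        events = [(int(SR * 2), "x"), (int(SR * 6), "x"), (int(SR * 10), "x")]
        rec = EEGRecording(channels=list("ABCD"), data=data, sample_rate=SR,
                          events=events)
        ep_ref = preprocess_epochs(rec, "A", species="human", epoch_dur_s=2.0,
                                  z_cutoff=99.0)
        ep_raw = preprocess_epochs(rec, "A", species="human", epoch_dur_s=2.0,
                                  z_cutoff=99.0, rereference=False)
        assert ep_ref.trials.std() < 0.5 * ep_raw.trials.std()

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(2)
        x0 = synth.one_over_f_noise(int(SR * 30), 1.0, rng)
        x1 = bandpass_notch(x0, SR)
        x2 = bandpass_notch(x1, SR)
        rms1 = np.sqrt(np.mean(x1**2))
        rms2 = np.sqrt(np.mean(x2**2))
        assert abs(rms2 - rms1) / rms1 < 0.01


@pytest.fixture(scope="module")
def locked_epochs_with_baseline():
    sr = 100.0
    t = np.arange(int(2.0 * sr)) / sr
    env = 1.0 + 0.5 * np.sin(2 * np.pi * 3.0 * t)
    return synth.gen_locked_eeg(
        synth.LockedEEGSpec(envelope=env, coupling=3.0, n_trials=15,
                            sample_rate=sr, seed=2, pre_s=1.0, lag_s=0.0)
    )


class TestTFPower:
    def test_post_onset_peak_at_locked_frequency(self, locked_epochs_with_baseline):
        tfr = tf_power(locked_epochs_with_baseline,
                       freqs_hz=np.arange(1.0, 10.5, 0.5))
        post = tfr.power[:, tfr.times_s > 0.3]
        f_idx, _ = np.unravel_index(np.argmax(post), post.shape)
        assert tfr.freqs_hz[f_idx] == pytest.approx(3.0, abs=0.5)

    def test_stationary_noise_relative_power_near_zero(self):
        sr = 100.0
        vals = []
        env = np.ones(int(2.0 * sr))
        for seed in range(20):
            ep = synth.gen_locked_eeg(synth.LockedEEGSpec(
                envelope=env, coupling=0.0, n_trials=100, sample_rate=sr,
                seed=seed, pre_s=1.0))
            tfr = tf_power(ep, freqs_hz=np.arange(2.0, 10.0, 1.0))
            vals.append(tfr.power.mean())
        assert abs(np.mean(vals)) < 0.05

    def test_zscore_map_standardised(self, locked_epochs_with_baseline):
        tfr = tf_power(locked_epochs_with_baseline,
                       freqs_hz=np.arange(1.0, 10.5, 0.5),
                       normalization="zscore")
        assert tfr.power.mean() == pytest.approx(0.0, abs=1e-9)
        assert tfr.power.std() == pytest.approx(1.0, abs=1e-9)

    def test_empty_epochs_rejected(self):
        ep = EpochSet(trials=np.zeros((2, 100)), sample_rate=100.0,
                      kept_mask=np.zeros(2, dtype=bool))
        with pytest.raises(InvalidInputError):
            tf_power(ep)


class TestPeakPowerFrequency:
    def _tfr(self, power, freqs, times):
        from canicoh.eeg import TFR
        return TFR(times_s=times, freqs_hz=freqs, power=power)

    def test_locked_frequency_recovered(self, locked_epochs_with_baseline):
        tfr = tf_power(locked_epochs_with_baseline,
                       freqs_hz=np.arange(1.0, 8.0, 0.25))
        assert peak_power_frequency(tfr, window_s=(0.0, 1.3)) == pytest.approx(
            3.0, abs=0.25
        )

    def test_tie_returns_lowest(self):
        freqs = np.arange(1.0, 8.0, 1.0)
        times = np.linspace(0, 1.3, 20)
        tfr = self._tfr(np.ones((freqs.size, times.size)), freqs, times)
        assert peak_power_frequency(tfr) == 1.0

    def test_out_of_range_peak_ignored(self):
        freqs = np.arange(1.0, 12.0, 1.0)
        times = np.linspace(0, 1.3, 20)
        power = np.ones((freqs.size, times.size))
        power[freqs == 9.0] = 10.0
        power[freqs == 3.0] = 5.0
        tfr = self._tfr(power, freqs, times)
        assert peak_power_frequency(tfr, range_hz=(1, 7)) == 3.0

    def test_scale_invariance(self, locked_epochs_with_baseline):
        tfr = tf_power(locked_epochs_with_baseline,
                       freqs_hz=np.arange(1.0, 8.0, 0.25))
        p1 = peak_power_frequency(tfr)
        tfr.power = tfr.power * 123.4
        assert peak_power_frequency(tfr) == p1

    def test_bad_window_rejected(self, locked_epochs_with_baseline):
        tfr = tf_power(locked_epochs_with_baseline,
                       freqs_hz=np.arange(1.0, 8.0, 0.5))
        with pytest.raises(InvalidArgumentError):
            peak_power_frequency(tfr, window_s=(10.0, 12.0))


class TestDecodeEnvelope:
    sr = 100.0

    def _env(self, seed=0):
        """Aperiodic envelope (low-passed rectified noise): a stationary
        sinusoid would be trivially reconstructible from its own reversal,
        which would defeat the misalignment control."""
        from scipy.signal import butter, sosfiltfilt

        rng = np.random.default_rng(seed)
        n = int(2.0 * self.sr)
        sos = butter(4, 6.0, btype="low", fs=self.sr, output="sos")
        env = sosfiltfilt(sos, np.abs(rng.standard_normal(n)))
        return env - env.min() + 0.1

    def test_noiseless_recovery(self):
        env = self._env()
        lagged = np.roll(env - env.mean(), 10)
        ep = EpochSet(trials=np.tile(lagged, (6, 1)), sample_rate=self.sr,
                      t0_s=0.0)
        res = decode_envelope(ep, env, ridge_lambda=1e-3)
        assert res.r > 0.9

    def test_null_near_zero(self):
        env = self._env()
        rs = []
        for seed in range(20):
            ep = synth.gen_locked_eeg(synth.LockedEEGSpec(
                envelope=env, coupling=0.0, n_trials=10, sample_rate=self.sr,
                seed=seed))
            rs.append(decode_envelope(ep, env, ridge_lambda=1.0).r)
        assert abs(np.mean(rs)) < 0.1

    def test_time_reversal_destroys_r(self):
        """Misalignment control, averaged over seeds. The envelope must have
        structure above the filter's phase-resolution limit (~1/lag-span),
        otherwise the lagged model can partially 'un-reverse' a very smooth
        signal by spectral phase matching."""
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, 12.0, btype="low", fs=self.sr, output="sos")
        fwd, rev = [], []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            env = sosfiltfilt(sos, np.abs(rng.standard_normal(int(6 * self.sr))))
            env = env - env.min() + 0.1
            ep = synth.gen_locked_eeg(synth.LockedEEGSpec(
                envelope=env, coupling=3.0, n_trials=8, sample_rate=self.sr,
                seed=seed + 100, lag_s=0.1, band_hz=(1.0, 12.0)))
            fwd.append(decode_envelope(ep, env, ridge_lambda=1.0).r)
            ep_rev = EpochSet(trials=ep.trials[:, ::-1], sample_rate=self.sr,
                              t0_s=0.0)
            rev.append(decode_envelope(ep_rev, env, ridge_lambda=1.0).r)
        assert np.mean(rev) < 0.5 * np.mean(fwd)

    def test_monotone_in_coupling(self):
        env = self._env()
        means = []
        for coupling in (0.3, 1.0, 3.0):
            rs = []
            for seed in range(20):
                ep = synth.gen_locked_eeg(synth.LockedEEGSpec(
                    envelope=env, coupling=coupling, n_trials=8,
                    sample_rate=self.sr, seed=seed, lag_s=0.1))
                rs.append(decode_envelope(ep, env, ridge_lambda=1.0).r)
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]

    def test_lambda_selected_from_grid(self):
        env = self._env()
        ep = synth.gen_locked_eeg(synth.LockedEEGSpec(
            envelope=env, coupling=2.0, n_trials=6, sample_rate=self.sr,
            seed=1, lag_s=0.1))
        res = decode_envelope(ep, env, lambda_grid=np.array([0.1, 10.0]))
        assert res.ridge_lambda in (0.1, 10.0)

    def test_single_trial_rejected(self):
        env = self._env()
        ep = EpochSet(trials=env[None, :], sample_rate=self.sr, t0_s=0.0)
        with pytest.raises(InsufficientDataError):
            decode_envelope(ep, env)
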