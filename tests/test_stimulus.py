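import numpy as np
import pytest

from canicoh import acoustics, stimulus, synth
from canicoh.acoustics import f0_contour
from canicoh.audio import AudioSequence
from canicoh.errors import (
    InsufficientDurationError,
    InvalidArgumentError,
    InvalidInputError,
)

SR = 8000.0


def _bandpass_corr(a, b, sr, hi=4000.0):
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, min(hi, 0.45 * sr), btype="low", fs=sr, output="sos")
    fa, fb = sosfiltfilt(sos, a), sosfiltfilt(sos, b)
    return np.corrcoef(fa, fb)[0, 1]


class TestBuildStream:
    def test_duration_is_words_plus_gaps(self, prosodic_words, base_stream):
        total_words = sum(w.n_samples for w in prosodic_words) / SR
        gaps = base_stream.audio.duration_s - total_words
        assert 4 * 0.25 <= gaps <= 4 * 0.35

    def test_gap_window(self, prosodic_words):
        for seed in range(5):
            s = stimulus.build_stream(prosodic_words, seed=seed)
            onsets = np.asarray(s.word_onsets_s)
            durs = np.asarray(s.word_durs_s)
            gaps = onsets[1:] - (onsets[:-1] + durs[:-1])
            assert np.all((gaps >= 0.2499) & (gaps <= 0.3501))

    def test_peak_normalised_minus_2dbfs(self, base_stream):
        for sl in base_stream.word_slices():
            peak_db = 20 * np.log10(np.max(np.abs(base_stream.audio.samples[sl])))
            assert peak_db == pytest.approx(-2.0, abs=0.1)

    def test_highpass_attenuates_50hz_vs_500hz(self):
        """Filter response oracle: a 50 Hz probe must lose >= 20 dB more
        than a 500 Hz probe through stream construction."""
        t = np.arange(int(1.0 * SR)) / SR
        def gain(freq):
            word = AudioSequence(0.5 * np.sin(2 * np.pi * freq * t), SR)
            s = stimulus.build_stream([word], seed=0)
            out = s.audio.samples[int(0.1 * SR) : -int(0.1 * SR)]
            return np.sqrt(np.mean(out**2))
        # words are re-normalised to -2 dBFS, so compare pre-normalisation
        from canicoh.stimulus import butter, sosfiltfilt  # same filter path
        sos = butter(4, 100.0, btype="high", fs=SR, output="sos")
        g50 = np.sqrt(np.mean(sosfiltfilt(sos, np.sin(2 * np.pi * 50 * t)) ** 2))
        g500 = np.sqrt(np.mean(sosfiltfilt(sos, np.sin(2 * np.pi * 500 * t)) ** 2))
        assert 20 * np.log10(g500 / max(g50, 1e-12)) >= 20.0
        assert gain(500.0) > 0  # construction path stays finite

    def test_mixed_sample_rates_rejected(self):
        w1 = synth.gen_word(1, 4.0, sample_rate=8000.0)
        w2 = synth.gen_word(1, 4.0, sample_rate=16000.0)
        with pytest.raises(InvalidInputError):
            stimulus.build_stream([w1, w2])

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            stimulus.build_stream([])


class TestApplySpeechType:
    def test_unknown_mode_rejected(self, base_stream):
        with pytest.raises(InvalidArgumentError):
            stimulus.apply_speech_type(base_stream, "backwards")

    def test_duration_preserved_all_modes(self, base_stream):
        for mode in stimulus.SPEECH_TYPES:
            out = stimulus.apply_speech_type(base_stream, mode,
                                             reference_f0_hz=200.0)
            assert out.audio.n_samples == base_stream.audio.n_samples

    def test_content_only_flat_pitch(self, base_stream):
        out = stimulus.apply_speech_type(base_stream, "content_only",
                                         reference_f0_hz=200.0)
        feats = acoustics.pitch_track(out.audio)
        assert feats.f0_iqr_hz < 5.0
        assert feats.f0_mean_hz == pytest.approx(200.0, rel=0.05)

    def test_content_only_reverses_intensity(self, prosodic_words):
        """Make one word with a strongly asymmetric loudness ramp and check
        the output word's envelope is flipped."""
        word = synth.gen_word(2, 4.0, f0_hz=220.0)
        ramp = np.linspace(0.2, 1.0, word.n_samples)
        asym = AudioSequence(word.samples * ramp, SR)
        s = stimulus.build_stream([asym], seed=0)
        out = stimulus.apply_speech_type(s, "content_only")
        from canicoh.stimulus import _smooth_envelope
        env_in = _smooth_envelope(s.audio.samples, SR)
        env_out = _smooth_envelope(out.audio.samples, SR)
        r_flip = np.corrcoef(env_out, env_in[::-1])[0, 1]
        r_same = np.corrcoef(env_out, env_in)[0, 1]
        assert r_flip > r_same

    def test_prosody_only_is_reversal_for_flat_pitch(self):
        words = [synth.gen_word(n, 4.0, f0_hz=220.0, f0_excursion=0.0)
                 for n in (2, 1)]
        s = stimulus.build_stream(words, seed=1)
        out = stimulus.apply_speech_type(s, "prosody_only")
        for sl in s.word_slices():
            r = _bandpass_corr(out.audio.samples[sl],
                               s.audio.samples[sl][::-1], SR)
            assert r > 0.9

    def test_prosody_only_restores_contour(self, base_stream):
        out = stimulus.apply_speech_type(base_stream, "prosody_only")
        _, c1 = f0_contour(base_stream.audio)
        _, c2 = f0_contour(out.audio)
        m = np.isfinite(c1) & np.isfinite(c2)
        assert np.corrcoef(c1[m], c2[m])[0, 1] > 0.9

    def test_normal_roundtrip_preserves_contour(self, base_stream):
        out = stimulus.apply_speech_type(base_stream, "normal")
        _, c1 = f0_contour(base_stream.audio)
        _, c2 = f0_contour(out.audio)
        m = np.isfinite(c1) & np.isfinite(c2)
        assert np.corrcoef(c1[m], c2[m])[0, 1] > 0.9

    def test_double_reversal_recovers_normal(self, base_stream):
        nm = stimulus.apply_speech_type(base_stream, "normal")
        p1 = stimulus.apply_speech_type(base_stream, "prosody_only")
        p2 = stimulus.apply_speech_type(p1, "prosody_only")
        r = np.corrcoef(p2.audio.samples, nm.audio.samples)[0, 1]
        assert r > 0.95


class TestChangeTempo:
    def test_identity_factor(self, base_stream):
        out = stimulus.change_tempo(base_stream, 1)
        assert out.audio.n_samples == base_stream.audio.n_samples

    def test_invalid_factor(self, base_stream):
        with pytest.raises(InvalidArgumentError):
            stimulus.change_tempo(base_stream, 3)

    def test_factor_2_halves_duration(self, base_stream):
        out = stimulus.change_tempo(base_stream, 2)
        assert out.audio.n_samples == pytest.approx(
            base_stream.audio.n_samples / 2, abs=1
        )
        assert out.word_onsets_s == pytest.approx(
            [o / 2 for o in base_stream.word_onsets_s]
        )

    def test_pitch_preserved(self, base_stream):
        f_in = acoustics.pitch_track(base_stream.audio).f0_mean_hz
        for factor in (2, 4):
            out = stimulus.change_tempo(base_stream, factor)
            f_out = acoustics.pitch_track(out.audio).f0_mean_hz
            assert f_out == pytest.approx(f_in, rel=0.05)


@pytest.fixture(scope="module")
def long_stream():
    words = [synth.gen_word(2, 5.0, f0_hz=220.0) for _ in range(8)]
    return stimulus.build_stream(words, silence_ms=300, half_range_ms=50, seed=2)


class TestStreamRates:
    @staticmethod
    def _onset_train_peak(onsets, total_s, band, res=0.02):
        """Independent oracle: FFT peak of the annotated onset pulse train."""
        sr = 200.0
        x = np.zeros(int(total_s * sr))
        for o in onsets:
            i = int(o * sr)
            if i < x.size:
                x[i] = 1.0
        x -= x.mean()
        nfft = int(2 ** np.ceil(np.log2(max(sr / res, x.size))))
        p = np.abs(np.fft.rfft(x, nfft)) ** 2
        f = np.fft.rfftfreq(nfft, 1 / sr)
        m = (f >= band[0]) & (f <= band[1])
        return f[m][np.argmax(p[m])]

    def test_rates_match_onset_train_oracle(self, long_stream):
        wr, syr = stimulus.stream_rates(long_stream,
                                        word_band_hz=(0.5, 3.0),
                                        syllable_band_hz=(3.5, 8.0))
        onsets = np.asarray(long_stream.word_onsets_s)
        syll = np.concatenate([onsets + 0.0, onsets + 0.2])
        total = long_stream.audio.duration_s
        wr_oracle = self._onset_train_peak(onsets, total, (0.5, 3.0))
        syr_oracle = self._onset_train_peak(np.sort(syll), total, (3.5, 8.0))
        res = 1.0 / total  # natural spectral resolution
        assert wr == pytest.approx(wr_oracle, abs=res)
        assert syr == pytest.approx(syr_oracle, abs=res)

    def test_compression_doubles_rates(self, long_stream):
        wr, syr = stimulus.stream_rates(long_stream,
                                        word_band_hz=(0.5, 3.0),
                                        syllable_band_hz=(3.5, 8.0))
        fast = stimulus.change_tempo(long_stream, 2)
        wr2, syr2 = stimulus.stream_rates(fast,
                                          word_band_hz=(1.0, 6.0),
                                          syllable_band_hz=(7.0, 16.0))
        res = 1.0 / fast.audio.duration_s
        assert wr2 == pytest.approx(2 * wr, abs=res)
        assert syr2 == pytest.approx(2 * syr, abs=res)

    def test_monosyllabic_word_rate_equals_syllable_rate(self):
        words = [synth.gen_word(1, 4.0) for _ in range(10)]
        s = stimulus.build_stream(words, silence_ms=300, half_range_ms=40,
                                  seed=7)
        wr, syr = stimulus.stream_rates(s, word_band_hz=(0.5, 5.0),
                                        syllable_band_hz=(0.5, 5.0))
        assert wr == syr

    def test_short_stream_rejected(self):
        word = synth.gen_word(1, 4.0)
        s = stimulus.build_stream([word], seed=0)
        with pytest.raises(InsufficientDurationError):
            stimulus.stream_rates(s)


class TestConditionGrid:
    def test_nine_distinct_reproducible_conditions(self, prosodic_words):
        grid1 = stimulus.condition_grid(prosodic_words, seed=4)
        grid2 = stimulus.condition_grid(prosodic_words, seed=4)
        assert len(grid1) == 9
        assert set(grid1) == {
            (m, f) for m in stimulus.SPEECH_TYPES for f in stimulus.RATE_FACTORS
        }
        for key, stream in grid1.items():
            assert stream.speech_type == key[0]
            assert stream.rate_factor == key[1]
            assert np.array_equal(stream.audio.samples, grid2[key].audio.samples)
        # distinct audio across conditions (pairwise, full waveforms)
        streams = list(grid1.values())
        for i in range(len(streams)):
            for j in range(i + 1, len(streams)):
                a, b = streams[i].audio.samples, streams[j].audio.samples
                assert a.size != b.size or not np.allclose(a, b)
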