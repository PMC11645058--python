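import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apneasiam.dataio import ApneaEvent, AudioRecording
from apneasiam.features import (
    FeatureConfig,
    STFT_CONFIG,
    downsample,
    load_features,
    mel_spectrogram,
    mel_filterbank,
    save_features,
    segment_and_label,
    stft_spectrogram,
)


def make_recording(duration_s=60.0, sr=16000, seed=0, pid="p0"):
    rng = np.random.default_rng(seed)
    return AudioRecording(pid, sr, rng.uniform(-0.5, 0.5, int(duration_s * sr)))


class TestSegmentAndLabel:
    def test_event_spanning_window_is_apnea(self):
        rec = make_recording(24.0)
        windows = segment_and_label(rec, [ApneaEvent(10.0, 30.0)])
        # window (12, 18) fully inside the event
        assert windows[2].label == "apnea"

    def test_partial_coverage_is_non_apnea(self):
        rec = make_recording(24.0)
        windows = segment_and_label(rec, [ApneaEvent(10.0, 30.0)])
        # window (6, 12) only partly covered
        assert windows[1].label == "non_apnea"

    def test_no_events_gives_all_negative(self):
        rec = make_recording(60.0)
        windows = segment_and_label(rec, [])
        assert len(windows) == 10
        assert all(w.label == "non_apnea" for w in windows)

    def test_trailing_remainder_discarded(self):
        rec = make_recording(20.0)
        assert len(segment_and_label(rec, [])) == 3

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            segment_and_label(make_recording(5.0), [])

    @given(onset=st.integers(0, 20), extra=st.integers(0, 20))
    @settings(max_examples=25, deadline=None)
    def test_enlarging_event_never_unflags_windows(self, onset, extra):
        """Labeling is monotone: a larger event can only add apnea windows."""
        rec = make_recording(60.0, seed=1)
        small = [ApneaEvent(onset * 0.5, onset * 0.5 + 12.0)]
        large = [ApneaEvent(max(onset - extra, 0) * 0.5,
                            onset * 0.5 + 12.0 + extra * 0.5)]
        flags_small = [w.label == "apnea" for w in segment_and_label(rec, small)]
        flags_large = [w.label == "apnea" for w in segment_and_label(rec, large)]
        assert all(l or not s for s, l in zip(flags_small, flags_large))

    def test_class_counts_sum_to_total(self, small_patient):
        rec, events = small_patient
        windows = segment_and_label(rec, events)
        n_apnea = sum(w.label == "apnea" for w in windows)
        n_non = sum(w.label == "non_apnea" for w in windows)
        assert n_apnea + n_non == len(windows) == 20


class TestDownsample:
    def test_sixteen_fold_decimation(self):
        rec = make_recording(6.0, sr=16000)
        out = downsample(rec, 1000)
        assert out.sample_rate == 1000
        assert len(out.samples) == 6000

    def test_identity_at_same_rate(self):
        rec = make_recording(1.0)
        out = downsample(rec, 16000)
        assert np.array_equal(out.samples, rec.samples)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            downsample(make_recording(1.0, sr=8000), 16000)

    def test_aliasing_suppressed_for_out_of_band_tone(self):
        """A 600 Hz tone is above the 500 Hz Nyquist of a 1 kHz track and must
        be filtered out rather than folded back in."""
        sr = 16000
        t = np.arange(sr) / sr
        tone = AudioRecording("p", sr, 0.5 * np.sin(2 * np.pi * 600 * t))
        out = downsample(tone, 1000)
        e_in = np.mean(tone.samples ** 2)
        e_out = np.mean(out.samples ** 2)
        assert 10 * np.log10(e_out / e_in) < -20


class TestSpectrograms:
    def test_mel_full_band_shape(self, rng):
        x = rng.standard_normal(96000)
        feat = mel_spectrogram(x, FeatureConfig(n_bands_kept=32))
        assert feat.values.shape == (32, 376)
        assert np.all(np.isfinite(feat.values))

    @pytest.mark.parametrize("k", [8, 12, 18, 25])
    def test_truncation_equals_lowest_rows_of_full_analysis(self, rng, k):
        x = rng.standard_normal(96000)
        raw = dict(log_scale=False, standardize=False)
        full = mel_spectrogram(x, FeatureConfig(n_bands_kept=32, **raw))
        part = mel_spectrogram(x, FeatureConfig(n_bands_kept=k, **raw))
        assert part.values.shape == (k, 376)
        np.testing.assert_allclose(part.values, full.values[:k])

    def test_all_zero_input_sits_at_log_floor(self):
        feat = mel_spectrogram(np.zeros(96000),
                               FeatureConfig(standardize=False))
        assert np.allclose(feat.values, feat.values.flat[0])
        assert np.isclose(feat.values.flat[0], 10 * np.log10(1e-10))

    def test_stft_shape_is_1025_by_24(self, rng):
        feat = stft_spectrogram(rng.standard_normal(6000))
        assert feat.values.shape == (1025, 24)

    def test_stft_row_zero_is_dc(self):
        x = np.full(6000, 0.25)  # constant signal: all energy at 0 Hz
        feat = stft_spectrogram(x, FeatureConfig(feature_type="stft",
                                                 analysis_sr=1000,
                                                 log_scale=False,
                                                 standardize=False))
        assert feat.values[0].max() > feat.values[1:].max()

    def test_impulse_spreads_broadband(self):
        x = np.zeros(6000)
        x[3000] = 1.0
        feat = stft_spectrogram(x, FeatureConfig(feature_type="stft",
                                                 analysis_sr=1000,
                                                 log_scale=False,
                                                 standardize=False))
        hit = feat.values[:, feat.values.sum(axis=0) > 0]
        assert np.all(hit.mean(axis=1) > 0)

    def test_wrong_length_rejected(self, rng):
        with pytest.raises(ValueError, match="expected"):
            mel_spectrogram(rng.standard_normal(95999), FeatureConfig())
        with pytest.raises(ValueError, match="expected"):
            stft_spectrogram(rng.standard_normal(6001))

    def test_feature_determinism(self, rng):
        x = rng.standard_normal(96000)
        a = mel_spectrogram(x, FeatureConfig())
        b = mel_spectrogram(x, FeatureConfig())
        assert np.array_equal(a.values, b.values)

    def test_filterbank_rows_cover_disjoint_ascending_bands(self):
        fb = mel_filterbank(16000, 2048, 32)
        assert fb.shape == (32, 1025)
        peaks = fb.argmax(axis=1)
        assert np.all(np.diff(peaks) > 0)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, small_patient):
        rec, events = small_patient
        from apneasiam.features import extract_features
        feats = extract_features(rec, events, FeatureConfig(n_bands_kept=8))
        save_features(feats, tmp_path)
        loaded = load_features(tmp_path)
        assert len(loaded) == len(feats)
        for a, b in zip(feats, loaded):
            np.testing.assert_array_equal(a.values, b.values)
            assert a.window == b.window
            assert a.config == b.config
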