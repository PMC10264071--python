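"""Preprocessing chain, Morlet power, band grouping, Welch coherence."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from motorstates.spectral import (BANDS, FeatureMatrix, NeuralRecording,
                                  band_features, coherence_features,
                                  feature_labels, power_features, preprocess,
                                  wavelet_epoch_power, wavelet_power)

FS = 1000.0


def _tone(freq, dur=10.0, fs=FS, amp=1.0):
    t = np.arange(0, dur, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


class TestPreprocess:
    def test_line_noise_notched_at_least_20db(self):
        rec = NeuralRecording(signal=_tone(60.0, 10.0, 4000.0), fs=4000.0)
        out = preprocess(rec)
        atten = 20 * np.log10(np.std(out.signal[1000:-1000])
                              / np.std(rec.signal))
        assert atten <= -20.0
        assert out.fs == 1000.0

    def test_common_median_reference_cancels_shared_signal(self, rng):
        x = rng.standard_normal(8000)
        chans = [NeuralRecording(signal=x.copy(), fs=2000.0,
                                 channel_type="ecog") for _ in range(4)]
        out = preprocess(chans[0], strip_channels=chans[1:])
        assert np.std(out.signal) < 1e-9 * np.std(x)

    def test_in_band_amplitude_preserved(self):
        rec = NeuralRecording(signal=_tone(10.0, 20.0, 3000.0), fs=3000.0)
        out = preprocess(rec)
        # sinusoid std = A/sqrt(2) independent of sampling rate
        ratio = np.std(out.signal[2000:-2000]) / (1.0 / np.sqrt(2))
        assert abs(ratio - 1.0) < 0.05

    def test_low_rate_input_rejected(self):
        rec = NeuralRecording(signal=np.zeros(1000), fs=1000.0)
        with pytest.raises(ValueError, match="1200"):
            preprocess(rec)


class TestWaveletPower:
    def test_tone_selectivity(self):
        freqs, p = wavelet_power(_tone(20.0), FS)
        row = p[:, 2000:-2000].mean(axis=1)
        assert freqs[np.argmax(row)] == 20.0
        assert row[freqs == 10.0][0] < 0.1 * row.max()
        assert row[freqs == 40.0][0] < 0.1 * row.max()

    def test_unit_tone_power_calibration(self):
        # amplitude-1 sinusoid -> squared analytic amplitude 1 at its row
        freqs, p = wavelet_power(_tone(50.0), FS)
        assert p[freqs == 50.0, 3000:-3000].mean() == pytest.approx(1.0,
                                                                    rel=0.02)

    def test_zero_signal_gives_zero_power(self):
        _, p = wavelet_power(np.zeros(5000), FS)
        assert np.all(p == 0.0)

    def test_two_tones_give_two_local_maxima(self):
        x = _tone(8.0) + _tone(80.0)
        freqs, p = wavelet_power(x, FS)
        row = p[:, 2000:-2000].mean(axis=1)
        lo = slice(0, np.searchsorted(freqs, 30))
        hi = slice(np.searchsorted(freqs, 40), np.searchsorted(freqs, 150))
        assert freqs[lo][np.argmax(row[lo])] == 8.0
        assert freqs[hi][np.argmax(row[hi])] == 80.0

    def test_series_shorter_than_wavelet_support_raises(self):
        with pytest.raises(ValueError, match="support"):
            wavelet_power(np.zeros(500), FS)

    def test_low_wave_number_warns(self):
        with pytest.warns(UserWarning, match="wave number"):
            wavelet_power(np.zeros(20000), FS, w=4.0)

    def test_epoch_power_matches_full_plane(self, rng):
        x = rng.standard_normal(20000) + 2 * _tone(20.0, 20.0)
        epochs = [(0.0, 7.0), (7.0, 14.0)]
        freqs, pfull = wavelet_power(x, FS)
        ref = np.stack([pfull[:, :7000].mean(axis=1),
                        pfull[:, 7000:14000].mean(axis=1)], axis=1)
        _, fast, _ = wavelet_epoch_power(x, FS, epochs)
        assert np.max(np.abs(fast - ref) / ref) < 0.01


class TestBandFeatures:
    def test_exactly_42_columns(self, rng):
        rec = NeuralRecording(signal=rng.standard_normal(21000), fs=FS)
        feats = power_features(rec, [(0.0, 7.0), (7.0, 14.0)])
        assert feats.values.shape == (2, 42)
        assert len(feature_labels()) == 42

    def test_tone_lands_in_containing_beta_sub_band(self):
        freqs, p = wavelet_power(_tone(20.0, 14.0), FS)
        feats = band_features(p, FS, [(0.0, 7.0)], freqs=freqs, log=False)
        best = feats.labels[int(np.argmax(feats.values[0]))]
        assert best.band == "beta"
        assert best.f_low <= 20.0 <= best.f_high

    def test_white_noise_hfo_exceeds_theta_alpha(self, rng):
        # flat spectrum: total power scales with band width (200 vs 9 Hz)
        rec = NeuralRecording(signal=rng.standard_normal(14000), fs=FS)
        feats = power_features(rec, [(0.0, 7.0)], log=False)
        theta = feats.values[0, :7].sum()
        hfo = feats.values[0, 35:].sum()
        assert hfo > theta

    def test_epoch_past_data_dropped_with_warning(self, rng):
        freqs, p = wavelet_power(rng.standard_normal(10000), FS)
        with pytest.warns(UserWarning, match="dropped"):
            feats = band_features(p, FS, [(0.0, 7.0), (7.0, 14.0)],
                                  freqs=freqs)
        assert feats.values.shape[0] == 1

    def test_labels_tile_each_band_exactly(self):
        labels = feature_labels()
        for band, (lo, hi) in BANDS.items():
            sub = [l for l in labels if l.band == band]
            assert len(sub) == 7
            assert sub[0].f_low == pytest.approx(lo)
            assert sub[-1].f_high == pytest.approx(hi)
            for a, b in zip(sub, sub[1:]):
                assert b.f_low == pytest.approx(a.f_high)   # no gaps/overlap
                assert b.f_low > a.f_low                    # increasing

    def test_feature_matrix_hdf5_roundtrip(self, tmp_path, rng):
        rec = NeuralRecording(signal=rng.standard_normal(14000), fs=FS)
        feats = power_features(rec, [(0.0, 7.0)])
        path = tmp_path / "feats.h5"
        feats.to_hdf5(path)
        back = FeatureMatrix.from_hdf5(path)
        np.testing.assert_allclose(back.values, feats.values)
        assert back.labels[5].band == feats.labels[5].band


class TestCoherenceFeatures:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(14000)
        feats = coherence_features(x, x, FS, [(0.0, 7.0)])
        np.testing.assert_allclose(feats.values, 1.0, atol=1e-6)

    def test_independent_noise_coherence_below_bias_bound(self, rng):
        x = rng.standard_normal(14000)
        y = rng.standard_normal(14000)
        feats = coherence_features(x, y, FS, [(0.0, 7.0), (7.0, 14.0)])
        assert feats.values.mean() < 0.25

    def test_shared_narrowband_component_raises_beta_coherence(self, rng):
        shared = sp_signal.sosfilt(
            sp_signal.butter(4, [18, 22], btype="bandpass", fs=FS,
                             output="sos"), rng.standard_normal(14000)) * 5
        x = shared + rng.standard_normal(14000)
        y = shared + rng.standard_normal(14000)
        feats = coherence_features(x, y, FS, [(0.0, 7.0), (7.0, 14.0)])
        beta = feats.values[:, 7:14].mean()
        ghigh = feats.values[:, 28:35].mean()
        assert beta > ghigh

    def test_short_epoch_dropped(self, rng):
        x = rng.standard_normal(3000)
        with pytest.warns(UserWarning, match="dropped"):
            feats = coherence_features(x, x, FS, [(0.0, 1.0), (1.0, 3.0)])
        assert feats.values.shape[0] == 1


def test_wavelet_band_power_consistent_with_welch(rng):
    """Parseval-style cross-check of the Morlet bank against Welch PSD."""
    n_ep, ep_len = 8, 7.0
    x = rng.standard_normal(int(n_ep * ep_len * FS))
    x += 3 * _tone(15.0, n_ep * ep_len) * np.repeat(
        rng.uniform(0.2, 1.0, n_ep), int(ep_len * FS))
    epochs = [(k * ep_len, (k + 1) * ep_len) for k in range(n_ep)]
    freqs, wp, _ = wavelet_epoch_power(x, FS, epochs)
    wavelet_tot = wp.sum(axis=0)
    welch_tot = []
    for a, b in epochs:
        f, psd = sp_signal.welch(x[int(a * FS):int(b * FS)], FS, nperseg=1024)
        sel = (f >= 3) & (f <= 400)
        welch_tot.append(np.trapezoid(psd[sel], f[sel]))
    r = np.corrcoef(wavelet_tot, welch_tot)[0, 1]
    assert r > 0.95
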