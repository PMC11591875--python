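"""Tests for Mel spectrograms, MFCC, ZCR, spectral roll-off and the
flatten → PCA → standardize baseline track."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coughkit.features import (FlattenPCAStandardizer, MelFeaturizer,
                               flatten_pca_standardize, hz_to_mel,
                               mel_band_edges, mel_filter_bank, mel_to_hz,
                               mel_spectrogram, mfcc, power_spectrogram,
                               spectral_rolloff, zero_crossing_rate)

SR = 22050
N = 11025                      # samples in a 0.5-s window


def _sine(freq, n=N, sr=SR):
    return np.sin(2 * np.pi * freq * np.arange(n) / sr)


# ---------------------------------------------------------------------------
# Mel scale
# ---------------------------------------------------------------------------

@given(st.floats(min_value=0.0, max_value=11025.0))
def test_mel_scale_inverse(f):
    assert float(mel_to_hz(hz_to_mel(f))) == pytest.approx(f, abs=1e-6)


def test_mel_scale_monotone():
    f = np.linspace(0, SR / 2, 500)
    m = hz_to_mel(f)
    assert np.all(np.diff(m) > 0)


def test_filter_bank_shape_and_coverage():
    fb = mel_filter_bank(SR, 2048, 128)
    assert fb.shape == (128, 1025)
    assert np.all(fb >= 0)
    # every band has support
    assert np.all(fb.sum(axis=1) > 0)


# ---------------------------------------------------------------------------
# mel_spectrogram
# ---------------------------------------------------------------------------

def test_mel_shape_contract():
    mel = mel_spectrogram(_sine(440.0))
    assert mel.values.shape == (128, 22)
    assert mel.n_mels == 128 and mel.n_frames == 22
    assert np.all(np.isfinite(mel.values))
    # dB relative to segment max, clipped to 80 dB range
    assert mel.values.max() == pytest.approx(0.0)
    assert mel.values.min() >= -80.0


def test_mel_silence_uniform_floor():
    mel = mel_spectrogram(np.zeros(N))
    # the reference and the floor coincide: uniform 0 dB grid
    assert np.all(mel.values == 0.0)


def test_mel_pure_tone_band_localization():
    mel = mel_spectrogram(_sine(1000.0))
    edges = mel_band_edges(128, 0.0, SR / 2)
    peaks = np.argmax(mel.values, axis=0)
    for band in peaks:
        # the peak band's triangular support must contain 1 kHz
        assert edges[band] < 1000.0 < edges[band + 2]


def test_mel_linear_power_mode():
    mel = mel_spectrogram(_sine(1000.0), as_db=False)
    assert np.all(mel.values >= 0.0)
    assert mel.values.max() > 0.0


def test_mel_deterministic():
    x = np.random.default_rng(0).standard_normal(N)
    a = mel_spectrogram(x).values
    b = mel_spectrogram(x).values
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def test_mfcc_shape():
    assert mfcc(_sine(500.0)).shape == (13, 22)


def test_mfcc_silence_all_zero():
    # silence gives a uniform 0-dB Mel grid, whose DCT is zero everywhere
    # (including coefficient 0)
    c = mfcc(np.zeros(N))
    assert np.allclose(c, 0.0)


def test_mfcc_noise_vs_sine_differ():
    rng = np.random.default_rng(1)
    c_noise = mfcc(rng.standard_normal(N)).mean(axis=1)
    c_sine = mfcc(_sine(1000.0)).mean(axis=1)
    # a flat spectrum and a peaked spectrum have clearly different
    # first cepstral coefficients
    assert abs(c_noise[1] - c_sine[1]) > 1.0


# ---------------------------------------------------------------------------
# zero-crossing rate
# ---------------------------------------------------------------------------

def test_zcr_constant_signal_is_zero():
    assert np.all(zero_crossing_rate(np.full(N, 0.5)) == 0.0)


def test_zcr_alternating_signal_is_one():
    x = np.tile([1.0, -1.0], 2048)
    rates = zero_crossing_rate(x, frame_length=512, hop=512)
    assert np.allclose(rates, 1.0)


def test_zcr_bounded():
    x = np.random.default_rng(2).standard_normal(N)
    rates = zero_crossing_rate(x)
    assert np.all((rates >= 0.0) & (rates <= 1.0))


def test_zcr_100hz_sine_matches_brute_force():
    x = _sine(100.0)
    rates = zero_crossing_rate(x)
    sb = np.signbit(x)
    brute = np.mean(sb[1:] != sb[:-1])
    # ~200 sign changes per second at 22,050 samples/s
    assert np.mean(rates) == pytest.approx(brute, abs=1e-3)
    assert np.mean(rates) == pytest.approx(200.0 / SR, abs=5e-4)


# ---------------------------------------------------------------------------
# spectral roll-off
# ---------------------------------------------------------------------------

def test_rolloff_pure_tone_near_1khz():
    r = spectral_rolloff(_sine(1000.0))
    # concentrated spectrum: roll-off within a few FFT bins (~10.8 Hz each)
    # of the tone; Hann-window leakage spreads it slightly
    assert np.all(np.abs(r - 1000.0) < 25.0)


def test_rolloff_full_energy_boundary():
    x = _sine(1000.0)
    r100 = spectral_rolloff(x, pct=1.0)
    r85 = spectral_rolloff(x, pct=0.85)
    assert np.all(r100 >= r85)
    assert np.all(r100 <= SR / 2)
    # brute-force cumulative-sum oracle at pct=1.0, frame by frame
    spec = power_spectrogram(x)
    freqs = np.fft.rfftfreq(2048, d=1.0 / SR)
    for frame in range(spec.shape[1]):
        csum = np.cumsum(spec[:, frame])
        k = next(i for i in range(csum.size) if csum[i] >= csum[-1])
        assert r100[frame] == freqs[k]


def test_rolloff_monotone_in_pct():
    x = np.random.default_rng(3).standard_normal(N)
    r_low = spectral_rolloff(x, pct=0.5)
    r_high = spectral_rolloff(x, pct=0.95)
    assert np.all(r_high >= r_low)


def test_rolloff_silence_is_zero():
    assert np.all(spectral_rolloff(np.zeros(N)) == 0.0)


def test_rolloff_rejects_bad_pct():
    with pytest.raises(ValueError):
        spectral_rolloff(np.zeros(N), pct=0.0)
    with pytest.raises(ValueError):
        spectral_rolloff(np.zeros(N), pct=1.5)


# ---------------------------------------------------------------------------
# MelFeaturizer
# ---------------------------------------------------------------------------

def test_mel_featurizer_stacks_grids():
    X = np.stack([_sine(500.0), _sine(2000.0)])
    grids = MelFeaturizer().transform(X)
    assert grids.shape == (2, 128, 22)


# ---------------------------------------------------------------------------
# flatten -> PCA -> standardize
# ---------------------------------------------------------------------------

def test_flatten_dimension_2816():
    rng = np.random.default_rng(4)
    mels = rng.standard_normal((10, 128, 22))
    tr = FlattenPCAStandardizer().fit(mels)
    assert tr.input_dim_ == 2816


def test_pca_rank3_retains_3_components():
    rng = np.random.default_rng(5)
    factors = rng.standard_normal((3, 60))
    weights = rng.standard_normal((40, 3))
    X = (weights @ factors).reshape(40, 6, 10)    # exact rank-3 mixture
    tr = FlattenPCAStandardizer(variance_kept=0.95).fit(X)
    assert tr.n_components_ == 3


def test_standardized_components_zero_mean_unit_variance():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((50, 8, 4))
    tr = FlattenPCAStandardizer(variance_kept=0.9)
    Z = tr.fit_transform(X)
    assert np.all(np.abs(Z.mean(axis=0)) < 1e-6)
    assert np.all(np.abs(Z.std(axis=0) - 1.0) < 1e-6)


def test_transform_requires_matching_dim():
    rng = np.random.default_rng(7)
    tr = FlattenPCAStandardizer().fit(rng.standard_normal((10, 4, 5)))
    with pytest.raises(ValueError):
        tr.transform(rng.standard_normal((3, 4, 6)))


def test_fit_requires_two_samples():
    with pytest.raises(ValueError):
        FlattenPCAStandardizer().fit(np.zeros((1, 4, 5)))


def test_flatten_pca_standardize_wrapper():
    rng = np.random.default_rng(8)
    mels = rng.standard_normal((20, 6, 5))
    feats, tr = flatten_pca_standardize(mels, variance_kept=0.9)
    assert len(feats) == 20
    assert all(f.dim == 30 and f.standardized for f in feats)
    assert all(f.pca_dim == tr.n_components_ for f in feats)
    meta = tr.get_metadata()
    assert meta["input_dim"] == 30
    assert meta["explained_variance"] >= 0.9
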