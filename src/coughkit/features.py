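"""Audio featurization: Mel spectrograms (the model input), MFCC,
zero-crossing rate and spectral roll-off, plus the flatten → PCA →
standardize track used by the classical baselines.

A 0.5-s window at 22,050 Hz (11,025 samples), analyzed with a 2048-point
Hann-windowed STFT at hop 512 with centered frames, yields 22 frames; a
128-band Mel filter bank then gives the (128, 22) time-frequency "image"
the classifier consumes.  Energies are expressed in dB relative to the
segment's maximum, clipped to an 80-dB dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.fft
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .segmentation import Segment, SegmentSet

DEFAULT_SAMPLE_RATE = 22050
DEFAULT_N_MELS = 128
DEFAULT_N_FFT = 2048
DEFAULT_HOP = 512
DEFAULT_TOP_DB = 80.0
_AMIN = 1e-10


@dataclass
class MelSegment:
    """dB-scaled Mel energies of one segment: (n_mels, n_frames)."""

    values: np.ndarray
    n_mels: int
    n_frames: int
    segment_ref: Segment | None = None


@dataclass
class FlatFeatures:
    """A flattened (optionally PCA-reduced, standardized) feature vector."""

    vector: np.ndarray
    dim: int
    pca_dim: int | None = None
    standardized: bool = False


# ---------------------------------------------------------------------------
# Mel scale (Slaney variant: linear below 1 kHz, logarithmic above)
# ---------------------------------------------------------------------------

_F_SP = 200.0 / 3.0
_MIN_LOG_HZ = 1000.0
_MIN_LOG_MEL = _MIN_LOG_HZ / _F_SP
_LOGSTEP = np.log(6.4) / 27.0


def hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    mel = f / _F_SP
    above = f >= _MIN_LOG_HZ
    mel = np.where(above, _MIN_LOG_MEL + np.log(np.maximum(f, _MIN_LOG_HZ)
                                                / _MIN_LOG_HZ) / _LOGSTEP, mel)
    return mel


def mel_to_hz(m: np.ndarray | float) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    f = m * _F_SP
    above = m >= _MIN_LOG_MEL
    return np.where(above, _MIN_LOG_HZ * np.exp(_LOGSTEP * (m - _MIN_LOG_MEL)), f)


def mel_band_edges(n_mels: int, fmin: float, fmax: float) -> np.ndarray:
    """The n_mels + 2 Hz edge frequencies of a triangular Mel filter bank."""
    mels = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    return mel_to_hz(mels)


def mel_filter_bank(sr: int, n_fft: int, n_mels: int,
                    fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular, area-normalized Mel filter bank, shape (n_mels, n_fft//2+1)."""
    if fmax is None:
        fmax = sr / 2.0
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    edges = mel_band_edges(n_mels, fmin, fmax)
    weights = np.zeros((n_mels, fft_freqs.size))
    for m in range(n_mels):
        lower, center, upper = edges[m], edges[m + 1], edges[m + 2]
        up = (fft_freqs - lower) / max(center - lower, 1e-12)
        down = (upper - fft_freqs) / max(upper - center, 1e-12)
        weights[m] = np.maximum(0.0, np.minimum(up, down))
        weights[m] *= 2.0 / (upper - lower)        # equal-area normalization
    return weights


# ---------------------------------------------------------------------------
# spectrogram primitives
# ---------------------------------------------------------------------------

def _frame_centered(samples: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    """Centered frames (reflect padding), shape (n_frames, n_fft)."""
    pad = n_fft // 2
    if samples.size > 1:
        x = np.pad(samples, pad, mode="reflect")
    else:
        x = np.pad(samples, pad, mode="constant")
    n_frames = 1 + samples.size // hop
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def power_spectrogram(samples: np.ndarray, n_fft: int = DEFAULT_N_FFT,
                      hop: int = DEFAULT_HOP) -> np.ndarray:
    """Hann-windowed STFT power, shape (n_fft//2 + 1, n_frames)."""
    samples = np.asarray(samples, dtype=np.float64)
    frames = _frame_centered(samples, n_fft, hop)
    window = np.hanning(n_fft)
    spec = np.fft.rfft(frames * window, axis=1)
    return (np.abs(spec) ** 2).T


def _segment_samples(seg: "Segment | np.ndarray") -> np.ndarray:
    return seg.samples if isinstance(seg, Segment) else np.asarray(seg, float)


def mel_spectrogram(seg: "Segment | np.ndarray",
                    sample_rate: int = DEFAULT_SAMPLE_RATE,
                    n_mels: int = DEFAULT_N_MELS, n_fft: int = DEFAULT_N_FFT,
                    hop: int = DEFAULT_HOP, top_db: float = DEFAULT_TOP_DB,
                    as_db: bool = True) -> MelSegment:
    """Mel spectrogram of one segment, dB-scaled and range-clipped.

    dB values are relative to the segment's maximum Mel energy, so they lie
    in [-top_db, 0]; an all-zero segment gives a uniform grid at 0 dB (the
    floor and the reference coincide).  ``as_db=False`` returns linear power.
    """
    samples = _segment_samples(seg)
    spec = power_spectrogram(samples, n_fft=n_fft, hop=hop)
    mel = mel_filter_bank(sample_rate, n_fft, n_mels) @ spec
    if as_db:
        ref = max(float(mel.max()), _AMIN)
        values = 10.0 * np.log10(np.maximum(mel, _AMIN) / ref)
        values = np.maximum(values, -top_db)
    else:
        values = mel
    return MelSegment(values=values, n_mels=n_mels, n_frames=values.shape[1],
                      segment_ref=seg if isinstance(seg, Segment) else None)


def mfcc(seg: "Segment | np.ndarray", n_coeff: int = 13,
         sample_rate: int = DEFAULT_SAMPLE_RATE, n_mels: int = DEFAULT_N_MELS,
         n_fft: int = DEFAULT_N_FFT, hop: int = DEFAULT_HOP) -> np.ndarray:
    """Mel-frequency cepstral coefficients: DCT-II (ortho) of the dB Mel
    energies per frame; shape (n_coeff, n_frames)."""
    mel = mel_spectrogram(seg, sample_rate=sample_rate, n_mels=n_mels,
                          n_fft=n_fft, hop=hop)
    return scipy.fft.dct(mel.values, type=2, axis=0, norm="ortho")[:n_coeff]


def zero_crossing_rate(seg: "Segment | np.ndarray",
                       frame_length: int = DEFAULT_HOP,
                       hop: int = DEFAULT_HOP) -> np.ndarray:
    """Per-frame fraction of adjacent sample pairs that change sign, in [0, 1]."""
    samples = _segment_samples(seg)
    n_frames = max(int(np.ceil(samples.size / hop)), 1)
    rates = np.zeros(n_frames)
    sb = np.signbit(samples)
    for k in range(n_frames):
        fr = sb[k * hop: k * hop + frame_length]
        if fr.size > 1:
            rates[k] = np.mean(fr[1:] != fr[:-1])
    return rates


def spectral_rolloff(seg: "Segment | np.ndarray", pct: float = 0.85,
                     sample_rate: int = DEFAULT_SAMPLE_RATE,
                     n_fft: int = DEFAULT_N_FFT,
                     hop: int = DEFAULT_HOP) -> np.ndarray:
    """Per-frame frequency (Hz) below which ``pct`` of spectral energy lies.

    Silent frames (zero total energy) report bin 0, i.e. 0 Hz, by convention.
    """
    if not (0.0 < pct <= 1.0):
        raise ValueError("pct must be in (0, 1]")
    samples = _segment_samples(seg)
    spec = power_spectrogram(samples, n_fft=n_fft, hop=hop)
    csum = np.cumsum(spec, axis=0)
    total = csum[-1]
    thresh = pct * total
    # smallest bin whose cumulative energy reaches the threshold
    bins = np.argmax(csum >= thresh[None, :], axis=0)
    bins[total <= 0] = 0
    return np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)[bins]


# ---------------------------------------------------------------------------
# batch featurization and the baseline feature track
# ---------------------------------------------------------------------------

class MelFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: segments → stacked Mel grids (n, n_mels, n_frames).

    Accepts a :class:`SegmentSet`, a list of segments, or an array of raw
    sample windows.  A configured ``sample_rate`` that disagrees with the
    window length produces the wrong frame count downstream, so the expected
    frame count is checked when ``expected_shape`` is set.
    """

    def __init__(self, sample_rate: int = DEFAULT_SAMPLE_RATE,
                 n_mels: int = DEFAULT_N_MELS, n_fft: int = DEFAULT_N_FFT,
                 hop: int = DEFAULT_HOP, top_db: float = DEFAULT_TOP_DB):
        self.sample_rate = sample_rate
        self.n_mels = n_mels
        self.n_fft = n_fft
        self.hop = hop
        self.top_db = top_db

    def fit(self, X, y=None):  # noqa: D102 - stateless
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        segments = list(X) if not isinstance(X, np.ndarray) else X
        grids = [
            mel_spectrogram(s, sample_rate=self.sample_rate, n_mels=self.n_mels,
                            n_fft=self.n_fft, hop=self.hop,
                            top_db=self.top_db).values
            for s in segments
        ]
        return np.stack(grids) if grids else np.empty((0, self.n_mels, 0))


class FlattenPCAStandardizer(BaseEstimator, TransformerMixin):
    """The baseline feature track: flatten → PCA (variance kept) → standardize.

    Mel grids of shape (n_mels, n_frames) flatten to n_mels × n_frames
    (2816 for the 128×22 default).  PCA retains the smallest component count
    reaching at least ``variance_kept`` explained variance; each retained
    component is then centered and scaled to unit variance, in that order.
    Fit on the training split only; reuse on the test split.
    """

    def __init__(self, variance_kept: float = 0.95):
        self.variance_kept = variance_kept

    @staticmethod
    def _flatten(X) -> np.ndarray:
        if not isinstance(X, np.ndarray):
            X = np.stack([m.values if isinstance(m, MelSegment) else np.asarray(m)
                          for m in X])
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        return X

    def fit(self, X, y=None):
        X = self._flatten(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples to fit PCA")
        self.input_dim_ = X.shape[1]
        self.pca_ = PCA(n_components=self.variance_kept, svd_solver="full")
        Z = self.pca_.fit_transform(X)
        self.scaler_ = StandardScaler().fit(Z)
        self.n_components_ = self.pca_.n_components_
        return self

    def transform(self, X) -> np.ndarray:
        X = self._flatten(X)
        if X.shape[1] != self.input_dim_:
            raise ValueError(
                f"expected {self.input_dim_} flattened features, got {X.shape[1]}"
            )
        return self.scaler_.transform(self.pca_.transform(X))

    def get_metadata(self) -> dict:
        """Plain-metadata description of the fitted transform."""
        return {
            "variance_kept": self.variance_kept,
            "input_dim": int(self.input_dim_),
            "n_components": int(self.n_components_),
            "explained_variance": float(
                np.sum(self.pca_.explained_variance_ratio_)
            ),
        }


def flatten_pca_standardize(mels: Sequence[MelSegment] | np.ndarray,
                            variance_kept: float = 0.95,
                            ) -> tuple[list[FlatFeatures], FlattenPCAStandardizer]:
    """Fit the baseline feature track on a list of Mel grids.

    Returns per-segment :class:`FlatFeatures` plus the fitted transformer
    (to be reused, unrefitted, on held-out data).
    """
    transformer = FlattenPCAStandardizer(variance_kept=variance_kept)
    Z = transformer.fit_transform(mels)
    feats = [
        FlatFeatures(vector=z, dim=transformer.input_dim_,
                     pca_dim=transformer.n_components_, standardized=True)
        for z in Z
    ]
    return feats, transformer
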