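"""Windowed segmentation of recordings, the amplitude-based class-imbalance
filter, and a silence-trimming utility.

The analysis unit is a 0.5-s window.  A window is labeled positive when it
overlaps a cough annotation by at least 0.1 s (or half the annotation's
duration, for very short coughs).  The imbalance filter drops quiet negative
windows — those whose mean absolute amplitude falls below the recording-wide
mean — while always retaining positives, raising the positive fraction of a
heavily imbalanced segment set.  Silence trimming is an annotation-effort
utility only; model training consumes the unsilenced stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import Annotation, AudioRecording

DEFAULT_WINDOW_S = 0.5


@dataclass
class Segment:
    """One analysis window of a recording."""

    source_id: str
    start_s: float
    end_s: float
    samples: np.ndarray
    label: bool
    mean_abs_amplitude: float


@dataclass
class SegmentSet:
    """A list of segments plus its positive-class fraction."""

    segments: list[Segment]

    @property
    def positive_fraction(self) -> float:
        if not self.segments:
            return 0.0
        return sum(s.label for s in self.segments) / len(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """Columnar view (audio itself persists via source WAV + offsets)."""
        return pd.DataFrame(
            {
                "source_id": [s.source_id for s in self.segments],
                "start_s": [s.start_s for s in self.segments],
                "end_s": [s.end_s for s in self.segments],
                "label": [s.label for s in self.segments],
                "mean_abs_amplitude": [s.mean_abs_amplitude for s in self.segments],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def _window_is_positive(w_start: float, w_end: float,
                        annotations: list[Annotation]) -> bool:
    for ann in annotations:
        if ann.label != "cough":
            continue
        overlap = min(w_end, ann.end_s) - max(w_start, ann.start_s)
        if overlap >= min(0.1, ann.duration_s / 2.0):
            return True
    return False


def window_recording(rec: AudioRecording, annotations: list[Annotation],
                     window_s: float = DEFAULT_WINDOW_S,
                     stride_s: float = DEFAULT_WINDOW_S) -> SegmentSet:
    """Tile a recording into fixed-length windows with cough labels.

    Windows start at multiples of ``stride_s`` and cover [0, duration); a
    trailing partial window is zero-padded to full length.  The stored
    ``mean_abs_amplitude`` is computed over the real samples, before padding.
    """
    if window_s <= 0 or stride_s <= 0:
        raise ValueError("window_s and stride_s must be positive")
    sr = rec.sample_rate
    win = int(round(window_s * sr))
    hop = int(round(stride_s * sr))
    n = rec.samples.size
    n_windows = int(np.ceil(n / hop))
    segments: list[Segment] = []
    for k in range(n_windows):
        i0 = k * hop
        raw = rec.samples[i0: i0 + win]
        mean_abs = float(np.mean(np.abs(raw))) if raw.size else 0.0
        if raw.size < win:
            raw = np.pad(raw, (0, win - raw.size))
        w_start = i0 / sr
        w_end = w_start + window_s
        segments.append(
            Segment(
                source_id=rec.source_id,
                start_s=w_start,
                end_s=w_end,
                samples=raw,
                label=_window_is_positive(w_start, w_end, annotations),
                mean_abs_amplitude=mean_abs,
            )
        )
    return SegmentSet(segments)


def global_mean_abs(rec: AudioRecording) -> float:
    """Mean absolute amplitude of the entire raw recording."""
    return float(np.mean(np.abs(rec.samples)))


def amplitude_filter(segment_set: SegmentSet,
                     global_mean: float) -> SegmentSet:
    """Drop quiet negative segments; always keep positives.

    A segment survives iff its mean absolute amplitude is at least the
    recording-wide mean, or it contains a cough.  Because no positive is
    ever removed and only negatives can be dropped, the positive fraction of
    the output never falls below that of the input.
    """
    if global_mean < 0:
        raise ValueError("global_mean must be non-negative")
    kept = [s for s in segment_set.segments
            if s.label or s.mean_abs_amplitude >= global_mean]
    return SegmentSet(kept)


@dataclass
class TimeMap:
    """Piecewise-linear map between trimmed time and original time.

    ``spans`` lists the kept original-time intervals in order; their trimmed
    positions are cumulative.
    """

    spans: list[tuple[float, float]]

    def _trimmed_starts(self) -> list[float]:
        starts, pos = [], 0.0
        for a, b in self.spans:
            starts.append(pos)
            pos += b - a
        return starts

    @property
    def trimmed_duration_s(self) -> float:
        return sum(b - a for a, b in self.spans)

    def to_original(self, t_trimmed: float) -> float:
        """Map a time in the trimmed recording back to original time."""
        if t_trimmed < 0:
            raise ValueError("time must be non-negative")
        for start, (a, b) in zip(self._trimmed_starts(), self.spans):
            if t_trimmed <= start + (b - a):
                return a + (t_trimmed - start)
        raise ValueError("time beyond the trimmed recording")

    def to_trimmed(self, t_original: float) -> float | None:
        """Map original time into the trimmed recording; None if removed."""
        for start, (a, b) in zip(self._trimmed_starts(), self.spans):
            if a <= t_original <= b:
                return start + (t_original - a)
        return None


def trim_silence(rec: AudioRecording, frame_s: float = 0.05,
                 rel_threshold: float = 0.1, min_gap_s: float = 1.0,
                 ) -> tuple[AudioRecording | None, TimeMap]:
    """Remove long sub-threshold runs from a recording.

    Frames of ``frame_s`` whose RMS falls below ``rel_threshold`` times the
    whole-recording RMS are silence candidates; contiguous silent runs longer
    than ``min_gap_s`` are cut.  Returns the shortened recording (``None``
    when everything was silent) and the monotone :class:`TimeMap` from
    trimmed time back to original time.  This is an annotation aid — the
    classification training path consumes the original, unsilenced audio.
    """
    if frame_s <= 0 or rel_threshold <= 0 or min_gap_s <= 0:
        raise ValueError("parameters must be positive")
    sr = rec.sample_rate
    frame = max(int(round(frame_s * sr)), 1)
    n = rec.samples.size
    n_frames = int(np.ceil(n / frame))
    padded = np.pad(rec.samples, (0, n_frames * frame - n))
    rms = np.sqrt(np.mean(padded.reshape(n_frames, frame) ** 2, axis=1))
    global_rms = float(np.sqrt(np.mean(rec.samples ** 2)))
    if global_rms == 0.0:
        # a digitally silent recording is silence throughout
        silent = np.ones(n_frames, dtype=bool)
    else:
        silent = rms < rel_threshold * global_rms

    min_frames = int(np.ceil(min_gap_s / frame_s))
    keep = np.ones(n_frames, dtype=bool)
    i = 0
    while i < n_frames:
        if silent[i]:
            j = i
            while j < n_frames and silent[j]:
                j += 1
            if j - i >= min_frames:
                keep[i:j] = False
            i = j
        else:
            i += 1

    spans: list[tuple[float, float]] = []
    pieces: list[np.ndarray] = []
    i = 0
    while i < n_frames:
        if keep[i]:
            j = i
            while j < n_frames and keep[j]:
                j += 1
            a, b = i * frame, min(j * frame, n)
            spans.append((a / sr, b / sr))
            pieces.append(rec.samples[a:b])
            i = j
        else:
            i += 1

    time_map = TimeMap(spans=spans)
    if not pieces:
        return None, time_map
    trimmed = AudioRecording(
        samples=np.concatenate(pieces), sample_rate=sr,
        source_id=rec.source_id, subset=rec.subset,
    )
    return trimmed, time_map
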