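"""Reading and writing clinical audio recordings and their event annotations.

Recordings are mono PCM WAV files (the reference corpus uses 22,050 Hz).
Event annotations travel as Audacity label tracks: one event per line,
TAB-separated ``start_s<TAB>end_s<TAB>label`` with times in seconds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: Canonical event labels.  Anything else read from a label file is mapped to
#: ``"other"`` with a warning.
LABELS = ("cough", "speech", "laugh", "throat_clear", "other")

#: Case-insensitive synonyms seen in hand-made label tracks.
_LABEL_SYNONYMS = {
    "cough": "cough",
    "coughing": "cough",
    "speech": "speech",
    "talk": "speech",
    "talking": "speech",
    "laugh": "laugh",
    "laughing": "laugh",
    "laughter": "laugh",
    "throat_clear": "throat_clear",
    "throat clear": "throat_clear",
    "clear throat": "throat_clear",
    "throat clearing": "throat_clear",
    "throat-clear": "throat_clear",
    "other": "other",
}

_PCM16_MAX = 32767


@dataclass
class AudioRecording:
    """A sampled mono waveform with amplitudes in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""
    subset: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class Annotation:
    """A labeled time interval within a recording."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid interval [{self.start_s}, {self.end_s}]: "
                "need 0 <= start < end"
            )
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


class AudioFormatError(ValueError):
    """Raised when a file cannot be parsed as the expected audio/label format."""


def read_wav(path: str | Path, source_id: str | None = None,
             subset: str = "") -> AudioRecording:
    """Read a PCM WAV file into an :class:`AudioRecording`.

    Integer samples are scaled to [-1, 1]; multi-channel input is averaged to
    mono.  The file's native sample rate is preserved — resampling, where
    needed, is an explicit separate step.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # wavfile warns on benign chunks
            rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize scipy's error zoo
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc

    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioRecording(
        samples=samples,
        sample_rate=int(rate),
        source_id=source_id if source_id is not None else path.stem,
        subset=subset,
    )


def write_wav(rec: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM mono WAV (clipping to [-1, 1])."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * _PCM16_MAX).astype(np.int16)
    wavfile.write(Path(path), rec.sample_rate, pcm)


def normalize_label(raw: str) -> str:
    """Map a free-text event tag onto the canonical label vocabulary."""
    key = raw.strip().lower().replace("_", " ")
    canon = _LABEL_SYNONYMS.get(key) or _LABEL_SYNONYMS.get(key.replace(" ", "_"))
    if canon is None:
        logger.warning("unknown annotation label %r mapped to 'other'", raw)
        return "other"
    return canon


def read_labels(path: str | Path) -> list[Annotation]:
    """Parse an Audacity label-track file into annotations, in file order.

    Unknown label strings map to ``other`` (with a warning); malformed times
    or inverted intervals raise with the offending line number.
    """
    path = Path(path)
    annotations: list[Annotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AudioFormatError(
                    f"{path}:{lineno}: expected 'start<TAB>end<TAB>label', got {line!r}"
                )
            try:
                start_s, end_s = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise AudioFormatError(
                    f"{path}:{lineno}: non-numeric time in {line!r}"
                ) from exc
            if not (0.0 <= start_s < end_s):
                raise AudioFormatError(
                    f"{path}:{lineno}: invalid interval [{start_s}, {end_s}]"
                )
            annotations.append(Annotation(start_s, end_s, normalize_label(parts[2])))
    return annotations


def write_labels(annotations: list[Annotation], path: str | Path) -> None:
    """Write annotations as an Audacity label track (6-decimal seconds)."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        for ann in annotations:
            fh.write(f"{ann.start_s:.6f}\t{ann.end_s:.6f}\t{ann.label}\n")
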