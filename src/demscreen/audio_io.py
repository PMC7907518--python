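"""Reading, writing and standardizing audio.

Every downstream stage (patch extraction, log-mel analysis, decimation)
assumes one canonical representation: mono float samples in [-1, 1] at
16 kHz. ``standardize`` produces it; ``read_wav``/``write_wav`` move it
to and from 16-bit PCM WAV on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

#: Canonical sample rate. Chosen so the 96 x 10 ms log-mel patch geometry
#: holds and the (4, 4, 2) decimation cascade lands on 500 Hz.
CANONICAL_RATE_HZ = 16000

LABEL_AD = "AD"
LABEL_NONAD = "NONAD"
#: Class order used everywhere (index 0 = NONAD keeps argmax ties on the
#: healthy class, matching the documented tie rule).
LABELS = (LABEL_NONAD, LABEL_AD)

_INT16_MAX = 32767.0


class AudioFormatError(ValueError):
    """Raised when a file is not a readable PCM WAV."""


@dataclass
class AudioRecording:
    """One subject's waveform.

    Parameters
    ----------
    subject_id : str
        Unique speaker identifier.
    samples : ndarray
        1-D (or 2-D channel-major before standardization) float amplitudes.
    sample_rate_hz : int
        Sampling rate of ``samples``.
    label : str, optional
        ``"AD"`` or ``"NONAD"``.
    """

    subject_id: str
    samples: np.ndarray
    sample_rate_hz: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        n = self.samples.shape[-1] if self.samples.ndim > 1 else len(self.samples)
        return n / self.sample_rate_hz


@dataclass
class CorpusManifest:
    """Tabular corpus index: ``subject_id, path, label, partition``."""

    frame: pd.DataFrame

    COLUMNS = ("subject_id", "path", "label", "partition")

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                if col == "partition":
                    df["partition"] = ""
                else:
                    raise ValueError(f"manifest missing column {col!r}")
        df = df[list(self.COLUMNS)]
        df["partition"] = df["partition"].fillna("")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject_ids in manifest: {dupes}")
        bad = set(df["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"labels must be drawn from {LABELS}; found {sorted(bad)}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return self.frame["subject_id"].tolist()

    def label_of(self, subject_id: str) -> str:
        row = self.frame.loc[self.frame["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        return row["label"].iloc[0]

    def subset(self, subject_ids: list[str], partition: str | None = None) -> "CorpusManifest":
        df = self.frame[self.frame["subject_id"].isin(subject_ids)].copy()
        if partition is not None:
            df["partition"] = partition
        return CorpusManifest(df)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorpusManifest":
        return cls(pd.read_csv(str(path), keep_default_na=False))


def read_wav(path: str | Path) -> AudioRecording:
    """Read a PCM WAV file into float samples scaled to [-1, 1].

    The original sample rate is preserved; the subject id defaults to the
    file stem. Integer PCM is scaled by its type's full range; float WAV
    is passed through.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise AudioFormatError(f"not a readable PCM WAV: {path} ({exc})") from exc
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _INT16_MAX
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV encoding {data.dtype} in {path}")
    np.clip(samples, -1.0, 1.0, out=samples)
    if samples.ndim == 2:  # scipy returns (frames, channels); store channel-major
        samples = samples.T
    return AudioRecording(subject_id=path.stem, samples=samples, sample_rate_hz=int(rate))


def write_wav(rec: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV readable by :func:`read_wav`."""
    if rec.samples.size == 0:
        raise ValueError("cannot write an empty recording")
    if np.max(np.abs(rec.samples)) > 1.0 + 1e-9:
        raise ValueError("samples exceed [-1, 1]; standardize first")
    data = rec.samples.T if rec.samples.ndim == 2 else rec.samples
    pcm = np.round(np.clip(data, -1.0, 1.0) * _INT16_MAX).astype(np.int16)
    wavfile.write(str(path), rec.sample_rate_hz, pcm)


def standardize(rec: AudioRecording, target_rate_hz: int = CANONICAL_RATE_HZ) -> AudioRecording:
    """Return a mono, resampled, peak-normalized copy of ``rec``.

    Channels are averaged to mono, the waveform is polyphase-resampled to
    ``target_rate_hz`` and scaled so max |sample| = 1. An all-zero input is
    returned unchanged apart from the rate, with a logged warning. The
    operation is idempotent.
    """
    if rec.samples.size == 0:
        raise ValueError("cannot standardize an empty recording")
    x = rec.samples
    if x.ndim == 2:
        x = x.mean(axis=0)
    if rec.sample_rate_hz != target_rate_hz:
        frac = Fraction(target_rate_hz, rec.sample_rate_hz)
        x = resample_poly(x, frac.numerator, frac.denominator)
    peak = np.max(np.abs(x))
    if peak == 0.0:
        logger.warning("all-zero recording %s left unnormalized", rec.subject_id)
    else:
        x = x / peak
    return replace(rec, samples=x, sample_rate_hz=target_rate_hz)
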