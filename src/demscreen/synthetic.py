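"""Seeded synthetic two-class speech-like corpus.

The access-controlled ADReSS recordings cannot ship with the package, so
tests and examples run on a generated corpus that carries the prosodic
cues the acoustic systems are built to detect: dementia-like speech shows
a slower syllable rate, more and longer pauses, and flatter intonation
(lower fundamental-frequency variability) than control speech.

The signal model is deliberately minimal: speech is an alternation of
voiced bursts and silences. Each burst is a harmonic tone whose
fundamental is drawn per-syllable from Normal(f0_mean_hz, f0_sd_hz),
band-limited below 4 kHz, amplitude-jittered and Hann-ramped at the
edges; syllable boundaries become pauses with probability ``pause_prob``,
with exponentially distributed pause durations. No formant structure is
modelled — no test depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from demscreen.audio_io import (
    AudioRecording,
    CorpusManifest,
    CANONICAL_RATE_HZ,
    LABEL_AD,
    LABEL_NONAD,
    write_wav,
)

import pandas as pd

#: Fraction of the syllable period that is voiced; the remainder is a
#: short articulatory gap between syllables.
_VOICED_FRACTION = 0.7
#: Harmonics are kept below this frequency (band-limited voicing).
_MAX_HARMONIC_HZ = 3800.0
#: Onset/offset Hann ramp applied to each burst, seconds.
_RAMP_S = 0.010


@dataclass(frozen=True)
class SpeechProfile:
    """Prosodic statistics of one speaker class.

    Parameters
    ----------
    f0_mean_hz, f0_sd_hz : float
        Mean and standard deviation of the per-syllable fundamental.
    syllable_rate_hz : float
        Voiced bursts per second of speech (pauses excluded).
    pause_prob : float
        Probability that a syllable boundary becomes a pause.
    pause_dur_mean_s : float
        Mean of the exponential pause-duration distribution.
    amplitude_sd : float
        Relative amplitude jitter across syllables.
    """

    f0_mean_hz: float
    f0_sd_hz: float
    syllable_rate_hz: float
    pause_prob: float
    pause_dur_mean_s: float
    amplitude_sd: float

    def __post_init__(self) -> None:
        if self.f0_mean_hz <= 0 or self.syllable_rate_hz <= 0 or self.pause_dur_mean_s <= 0:
            raise ValueError("rates and durations must be strictly positive")
        if self.f0_sd_hz < 0 or self.amplitude_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.pause_prob <= 1.0:
            raise ValueError("pause_prob must lie in [0, 1]")


def default_profiles() -> tuple[SpeechProfile, SpeechProfile]:
    """Default (AD, non-AD) profiles — the 'easy' condition.

    The AD profile speaks more slowly, pauses more often and for longer,
    and has a flatter pitch contour. Values are stated in docs/methods.md.
    """
    ad = SpeechProfile(
        f0_mean_hz=180.0,
        f0_sd_hz=12.0,
        syllable_rate_hz=2.5,
        pause_prob=0.50,
        pause_dur_mean_s=0.90,
        amplitude_sd=0.15,
    )
    nonad = SpeechProfile(
        f0_mean_hz=180.0,
        f0_sd_hz=30.0,
        syllable_rate_hz=4.0,
        pause_prob=0.15,
        pause_dur_mean_s=0.30,
        amplitude_sd=0.10,
    )
    return ad, nonad


def profile_pair(gap: str = "easy") -> tuple[SpeechProfile, SpeechProfile]:
    """Return (AD, non-AD) profiles for a named class-gap condition.

    ``easy``  — the defaults; clearly separated prosody.
    ``hard``  — the AD profile moved most of the way toward non-AD.
    ``null``  — identical profiles; labels carry no signal.
    """
    ad, nonad = default_profiles()
    if gap == "easy":
        return ad, nonad
    if gap == "hard":
        hard_ad = SpeechProfile(
            f0_mean_hz=180.0,
            f0_sd_hz=24.0,
            syllable_rate_hz=3.5,
            pause_prob=0.25,
            pause_dur_mean_s=0.45,
            amplitude_sd=0.12,
        )
        return hard_ad, nonad
    if gap == "null":
        return nonad, nonad
    raise ValueError(f"unknown gap {gap!r}; expected easy, hard or null")


@dataclass(frozen=True)
class CorpusSpec:
    """Specification of a synthetic corpus; generation is a pure function of it."""

    n_subjects_per_class: int = 10
    duration_s: float = 30.0
    profile_ad: SpeechProfile = field(default_factory=lambda: default_profiles()[0])
    profile_nonad: SpeechProfile = field(default_factory=lambda: default_profiles()[1])
    seed: int = 0
    sample_rate_hz: int = CANONICAL_RATE_HZ

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ValueError("n_subjects_per_class must be >= 1")
        if self.duration_s < 2 * 0.96:
            raise ValueError("duration_s must be at least two patch durations (1.92 s)")


def _burst(rng: np.random.Generator, profile: SpeechProfile, rate: int) -> np.ndarray:
    """One voiced syllable: band-limited harmonic tone with jitter and ramps."""
    dur = _VOICED_FRACTION / profile.syllable_rate_hz
    n = max(int(round(dur * rate)), 8)
    f0 = max(50.0, rng.normal(profile.f0_mean_hz, profile.f0_sd_hz))
    t = np.arange(n) / rate
    n_harm = max(1, min(12, int(_MAX_HARMONIC_HZ / f0)))
    x = np.zeros(n)
    for h in range(1, n_harm + 1):
        x += (1.0 / h) * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
    amp = max(0.1, 1.0 + rng.normal(0.0, profile.amplitude_sd))
    x *= amp / np.max(np.abs(x))
    ramp = min(int(_RAMP_S * rate), n // 2)
    if ramp > 0:
        env = np.ones(n)
        w = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = w
        env[-ramp:] = w[::-1]
        x *= env
    return x


def generate_recording(
    profile: SpeechProfile,
    duration_s: float,
    subject_id: str,
    label: str | None,
    seed: int,
    sample_rate_hz: int = CANONICAL_RATE_HZ,
) -> AudioRecording:
    """Synthesize one speech-like recording; deterministic given the seed.

    Raises
    ------
    ValueError
        If ``duration_s`` is too short to hold a single syllable.
    """
    rate = sample_rate_hz
    n_total = int(round(duration_s * rate))
    min_syllable = int(round(_VOICED_FRACTION / profile.syllable_rate_hz * rate))
    if n_total < min_syllable:
        raise ValueError(
            f"duration {duration_s} s too short for one syllable at "
            f"{profile.syllable_rate_hz} syllables/s"
        )
    rng = np.random.default_rng(seed)
    gap_n = int(round((1 - _VOICED_FRACTION) / profile.syllable_rate_hz * rate))
    pieces: list[np.ndarray] = []
    total = 0
    while total < n_total:
        b = _burst(rng, profile, rate)
        pieces.append(b)
        total += len(b)
        pieces.append(np.zeros(gap_n))
        total += gap_n
        if rng.random() < profile.pause_prob:
            pause_n = int(round(rng.exponential(profile.pause_dur_mean_s) * rate))
            if pause_n > 0:
                pieces.append(np.zeros(pause_n))
                total += pause_n
    x = np.concatenate(pieces)[:n_total]
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    return AudioRecording(subject_id=subject_id, samples=x, sample_rate_hz=rate, label=label)


def _subject_seed(corpus_seed: int, class_index: int, subject_index: int) -> int:
    """Per-subject seed: first word of SeedSequence([corpus_seed, class, index])."""
    ss = np.random.SeedSequence([corpus_seed, class_index, subject_index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_corpus(spec: CorpusSpec) -> tuple[list[AudioRecording], CorpusManifest]:
    """Generate ``n_subjects_per_class`` recordings per class plus a manifest."""
    recordings: list[AudioRecording] = []
    rows = []
    for class_index, (label, profile) in enumerate(
        [(LABEL_AD, spec.profile_ad), (LABEL_NONAD, spec.profile_nonad)]
    ):
        for i in range(spec.n_subjects_per_class):
            sid = f"{label.lower()}{i:03d}"
            rec = generate_recording(
                profile,
                spec.duration_s,
                sid,
                label,
                _subject_seed(spec.seed, class_index, i),
                spec.sample_rate_hz,
            )
            recordings.append(rec)
            rows.append({"subject_id": sid, "path": f"{sid}.wav", "label": label, "partition": ""})
    return recordings, CorpusManifest(pd.DataFrame(rows))


def write_corpus(
    recordings: list[AudioRecording], manifest: CorpusManifest, out_dir: str | Path
) -> Path:
    """Write WAVs and ``manifest.csv`` under ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = {r.subject_id: r for r in recordings}
    for _, row in manifest.frame.iterrows():
        write_wav(by_id[row["subject_id"]], out / row["path"])
    mpath = out / "manifest.csv"
    manifest.to_csv(mpath)
    return mpath
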