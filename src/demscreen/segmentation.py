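"""Fixed-length non-overlapping patches and speaker-disjoint partitions."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from demscreen.audio_io import AudioRecording, CorpusManifest

logger = logging.getLogger(__name__)

#: Patch length in seconds; with the 10 ms log-mel hop this yields the
#: 96-frame x 64-band input geometry of the embedding front end.
PATCH_DURATION_S = 0.96


@dataclass
class Segment:
    """A 0.96 s slice of one subject's standardized recording."""

    subject_id: str
    index: int
    samples: np.ndarray
    start_time_s: float
    label: str | None = None


def extract_patches(
    rec: AudioRecording, patch_duration_s: float = PATCH_DURATION_S
) -> list[Segment]:
    """Slice ``rec`` into non-overlapping patches; the trailing remainder is dropped.

    A recording shorter than one patch yields an empty list (with a logged
    warning), not an error — short recordings are legal corpus members.
    """
    if rec.samples.ndim != 1:
        raise ValueError("recording must be standardized (mono) before patch extraction")
    n_patch = int(round(patch_duration_s * rec.sample_rate_hz))
    n_segments = len(rec.samples) // n_patch
    if n_segments == 0:
        logger.warning(
            "recording %s (%.2f s) shorter than one %.2f s patch; no segments",
            rec.subject_id,
            rec.duration_s,
            patch_duration_s,
        )
        return []
    return [
        Segment(
            subject_id=rec.subject_id,
            index=i,
            samples=rec.samples[i * n_patch : (i + 1) * n_patch],
            start_time_s=i * patch_duration_s,
            label=rec.label,
        )
        for i in range(n_segments)
    ]


def speaker_partition(
    manifest: CorpusManifest, train_fraction: float = 0.8, seed: int = 0
) -> tuple[CorpusManifest, CorpusManifest]:
    """Stratified, subject-disjoint train/test split.

    Subjects are shuffled within each label and ``round(train_fraction * n)``
    of them assigned to the train partition, so class proportions are
    preserved up to rounding. Deterministic given ``seed``.
    """
    if len(manifest) == 0:
        raise ValueError("cannot partition an empty manifest")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for label, group in manifest.frame.groupby("label", sort=True):
        ids = sorted(group["subject_id"].tolist())
        if len(ids) < 2:
            raise ValueError(f"class {label!r} has {len(ids)} subject(s); need >= 2 to stratify")
        rng.shuffle(ids)
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)  # both partitions non-empty
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    return manifest.subset(train_ids, "train"), manifest.subset(test_ids, "test")
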