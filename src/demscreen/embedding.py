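"""Log-mel front end, 128-D embedders, and PCA whitening.

Each 0.96 s segment becomes a 96-frame x 64-band log-mel matrix (25 ms
analysis window, 10 ms hop, triangular HTK-mel filters spanning
125-7500 Hz, log(mel energy + 0.01)), which a pluggable embedder maps to
a 128-D vector. Embeddings are PCA-whitened to 128 components, with the
whitening statistics fitted on training subjects only.

The built-in :class:`SurrogateEmbedder` is a deterministic seeded random
projection followed by tanh. It preserves the geometry of the log-mel
space (distinct patches map to distinct vectors almost surely) without
any external checkpoint; an adapter wrapping pretrained weights can be
plugged in behind the same :class:`Embedder` interface.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.signal.windows import hann
from sklearn.decomposition import PCA

from demscreen.audio_io import AudioRecording, CANONICAL_RATE_HZ
from demscreen.segmentation import Segment, extract_patches, PATCH_DURATION_S

import pandas as pd

# Front-end constants (the embedding model's published input convention).
N_MELS = 64
N_FRAMES = 96
WINDOW_S = 0.025
HOP_S = 0.010
FMIN_HZ = 125.0
FMAX_HZ = 7500.0
LOG_OFFSET = 0.01
EMBEDDING_DIM = 128
_N_FFT = 512


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    # HTK mel scale: m = 2595 log10(1 + f/700)
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_band_centers_hz(
    n_mels: int = N_MELS, fmin: float = FMIN_HZ, fmax: float = FMAX_HZ
) -> np.ndarray:
    """Center frequencies of the triangular filters, strictly increasing."""
    edges = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    return np.asarray(edges[1:-1])


def mel_filterbank(
    n_mels: int = N_MELS,
    n_fft: int = _N_FFT,
    sample_rate_hz: int = CANONICAL_RATE_HZ,
    fmin: float = FMIN_HZ,
    fmax: float = FMAX_HZ,
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft // 2 + 1)."""
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate_hz)
    edges = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    fb = np.zeros((n_mels, len(fft_freqs)))
    for m in range(n_mels):
        lo, ctr, hi = edges[m], edges[m + 1], edges[m + 2]
        rising = (fft_freqs - lo) / (ctr - lo)
        falling = (hi - fft_freqs) / (hi - ctr)
        fb[m] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


@dataclass
class MelPatch:
    """A 96 x 64 log-mel matrix for one segment."""

    values: np.ndarray
    subject_id: str | None = None
    segment_index: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_FRAMES, N_MELS):
            raise ValueError(
                f"mel patch must be ({N_FRAMES}, {N_MELS}); got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("mel patch contains non-finite values")


_FB_CACHE: dict[tuple, np.ndarray] = {}


def mel_patch(seg: Segment, sample_rate_hz: int = CANONICAL_RATE_HZ) -> MelPatch:
    """Compute the 96 x 64 log-mel matrix of one 0.96 s segment.

    The 0.96 s segment (15360 samples) is reflect-padded by 120 samples on
    each side so the 400-sample window / 160-sample hop STFT yields exactly
    96 frames of 10 ms each.
    """
    expected = int(round(PATCH_DURATION_S * sample_rate_hz))
    if len(seg.samples) != expected:
        raise ValueError(
            f"segment must be exactly {PATCH_DURATION_S} s at {sample_rate_hz} Hz "
            f"({expected} samples); got {len(seg.samples)}"
        )
    win_n = int(round(WINDOW_S * sample_rate_hz))
    hop_n = int(round(HOP_S * sample_rate_hz))
    need = win_n + (N_FRAMES - 1) * hop_n
    pad = (need - expected) // 2
    x = np.pad(seg.samples, pad, mode="reflect")
    frames = as_strided(
        x,
        shape=(N_FRAMES, win_n),
        strides=(x.strides[0] * hop_n, x.strides[0]),
    )
    window = hann(win_n, sym=False)
    spec = np.fft.rfft(frames * window, n=_N_FFT, axis=1)
    power = np.abs(spec) ** 2
    key = (N_MELS, _N_FFT, sample_rate_hz, FMIN_HZ, FMAX_HZ)
    if key not in _FB_CACHE:
        _FB_CACHE[key] = mel_filterbank(*key)
    mel_energy = power @ _FB_CACHE[key].T
    return MelPatch(
        values=np.log(mel_energy + LOG_OFFSET),
        subject_id=seg.subject_id,
        segment_index=seg.index,
        label=seg.label,
    )


class Embedder(ABC):
    """Deterministic map from a :class:`MelPatch` to a 128-D vector."""

    name: str = "embedder"

    @abstractmethod
    def transform(self, patch: MelPatch) -> np.ndarray:
        """Return the 128-D embedding of ``patch``."""

    def transform_many(self, patches: list[MelPatch]) -> np.ndarray:
        return np.stack([self.transform(p) for p in patches])


class SurrogateEmbedder(Embedder):
    """Seeded random projection of the flattened log-mel patch, then tanh.

    A fixed Gaussian matrix (scaled by 1/sqrt(input dim)) projects the
    6144-D flattened patch to 128 dimensions; tanh bounds the output. Same
    seed, same patch -> bit-identical vector.
    """

    def __init__(self, seed: int = 0):
        self.name = f"surrogate(seed={seed})"
        self.seed = seed
        rng = np.random.default_rng(seed)
        d_in = N_FRAMES * N_MELS
        self._projection = rng.standard_normal((d_in, EMBEDDING_DIM)) / np.sqrt(d_in)

    def transform(self, patch: MelPatch) -> np.ndarray:
        return np.tanh(patch.values.ravel() @ self._projection)

    def transform_many(self, patches: list[MelPatch]) -> np.ndarray:
        flat = np.stack([p.values.ravel() for p in patches])
        return np.tanh(flat @ self._projection)


@dataclass
class WhiteningModel:
    """Fitted PCA whitening: center, rotate to principal axes, scale to unit variance."""

    mean: np.ndarray
    projection: np.ndarray  # (n_components, d); rows orthonormal
    component_variances: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.component_variances <= 0):
            raise ValueError("component variances must be strictly positive")


def fit_whitening(vectors: np.ndarray, n_components: int = EMBEDDING_DIM) -> WhiteningModel:
    """Fit a PCA whitening transform on training embeddings.

    Raises
    ------
    ValueError
        With guidance to reduce ``n_components`` when there are fewer
        samples (or less rank) than components.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("vectors must be a 2-D array (n_samples, dim)")
    if X.shape[0] < n_components:
        raise ValueError(
            f"{X.shape[0]} samples cannot support {n_components} components; "
            f"reduce n_components to at most {X.shape[0]}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    variances = np.maximum(pca.explained_variance_, np.finfo(float).tiny)
    if np.any(pca.explained_variance_ <= 1e-12):
        raise ValueError(
            "training embeddings are rank-deficient for the requested number of "
            f"components; reduce n_components below {n_components}"
        )
    return WhiteningModel(
        mean=pca.mean_.copy(),
        projection=pca.components_.copy(),
        component_variances=variances,
    )


def apply_whitening(model: WhiteningModel, v: np.ndarray) -> np.ndarray:
    """Whiten one vector or a stack of vectors: project then scale to unit variance."""
    if model is None:
        raise ValueError("whitening model is not fitted")
    v = np.asarray(v, dtype=np.float64)
    z = (v - model.mean) @ model.projection.T
    return z / np.sqrt(model.component_variances)


def inverse_whitening(model: WhiteningModel, z: np.ndarray) -> np.ndarray:
    """Map whitened coordinates back to the original embedding space."""
    z = np.asarray(z, dtype=np.float64)
    return (z * np.sqrt(model.component_variances)) @ model.projection + model.mean


def extract_features(
    recordings: list[AudioRecording],
    embedder: Embedder,
    whitening: WhiteningModel | None = None,
    patch_duration_s: float = PATCH_DURATION_S,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment, log-mel and embed a list of standardized recordings.

    Returns the (n_segments, 128) feature matrix, rows ordered by
    (recording order, segment index), and an aligned metadata frame with
    ``subject_id``, ``segment_index`` and ``label`` per row. Whitening is
    applied only when a fitted model is supplied; that model must have
    been fitted on training subjects only (the experiment runner enforces
    the call order).
    """
    if not recordings:
        raise ValueError("no recordings supplied")
    patches: list[MelPatch] = []
    meta = []
    for rec in recordings:
        for seg in extract_patches(rec, patch_duration_s):
            patches.append(mel_patch(seg, rec.sample_rate_hz))
            meta.append(
                {"subject_id": seg.subject_id, "segment_index": seg.index, "label": seg.label}
            )
    if not patches:
        raise ValueError("no segments produced; recordings shorter than one patch?")
    X = embedder.transform_many(patches)
    if whitening is not None:
        X = apply_whitening(whitening, X)
    return X, pd.DataFrame(meta)
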