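"""Log-mel front end, surrogate embedder and PCA whitening."""

import numpy as np
import pytest

import demscreen as ds
from demscreen.embedding import (
    EMBEDDING_DIM,
    N_FRAMES,
    N_MELS,
    SurrogateEmbedder,
    apply_whitening,
    extract_features,
    fit_whitening,
    inverse_whitening,
    mel_band_centers_hz,
    mel_filterbank,
    mel_patch,
)
from demscreen.segmentation import Segment, extract_patches


def _segment(samples, sid="s", idx=0):
    return Segment(subject_id=sid, index=idx, samples=np.asarray(samples, float), start_time_s=0.0)


def test_mel_patch_shape(standardized_tone):
    seg = extract_patches(standardized_tone)[0]
    patch = mel_patch(seg)
    assert patch.values.shape == (96, 64)
    assert np.all(np.isfinite(patch.values))


def test_all_zero_segment_gives_log_offset():
    patch = mel_patch(_segment(np.zeros(15360)))
    np.testing.assert_allclose(patch.values, np.log(0.01))


def test_wrong_segment_length_rejected():
    with pytest.raises(ValueError, match="15360"):
        mel_patch(_segment(np.zeros(1000)))


def test_tone_lands_in_nearest_mel_band():
    # filterbank center-frequency table as oracle
    t = np.arange(15360) / 16000
    patch = mel_patch(_segment(0.5 * np.sin(2 * np.pi * 1000 * t)))
    band = int(np.argmax(patch.values.mean(axis=0)))
    centers = mel_band_centers_hz()
    expected = int(np.argmin(np.abs(centers - 1000.0)))
    assert abs(band - expected) <= 1


def test_filterbank_centers_increase_and_cover_range():
    centers = mel_band_centers_hz()
    assert np.all(np.diff(centers) > 0)
    fb = mel_filterbank()
    freqs = np.fft.rfftfreq(512, d=1 / 16000)
    covered = (freqs > centers[0]) & (freqs < centers[-1])
    # every bin between the first and last center is touched by some filter
    assert np.all(fb[:, covered].sum(axis=0) > 0)


def test_surrogate_embedder_deterministic_and_sized(standardized_tone):
    seg = extract_patches(standardized_tone)[0]
    patch = mel_patch(seg)
    emb = SurrogateEmbedder(seed=4)
    v1, v2 = emb.transform(patch), emb.transform(patch)
    assert v1.shape == (EMBEDDING_DIM,)
    np.testing.assert_array_equal(v1, v2)
    assert not np.array_equal(v1, SurrogateEmbedder(seed=5).transform(patch))


def test_surrogate_embedder_separates_distinct_patches():
    rng = np.random.default_rng(0)
    emb = SurrogateEmbedder(seed=0)
    base = rng.normal(size=(N_FRAMES, N_MELS))
    other = base.copy()
    other[10] += 0.5  # one frame differs
    v_base = emb.transform(ds.MelPatch(base))
    v_other = emb.transform(ds.MelPatch(other))
    assert not np.array_equal(v_base, v_other)


def test_whitening_unit_variances_and_centering():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(500, 128)) @ np.diag(np.linspace(0.2, 3.0, 128))
    model = fit_whitening(X)
    Z = apply_whitening(model, X)
    variances = Z.var(axis=0, ddof=1)
    assert np.all(variances > 0.9) and np.all(variances < 1.1)
    np.testing.assert_allclose(apply_whitening(model, model.mean), 0.0, atol=1e-10)


def test_whitening_on_white_data_is_orthonormal():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(2000, 128))
    model = fit_whitening(X)
    gram = model.projection @ model.projection.T
    np.testing.assert_allclose(gram, np.eye(128), atol=1e-8)


def test_whitening_planar_data_reconstructs_exactly():
    # 3 points spanning a 2-D plane inside 128-D: rank-2 PCA is lossless
    rng = np.random.default_rng(3)
    basis = rng.normal(size=(2, 128))
    coeffs = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    X = coeffs @ basis
    model = fit_whitening(X, n_components=2)
    Z = apply_whitening(model, X)
    np.testing.assert_allclose(inverse_whitening(model, Z), X, atol=1e-9)


def test_whitening_affine_property():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(300, 128))
    model = fit_whitening(X)
    a, b = rng.normal(size=(2, 128))
    lhs = apply_whitening(model, a) + apply_whitening(model, b)
    rhs = apply_whitening(model, a + b - model.mean) + apply_whitening(model, model.mean)
    np.testing.assert_allclose(lhs, rhs, atol=1e-9)


def test_whitening_needs_enough_samples():
    with pytest.raises(ValueError, match="reduce n_components"):
        fit_whitening(np.random.default_rng(0).normal(size=(64, 128)), n_components=128)


def test_apply_whitening_requires_fitted_model():
    with pytest.raises(ValueError, match="not fitted"):
        apply_whitening(None, np.zeros(128))


def test_extract_features_composition_and_determinism(standardized_tone):
    emb = SurrogateEmbedder(seed=0)
    X1, meta1 = extract_features([standardized_tone], emb)
    X2, meta2 = extract_features([standardized_tone], emb)
    assert X1.shape == (10, EMBEDDING_DIM)  # 9.6 s -> 10 segments
    assert meta1["subject_id"].unique().tolist() == ["tone"]
    assert meta1["segment_index"].tolist() == list(range(10))
    np.testing.assert_array_equal(X1, X2)
    assert meta1.equals(meta2)


def test_extract_features_rejects_empty_input():
    with pytest.raises(ValueError, match="no recordings"):
        extract_features([], SurrogateEmbedder(0))
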