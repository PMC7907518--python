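"""DemCNN: decimation front end, network mechanics, lr machinery, training."""

import copy

import numpy as np
import pytest

import demscreen as ds
from demscreen.demcnn import (
    BlockSpec,
    DemCNN,
    DemCNNConfig,
    LRCurve,
    NoTrainableRegionError,
    StepSchedule,
    TrainSchedule,
    fit_two_step,
    forward_scores,
    load_demcnn,
    lr_range_test,
    prepare_input,
    save_demcnn,
    select_lr,
)


def _tone(freq, n=32000, rate=16000):
    t = np.arange(n) / rate
    return ds.AudioRecording(f"t{freq}", np.sin(2 * np.pi * freq * t), rate)


# ---------------------------------------------------------------------------
# decimation and input preparation
# ---------------------------------------------------------------------------


def test_decimation_length_and_rate():
    out = ds.decimate(_tone(50), (4, 4, 2))
    assert len(out.samples) == 1000
    assert out.sample_rate_hz == 500


def test_decimation_passband_preserves_50hz_tone():
    rec = _tone(50)
    out = ds.decimate(rec)
    # compare steady-state RMS away from the edges
    mid_in = rec.samples[8000:24000]
    mid_out = out.samples[250:750]
    gain_db = 20 * np.log10(np.sqrt((mid_out**2).mean()) / np.sqrt((mid_in**2).mean()))
    assert abs(gain_db) <= 1.0


def test_decimation_stopband_kills_1khz_tone():
    rec = _tone(1000)
    out = ds.decimate(rec)
    atten_db = 10 * np.log10((rec.samples**2).mean() / max((out.samples**2).mean(), 1e-30))
    assert atten_db >= 40.0


def test_decimation_rejects_too_short_input():
    with pytest.raises(ValueError, match="too short"):
        ds.decimate(ds.AudioRecording("s", np.zeros(10), 16000))


def test_prepare_input_identity_pad_crop():
    x = np.arange(16384, dtype=float)
    np.testing.assert_array_equal(prepare_input(x, 16384), x)
    padded = prepare_input(np.arange(1, 11, dtype=float), 16)
    np.testing.assert_array_equal(padded, [0, 0, 0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 0, 0, 0])
    cropped = prepare_input(np.arange(20, dtype=float), 16)
    np.testing.assert_array_equal(cropped, np.arange(2, 18, dtype=float))


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="6 conv blocks"):
        DemCNNConfig(blocks=tuple(BlockSpec(8) for _ in range(5)))
    with pytest.raises(ValueError, match="num_labels"):
        DemCNNConfig(num_labels=3)
    flat = tuple(BlockSpec(8, dropout_rate=0.1) for _ in range(6))
    with pytest.raises(ValueError, match="dropout"):
        DemCNNConfig(blocks=flat)


def test_forward_two_outputs_softmax_normalized():
    model = ds.build_demcnn(DemCNNConfig(seed=0))
    x = np.random.default_rng(0).normal(size=(3, 16384))
    scores = forward_scores(model, x)
    assert scores.shape == (3, 2)
    np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)


def test_same_seed_same_initial_weights():
    a = DemCNN(DemCNNConfig(seed=7))
    b = DemCNN(DemCNNConfig(seed=7))
    c = DemCNN(DemCNNConfig(seed=8))
    assert a.parameter_checksum() == b.parameter_checksum()
    assert a.parameter_checksum() != c.parameter_checksum()


def test_inference_deterministic_dropout_off():
    model = DemCNN(DemCNNConfig(seed=1))
    x = np.random.default_rng(1).normal(size=(2, 16384))
    np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))


def test_probabilities_finite_on_random_inputs():
    model = DemCNN(DemCNNConfig(seed=2))
    rng = np.random.default_rng(2)
    scores = forward_scores(model, rng.normal(size=(100, 16384)).astype(np.float32))
    assert np.all(np.isfinite(scores))
    assert np.all((scores >= 0) & (scores <= 1))


def test_wrong_input_length_rejected():
    model = DemCNN(DemCNNConfig(seed=0))
    with pytest.raises(ValueError, match="16384"):
        model.forward(np.zeros((1, 1000)))


# ---------------------------------------------------------------------------
# learning-rate machinery
# ---------------------------------------------------------------------------


class _Quadratic:
    """Convex 1-D surrogate: loss = 0.5 c w^2; GD diverges for lr > 2/c."""

    def __init__(self, curvature=10.0, w0=1.0):
        self.c = curvature
        self.w = w0

    def train_step(self, xb, yb, lr):
        loss = 0.5 * self.c * self.w**2
        self.w -= lr * self.c * self.w
        return float(loss)


def test_lr_range_test_grid_and_isolation():
    quad = _Quadratic()
    dummy = np.zeros((4, 1))
    curve = lr_range_test(quad, dummy, dummy, rate_bounds=(1e-3, 1.0), steps=20, seed=0)
    ratios = curve.rates[1:] / curve.rates[:-1]
    np.testing.assert_allclose(ratios, ratios[0])  # exponential spacing
    assert quad.w == 1.0  # original untouched


def test_lr_range_test_shows_divergence_above_stability_threshold():
    c = 10.0
    quad = _Quadratic(curvature=c)
    dummy = np.zeros((4, 1))
    curve = lr_range_test(
        quad, dummy, dummy, rate_bounds=(1e-4, 1.0), steps=60, seed=0, smoothing=0.5
    )
    threshold = 2.0 / c
    # gradient descent contracts for every rate below 2/c: the loss is
    # strictly decreasing throughout the stable region
    below = curve.losses[curve.rates < threshold]
    assert np.all(np.diff(below) < 0)
    # divergence: the loss eventually grows, and the first increase occurs
    # only above the analytic stability threshold
    increases = np.argwhere(np.diff(curve.losses) > 0)
    assert increases.size > 0
    assert curve.rates[int(increases[0, 0]) + 1] > threshold
    assert curve.losses[-1] > curve.losses.min()


def test_lr_range_test_errors_when_immediately_nonfinite():
    class _Explodes:
        def train_step(self, xb, yb, lr):
            return float("nan")

    with pytest.raises(RuntimeError, match="widen rate_bounds"):
        lr_range_test(_Explodes(), np.zeros((2, 1)), np.zeros(2), steps=10)


def test_select_lr_finds_steepest_descent_rate():
    rates = np.geomspace(1e-4, 1.0, 40)
    logr = np.log(rates)
    # sigmoid descent whose steepest drop sits at a known interior rate,
    # followed by a sharp post-minimum rise (the divergence regime)
    steepest = 20
    losses = 2.5 - 1.5 / (1 + np.exp(-(logr - logr[steepest]) / 0.3))
    losses += np.where(logr > logr[32], 5.0 * (logr - logr[32]), 0.0)
    curve = LRCurve(rates=rates, losses=losses)
    chosen = select_lr(curve)
    # brute-force slope scan over the pre-minimum region as oracle
    imin = int(np.argmin(losses))
    slopes = np.diff(losses[: imin + 1]) / np.diff(logr[: imin + 1])
    stable_region = rates[: imin + 1][np.r_[slopes < 0, False]]
    assert chosen in rates
    assert stable_region.min() <= chosen <= stable_region.max()
    assert abs(int(np.argwhere(rates == chosen)[0, 0]) - steepest) <= 2


def test_select_lr_flat_then_cliff_stays_below_cliff():
    rates = np.geomspace(1e-4, 1.0, 30)
    losses = np.concatenate([np.linspace(1.0, 0.95, 20), np.linspace(5.0, 60.0, 10)])
    chosen = select_lr(LRCurve(rates=rates, losses=losses))
    assert chosen < rates[20]


def test_select_lr_rejects_short_or_rising_curves():
    with pytest.raises(ValueError, match="5"):
        select_lr(LRCurve(rates=np.array([0.1, 0.2, 0.3]), losses=np.array([1.0, 2.0, 3.0])))
    rising = LRCurve(rates=np.geomspace(1e-3, 1, 10), losses=np.linspace(1, 9, 10))
    with pytest.raises(NoTrainableRegionError):
        select_lr(rising)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _mini_inputs(n_per_class=2, seed=0):
    """Strongly separated waveforms: dense bursts vs mostly silence."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i in range(n_per_class):
        loud = rng.normal(size=16384) * (rng.random(16384) < 0.9)
        quiet = rng.normal(size=16384) * (rng.random(16384) < 0.05)
        X += [loud, quiet]
        y += ["NONAD", "AD"]
    return np.array(X, dtype=np.float32), y


def test_two_step_history_bookkeeping_and_determinism():
    X, y = _mini_inputs()
    schedule = TrainSchedule(
        step1=StepSchedule(0.05, 4, cycles=1, cycle_length_epochs=3),
        step2=StepSchedule(0.01, 2, cycles=2, cycle_length_epochs=2),
    )
    model1, hist1 = fit_two_step(DemCNN(DemCNNConfig(seed=3)), X, y, schedule, seed=5)
    model2, hist2 = fit_two_step(DemCNN(DemCNNConfig(seed=3)), X, y, schedule, seed=5)
    assert len(hist1) == 3 + 4  # step1 epochs + step2 epochs
    assert [h["step"] for h in hist1] == [1] * 3 + [2] * 4
    assert {h["lr"] for h in hist1} == {0.05, 0.01}
    assert abs(hist1[-1]["loss"] - hist2[-1]["loss"]) < 1e-6
    assert model1.parameter_checksum() == pytest.approx(model2.parameter_checksum())


def test_two_step_rejects_single_class():
    X, _ = _mini_inputs()
    with pytest.raises(ValueError, match="two classes"):
        fit_two_step(DemCNN(DemCNNConfig(seed=0)), X, ["AD"] * len(X), TrainSchedule())


def test_schedule_validation():
    with pytest.raises(ValueError):
        StepSchedule(-0.1, 32)
    with pytest.raises(ValueError):
        StepSchedule("fastest", 32)
    with pytest.raises(ValueError):
        TrainSchedule(loss="hinge")


def test_batchnorm_recalibration_matches_population_stats():
    # after recalibration the first block's running stats equal the
    # population mean/variance of its dropout-free activations
    model = DemCNN(DemCNNConfig(seed=5))
    x = np.random.default_rng(5).normal(size=(6, 16384)).astype(np.float32)
    model.recalibrate_batchnorm(x)
    h = model.convs[0].forward(x[:, None, :], train=False)
    h = h * (h > 0)
    np.testing.assert_allclose(
        model.bns[0].running_mean, h.mean(axis=(0, 2)), rtol=1e-4, atol=1e-6
    )
    n = h.shape[0] * h.shape[2]
    np.testing.assert_allclose(
        model.bns[0].running_var, h.var(axis=(0, 2)) * n / (n - 1), rtol=1e-3, atol=1e-6
    )


def test_checkpoint_round_trip(tmp_path):
    X, y = _mini_inputs()
    schedule = TrainSchedule(
        step1=StepSchedule(0.05, 4, 1, 2), step2=StepSchedule(0.01, 2, 1, 2)
    )
    model, _ = fit_two_step(DemCNN(DemCNNConfig(seed=4)), X, y, schedule, seed=0)
    save_demcnn(model, tmp_path / "cnn.npz")
    back = load_demcnn(tmp_path / "cnn.npz")
    np.testing.assert_array_equal(back.predict_proba(X), model.predict_proba(X))
    assert back.config == model.config
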