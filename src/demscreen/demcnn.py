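"""DemCNN: a raw-waveform 1-D convolutional classifier for dementia screening.

The waveform is anti-alias decimated in stages (factors 4, 4, 2: 16 kHz
-> 500 Hz), length-normalized to ``input_len_samples``, and fed to a
sequential network of six blocks [Conv1D -> ReLU -> BatchNorm ->
Dropout], followed by global average pooling over time and a dense layer
with two outputs (non-AD, AD) trained with cross-entropy. Blocks 5 and 6
use a larger dropout rate than blocks 1-4, which is what gives the model
its regularization bias.

Training is two-step: a first pass at batch size 32, then a second pass
at batch size 2 whose learning rate is, by default, selected
automatically from a learning-rate range test (an exponential sweep of
rates, one mini-batch step each, choosing the rate of steepest loss
descent before the loss minimum).

The network, its backpropagation and the optimizer are implemented
directly on numpy arrays; all randomness (weight init, dropout, batch
shuffling, the range-test batches) is seeded.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.signal import butter, sosfiltfilt

from demscreen.audio_io import AudioRecording, LABELS

logger = logging.getLogger(__name__)

_F32 = np.float32
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockSpec:
    """One convolutional block: Conv1D -> ReLU -> BatchNorm -> Dropout."""

    out_channels: int
    kernel_size: int = 9
    stride: int = 2
    dropout_rate: float = 0.1


def _default_blocks() -> tuple[BlockSpec, ...]:
    channels = (16, 32, 32, 64, 64, 128)
    dropouts = (0.1, 0.1, 0.1, 0.1, 0.3, 0.3)
    return tuple(BlockSpec(c, 9, 2, d) for c, d in zip(channels, dropouts))


@dataclass(frozen=True)
class DemCNNConfig:
    """Architecture and front-end configuration.

    ``input_len_samples`` is the post-decimation length every example is
    cropped/padded to; the default 2**14 = 16384 covers ~32.8 s at the
    500 Hz decimated rate.
    """

    decimation_factors: tuple[int, ...] = (4, 4, 2)
    input_len_samples: int = 16384
    blocks: tuple[BlockSpec, ...] = field(default_factory=_default_blocks)
    num_labels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.blocks) != 6:
            raise ValueError(f"DemCNN has exactly 6 conv blocks; got {len(self.blocks)}")
        if self.num_labels != 2:
            raise ValueError("num_labels is fixed at 2 (non-AD vs AD)")
        early = max(b.dropout_rate for b in self.blocks[:4])
        late = min(b.dropout_rate for b in self.blocks[4:])
        if not late > early:
            raise ValueError(
                "dropout of blocks 5-6 must be strictly greater than that of blocks 1-4"
            )
        if any(f < 1 for f in self.decimation_factors):
            raise ValueError("decimation factors must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decimation_factors"] = list(self.decimation_factors)
        d["blocks"] = [asdict(b) for b in self.blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DemCNNConfig":
        return cls(
            decimation_factors=tuple(d["decimation_factors"]),
            input_len_samples=d["input_len_samples"],
            blocks=tuple(BlockSpec(**b) for b in d["blocks"]),
            num_labels=d["num_labels"],
            seed=d["seed"],
        )


@dataclass(frozen=True)
class StepSchedule:
    """One training step: constant learning rate, fixed batch size,
    ``cycles`` x ``cycle_length_epochs`` epochs. ``learning_rate="auto"``
    means the rate is chosen by :func:`select_lr` on a range test."""

    learning_rate: float | str
    batch_size: int
    cycles: int = 2
    cycle_length_epochs: int = 8

    def __post_init__(self) -> None:
        if isinstance(self.learning_rate, str):
            if self.learning_rate.lower() != "auto":
                raise ValueError("learning_rate must be a positive number or 'auto'")
        elif self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.cycles < 1 or self.cycle_length_epochs < 1:
            raise ValueError("batch_size, cycles and cycle_length_epochs must be >= 1")

    @property
    def epochs(self) -> int:
        return self.cycles * self.cycle_length_epochs


@dataclass(frozen=True)
class TrainSchedule:
    """The two-step schedule: batch 32 first, batch 2 second, cross-entropy loss."""

    step1: StepSchedule = field(default_factory=lambda: StepSchedule(0.1, 32))
    step2: StepSchedule = field(default_factory=lambda: StepSchedule("auto", 2))
    loss: str = "cross_entropy"

    def __post_init__(self) -> None:
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is supported")


@dataclass
class LRCurve:
    """Learning-rate range-test result: smoothed loss per swept rate."""

    rates: np.ndarray
    losses: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        self.losses = np.asarray(self.losses, dtype=np.float64)
        if self.rates.shape != self.losses.shape:
            raise ValueError("rates and losses must have equal length")
        if np.any(np.diff(self.rates) <= 0):
            raise ValueError("rates must be strictly increasing")


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training; carries the last finite history."""

    def __init__(self, message: str, history: list[dict]):
        super().__init__(message)
        self.history = history


class NoTrainableRegionError(RuntimeError):
    """The range-test loss never decreases: no usable learning rate."""


# ---------------------------------------------------------------------------
# decimation front end
# ---------------------------------------------------------------------------


def _stage_min_length() -> int:
    # sosfiltfilt needs len(x) > padlen = 3 * (2 * n_sections + 1); order-8
    # Butterworth -> 4 second-order sections.
    return 3 * (2 * 4 + 1) + 1


def decimate(rec: AudioRecording, factors: tuple[int, ...] = (4, 4, 2)) -> AudioRecording:
    """Stage-wise anti-aliased decimation.

    Each stage low-passes at 0.9 x the *new* Nyquist with a zero-phase
    (forward-backward) order-8 Butterworth filter, then keeps every f-th
    sample; lengths floor at each stage. Factor 1 stages are no-ops.
    """
    if rec.samples.ndim != 1:
        raise ValueError("recording must be standardized (mono) before decimation")
    x = rec.samples.astype(np.float64)
    rate = rec.sample_rate_hz
    for f in factors:
        if f == 1:
            continue
        if rate % f:
            raise ValueError(f"rate {rate} not divisible by decimation factor {f}")
        if len(x) < _stage_min_length():
            raise ValueError(
                f"recording too short ({len(x)} samples) for the anti-aliasing filter"
            )
        sos = butter(8, 0.9 / f, output="sos")
        y = sosfiltfilt(sos, x)
        n_out = len(y) // f
        x = y[: n_out * f : f]
        rate //= f
    return AudioRecording(
        subject_id=rec.subject_id, samples=x, sample_rate_hz=rate, label=rec.label
    )


def prepare_input(samples: np.ndarray, input_len: int = 16384) -> np.ndarray:
    """Center-crop or symmetrically zero-pad to exactly ``input_len`` samples."""
    x = np.asarray(samples, dtype=np.float64)
    n = len(x)
    if n == input_len:
        return x.copy()
    if n > input_len:
        start = (n - input_len) // 2
        return x[start : start + input_len].copy()
    pad = input_len - n
    left = pad // 2
    return np.pad(x, (left, pad - left))


# ---------------------------------------------------------------------------
# numpy layers
# ---------------------------------------------------------------------------


def _unfold(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int]:
    """(N, C, L) -> window view (N, Lout, C, k) over the padded signal."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    n, c, lp = xp.shape
    l_out = (lp - k) // stride + 1
    s0, s1, s2 = xp.strides
    win = as_strided(xp, (n, l_out, c, k), (s0, s2 * stride, s1, s2))
    return win, lp


class _Conv1D:
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int, stride: int):
        fan_in = c_in * k
        self.W = (rng.standard_normal((c_out, c_in, k)) * np.sqrt(2.0 / fan_in)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.k, self.stride, self.pad = k, stride, k // 2
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        win, lp = _unfold(x, self.k, self.stride, self.pad)
        n, l_out = win.shape[0], win.shape[1]
        cols = np.ascontiguousarray(win).reshape(n * l_out, -1)
        w2 = self.W.reshape(self.W.shape[0], -1)
        y = (cols @ w2.T + self.b).reshape(n, l_out, -1).transpose(0, 2, 1)
        if train:
            self._cache = (cols, x.shape, lp, l_out)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, lp, l_out = self._cache
        n, c_out, _ = dy.shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * l_out, c_out)
        self.dW = (dyt.T @ cols).reshape(self.W.shape)
        self.db = dyt.sum(axis=0)
        w2 = self.W.reshape(c_out, -1)
        dcols = (dyt @ w2).reshape(n, l_out, x_shape[1], self.k)
        dxp = np.zeros((n, x_shape[1], lp), dtype=_F32)
        for kk in range(self.k):
            dxp[:, :, kk : kk + self.stride * l_out : self.stride] += dcols[
                :, :, :, kk
            ].transpose(0, 2, 1)
        self._cache = None
        return dxp[:, :, self.pad : lp - self.pad]

    def step(self, lr: float) -> None:
        self.W -= (lr * self.dW).astype(_F32)
        self.b -= (lr * self.db).astype(_F32)

    def parameters(self):
        return [self.W, self.b]


class _BatchNorm1D:
    def __init__(self, c: int):
        self.gamma = np.ones(c, dtype=_F32)
        self.beta = np.zeros(c, dtype=_F32)
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            m = x.shape[0] * x.shape[2]
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            xhat = (x - mu[:, None]) / np.sqrt(var[:, None] + _BN_EPS)
            unbiased = var * m / max(m - 1, 1)
            self.running_mean = (
                (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            ).astype(_F32)
            self.running_var = (
                (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * unbiased
            ).astype(_F32)
            self._cache = (xhat, var, m)
        else:
            xhat = (x - self.running_mean[:, None]) / np.sqrt(
                self.running_var[:, None] + _BN_EPS
            )
        return self.gamma[:, None] * xhat + self.beta[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, var, m = self._cache
        self.dgamma = (dy * xhat).sum(axis=(0, 2))
        self.dbeta = dy.sum(axis=(0, 2))
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        dx = (self.gamma * inv_std)[:, None] * (
            dy - self.dbeta[:, None] / m - xhat * self.dgamma[:, None] / m
        )
        self._cache = None
        return dx.astype(_F32)

    def step(self, lr: float) -> None:
        self.gamma -= (lr * self.dgamma).astype(_F32)
        self.beta -= (lr * self.dbeta).astype(_F32)

    def parameters(self):
        return [self.gamma, self.beta]


class _Dense:
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int):
        self.W = (rng.standard_normal((c_in, c_out)) / np.sqrt(c_in)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.dW = x.T @ dy
        self.db = dy.sum(axis=0)
        self._cache = None
        return dy @ self.W.T

    def step(self, lr: float) -> None:
        self.W -= (lr * self.dW).astype(_F32)
        self.b -= (lr * self.db).astype(_F32)

    def parameters(self):
        return [self.W, self.b]


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class DemCNN:
    """Six 1-D conv blocks -> global average pooling -> dense(2).

    Class order is (NONAD, AD); with argmax decision a probability tie
    resolves to the healthy class.
    """

    classes = LABELS

    def __init__(self, config: DemCNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.convs: list[_Conv1D] = []
        self.bns: list[_BatchNorm1D] = []
        self.dropouts: list[float] = []
        c_in = 1
        for blk in config.blocks:
            self.convs.append(_Conv1D(rng, c_in, blk.out_channels, blk.kernel_size, blk.stride))
            self.bns.append(_BatchNorm1D(blk.out_channels))
            self.dropouts.append(blk.dropout_rate)
            c_in = blk.out_channels
        self.dense = _Dense(rng, c_in, config.num_labels)
        # independent stream for dropout masks, advanced across training steps
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xD0]).generate_state(1)[0]
        )

    # ---- forward / backward ----

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of prepared inputs, shape (N, input_len) -> (N, 2)."""
        x = np.asarray(x, dtype=_F32)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.config.input_len_samples:
            raise ValueError(
                f"inputs must have length {self.config.input_len_samples}; got {x.shape[1]}"
            )
        h = x[:, None, :]
        self._relu_masks = []
        self._drop_masks = []
        for conv, bn, p in zip(self.convs, self.bns, self.dropouts):
            h = conv.forward(h, train)
            relu_mask = h > 0
            h = h * relu_mask
            h = bn.forward(h, train)
            if train:
                self._relu_masks.append(relu_mask)
                keep = (self._dropout_rng.random(h.shape) >= p).astype(_F32)
                h = h * keep / (1.0 - p)
                self._drop_masks.append((keep, p))
        self._gap_len = h.shape[2]
        pooled = h.mean(axis=2)
        return self.dense.forward(pooled.astype(_F32), train)

    def _backward(self, dlogits: np.ndarray) -> None:
        dpooled = self.dense.backward(dlogits.astype(_F32))
        dh = np.repeat(dpooled[:, :, None] / self._gap_len, self._gap_len, axis=2).astype(_F32)
        for conv, bn, relu_mask, (keep, p) in zip(
            reversed(self.convs),
            reversed(self.bns),
            reversed(self._relu_masks),
            reversed(self._drop_masks),
        ):
            dh = dh * keep / (1.0 - p)
            dh = bn.backward(dh)
            dh = dh * relu_mask
            dh = conv.backward(dh)

    # ---- training / inference API ----

    def train_step(self, xb: np.ndarray, yb: np.ndarray, lr: float) -> float:
        """One SGD step on a mini-batch; returns the batch cross-entropy."""
        logits = self.forward(xb, train=True)
        loss, dlogits = _softmax_xent(logits, np.asarray(yb))
        self._backward(dlogits)
        for layer in [*self.convs, *self.bns, self.dense]:
            layer.step(lr)
        return float(loss)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (N, 2), dropout off, batch-norm in eval mode."""
        logits = self.forward(x, train=False)
        return _softmax(logits)

    def predict_labels(self, x: np.ndarray) -> list[str]:
        proba = self.predict_proba(x)
        return [self.classes[i] for i in np.argmax(proba, axis=1)]

    def recalibrate_batchnorm(self, x: np.ndarray, batch_size: int = 64) -> None:
        """Set batch-norm running statistics from the training set.

        Mini-batch training (especially at batch size 2) leaves the
        running mean/variance as a noisy average of the last few tiny
        batches. This pass recomputes population statistics layer by
        layer over ``x`` with dropout off, which is what inference-mode
        normalization should see.
        """
        x = np.asarray(x, dtype=_F32)
        if x.ndim == 1:
            x = x[None, :]
        sums = [None] * len(self.bns)
        sqsums = [None] * len(self.bns)
        counts = [0] * len(self.bns)
        for start in range(0, len(x), batch_size):
            h = x[start : start + batch_size][:, None, :]
            for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
                h = conv.forward(h, train=False)
                h = h * (h > 0)
                s = h.sum(axis=(0, 2), dtype=np.float64)
                sq = (h.astype(np.float64) ** 2).sum(axis=(0, 2))
                sums[i] = s if sums[i] is None else sums[i] + s
                sqsums[i] = sq if sqsums[i] is None else sqsums[i] + sq
                counts[i] += h.shape[0] * h.shape[2]
                # normalize with the statistics accumulated so far is wrong
                # mid-accumulation, so use the layer's population stats from
                # this batch alone to propagate forward
                mu = s / (h.shape[0] * h.shape[2])
                var = sq / (h.shape[0] * h.shape[2]) - mu**2
                hhat = (h - mu[:, None]) / np.sqrt(np.maximum(var[:, None], 0) + _BN_EPS)
                h = (bn.gamma[:, None] * hhat + bn.beta[:, None]).astype(_F32)
        for i, bn in enumerate(self.bns):
            mu = sums[i] / counts[i]
            var = np.maximum(sqsums[i] / counts[i] - mu**2, 0.0)
            bn.running_mean = mu.astype(_F32)
            bn.running_var = (var * counts[i] / max(counts[i] - 1, 1)).astype(_F32)

    # ---- bookkeeping ----

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in [*self.convs, *self.bns, self.dense]:
            out.extend(layer.parameters())
        return out

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(p.astype(np.float64)).sum() for p in self.parameters()))

    def clone(self) -> "DemCNN":
        return copy.deepcopy(self)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _softmax_xent(logits: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray]:
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), y_idx].mean()
    p = np.exp(logp)
    p[np.arange(n), y_idx] -= 1.0
    return float(loss), p / n


def build_demcnn(config: DemCNNConfig | None = None) -> DemCNN:
    """Construct a seeded DemCNN from a validated config."""
    return DemCNN(config or DemCNNConfig())


def forward_scores(model: DemCNN, batch: np.ndarray) -> np.ndarray:
    """Per-input (non-AD, AD) probabilities; inference mode (dropout off)."""
    return model.predict_proba(batch)


# ---------------------------------------------------------------------------
# learning-rate range test and automated selection
# ---------------------------------------------------------------------------


def lr_range_test(
    model,
    inputs: np.ndarray,
    targets: np.ndarray,
    rate_bounds: tuple[float, float] = (1e-5, 1.0),
    steps: int = 40,
    batch_size: int = 2,
    seed: int = 0,
    smoothing: float = 0.8,
) -> LRCurve:
    """Sweep exponentially spaced learning rates, one mini-batch step each.

    Works on a transient copy of ``model`` (any object with a
    ``train_step(xb, yb, lr) -> loss`` method that deep-copies cleanly);
    the original is never modified. Losses are exponentially smoothed
    with bias correction. The sweep stops early if the loss becomes
    non-finite; at least 3 finite points are required.
    """
    low, high = rate_bounds
    if not (0 < low < high):
        raise ValueError("rate_bounds must satisfy 0 < low < high")
    if steps < 3:
        raise ValueError("need at least 3 steps")
    rates = np.geomspace(low, high, steps)
    probe = copy.deepcopy(model)
    rng = np.random.default_rng(seed)
    n = len(inputs)
    smoothed: list[float] = []
    avg = 0.0
    for i, rate in enumerate(rates):
        idx = rng.choice(n, size=min(batch_size, n), replace=n < batch_size)
        loss = probe.train_step(inputs[idx], targets[idx], float(rate))
        if not np.isfinite(loss):
            break
        avg = smoothing * avg + (1 - smoothing) * loss
        smoothed.append(avg / (1 - smoothing ** (i + 1)))
    if len(smoothed) < 3:
        raise RuntimeError(
            "loss became non-finite before 3 range-test points were collected; "
            "widen rate_bounds toward smaller rates"
        )
    return LRCurve(rates=rates[: len(smoothed)], losses=np.array(smoothed))


def select_lr(curve: LRCurve) -> float:
    """Automated rate selection from a range-test curve.

    Returns the rate at which the smoothed loss falls fastest against
    log-rate, considering only the region at or before the loss minimum
    (everything beyond it is the divergence regime).
    """
    n = len(curve.rates)
    if n < 5:
        raise ValueError(f"need at least 5 range-test points; got {n}")
    # light extra smoothing to suppress single-batch noise
    kernel = np.ones(3) / 3.0
    sm = np.convolve(np.pad(curve.losses, 1, mode="edge"), kernel, mode="valid")
    imin = int(np.argmin(sm))
    if imin == 0:
        raise NoTrainableRegionError("loss increases from the smallest rate onward")
    logr = np.log(curve.rates[: imin + 1])
    slopes = np.gradient(sm[: imin + 1], logr)
    best = int(np.argmin(slopes))
    if slopes[best] >= 0:
        raise NoTrainableRegionError("no decreasing region in the range-test loss")
    return float(curve.rates[best])


# ---------------------------------------------------------------------------
# two-step training
# ---------------------------------------------------------------------------


def _labels_to_indices(labels) -> np.ndarray:
    lut = {lab: i for i, lab in enumerate(LABELS)}
    try:
        return np.array([lut[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}; expected one of {LABELS}") from exc


def fit_two_step(
    model: DemCNN,
    inputs: np.ndarray,
    labels,
    schedule: TrainSchedule | None = None,
    seed: int = 0,
    recalibrate_bn: bool = False,
) -> tuple[DemCNN, list[dict]]:
    """Two-step SGD training with cross-entropy loss.

    Step 1 runs ``cycles x cycle_length_epochs`` epochs at batch size 32;
    step 2 continues at batch size 2 with the automatically selected (or
    given) rate. Shuffling is seeded. Returns the trained model and a
    history with one record per epoch (step, epoch, lr, loss, train_acc).

    ``recalibrate_bn=True`` appends a :meth:`DemCNN.recalibrate_batchnorm`
    pass over the training set; the default keeps the procedure to the
    plain two-step scheme.

    Raises
    ------
    TrainingDivergedError
        If the loss becomes non-finite; carries the history so far.
    """
    schedule = schedule or TrainSchedule()
    X = np.asarray(inputs, dtype=_F32)
    y = _labels_to_indices(labels) if not np.issubdtype(
        np.asarray(labels).dtype, np.integer
    ) else np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes in the training set")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E]).generate_state(1)[0])
    history: list[dict] = []

    def run_step(step_no: int, step: StepSchedule, lr: float) -> None:
        for epoch in range(step.epochs):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), step.batch_size):
                idx = order[start : start + step.batch_size]
                losses.append(model.train_step(X[idx], y[idx], lr))
            mean_loss = float(np.mean(losses))
            if not np.isfinite(mean_loss):
                raise TrainingDivergedError(
                    f"loss diverged in step {step_no}, epoch {epoch}", history
                )
            acc = float(np.mean(np.argmax(model.predict_proba(X), axis=1) == y))
            history.append(
                {
                    "step": step_no,
                    "epoch": epoch,
                    "lr": lr,
                    "loss": mean_loss,
                    "train_acc": acc,
                }
            )

    run_step(1, schedule.step1, float(schedule.step1.learning_rate))

    lr2 = schedule.step2.learning_rate
    if isinstance(lr2, str):  # AUTO
        try:
            curve = lr_range_test(
                model,
                X,
                y,
                rate_bounds=(1e-5, 1.0),
                steps=40,
                batch_size=schedule.step2.batch_size,
                seed=int(np.random.SeedSequence([seed, 0x1F]).generate_state(1)[0] & 0x7FFFFFFF),
            )
            lr2 = select_lr(curve)
        except (NoTrainableRegionError, RuntimeError) as exc:
            lr2 = float(schedule.step1.learning_rate) / 10.0
            logger.warning(
                "automatic step-2 rate selection failed (%s); falling back to %.4g",
                exc,
                lr2,
            )
    run_step(2, schedule.step2, float(lr2))
    if recalibrate_bn:
        model.recalibrate_batchnorm(X)
    return model, history


# ---------------------------------------------------------------------------
# persistence and recording-level inference
# ---------------------------------------------------------------------------


def save_demcnn(model: DemCNN, path: str | Path) -> None:
    """Checkpoint as npz with a JSON config sidecar."""
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
    arrays: dict[str, np.ndarray] = {}
    for i, (conv, bn) in enumerate(zip(model.convs, model.bns)):
        arrays[f"conv{i}_W"], arrays[f"conv{i}_b"] = conv.W, conv.b
        arrays[f"bn{i}_gamma"], arrays[f"bn{i}_beta"] = bn.gamma, bn.beta
        arrays[f"bn{i}_rm"], arrays[f"bn{i}_rv"] = bn.running_mean, bn.running_var
    arrays["dense_W"], arrays["dense_b"] = model.dense.W, model.dense.b
    with open(npz_path, "wb") as fh:
        np.savez(fh, **arrays)
    Path(str(npz_path) + ".json").write_text(json.dumps(model.config.to_dict(), sort_keys=True))


def load_demcnn(path: str | Path) -> DemCNN:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
    config = DemCNNConfig.from_dict(json.loads(Path(str(npz_path) + ".json").read_text()))
    model = DemCNN(config)
    with np.load(npz_path) as data:
        for i, (conv, bn) in enumerate(zip(model.convs, model.bns)):
            conv.W, conv.b = data[f"conv{i}_W"], data[f"conv{i}_b"]
            bn.gamma, bn.beta = data[f"bn{i}_gamma"], data[f"bn{i}_beta"]
            bn.running_mean, bn.running_var = data[f"bn{i}_rm"], data[f"bn{i}_rv"]
        model.dense.W, model.dense.b = data["dense_W"], data["dense_b"]
    return model


def recordings_to_inputs(
    recordings: list[AudioRecording], config: DemCNNConfig
) -> tuple[np.ndarray, list[str]]:
    """Decimate and length-normalize recordings into a model input batch."""
    rows = []
    sids = []
    for rec in recordings:
        dec = decimate(rec, config.decimation_factors)
        rows.append(prepare_input(dec.samples, config.input_len_samples))
        sids.append(rec.subject_id)
    return np.stack(rows).astype(_F32), sids


def classify_recordings(model: DemCNN, recordings: list[AudioRecording]) -> dict[str, str]:
    """One whole-recording decision per subject id."""
    X, sids = recordings_to_inputs(recordings, model.config)
    labels = model.predict_labels(X)
    return dict(zip(sids, labels))
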