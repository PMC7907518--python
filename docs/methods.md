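# Methods

This note records the models implemented in `demscreen`, the defaults
and why they were chosen, what the synthetic corpus does and does not
emulate, and the numerical choices that affect results.

## Task and data model

The task is binary screening: given one mono speech recording per
subject, predict AD vs non-AD. Clinical corpora for this task are
access-controlled, so the package ships a generator of speech-like
recordings whose two classes differ only in prosodic statistics. All
experiments here run on that generator; see "What the synthetic corpus
shows" below for the consequences.

Canonical audio form: mono, 16 kHz, peak-normalized to max |x| = 1.
16 kHz makes the 96 × 10 ms log-mel patch geometry exact and sends the
(4, 4, 2) decimation cascade to 500 Hz. Multi-channel audio is averaged
to mono; peak (not RMS) normalization is used because it is the simplest
deterministic loudness contract. `standardize` is idempotent.

## Synthetic corpus

Speech is modelled as an alternation of voiced bursts and silences.
Per subject, syllables are emitted at `syllable_rate_hz` (voiced
fraction 0.7 of the syllable period, the rest an articulatory gap); each
syllable is a harmonic tone with fundamental drawn from
Normal(`f0_mean_hz`, `f0_sd_hz`), harmonics kept below 3.8 kHz with 1/h
amplitude roll-off, a random phase per harmonic, log-amplitude jitter
(`amplitude_sd`) and 10 ms Hann on/off ramps. Each syllable boundary
becomes a pause with probability `pause_prob`; pause durations are
exponential with mean `pause_dur_mean_s`.

Default class profiles (the "easy" condition; units Hz and seconds):

| parameter         | AD   | non-AD | AD markers emulated            |
|-------------------|------|--------|--------------------------------|
| f0_mean_hz        | 180  | 180    | (matched on purpose)           |
| f0_sd_hz          | 12   | 30     | flatter intonation             |
| syllable_rate_hz  | 2.5  | 4.0    | slower speech                  |
| pause_prob        | 0.50 | 0.15   | more frequent pauses           |
| pause_dur_mean_s  | 0.90 | 0.30   | longer pauses                  |
| amplitude_sd      | 0.15 | 0.10   | slightly less stable loudness  |

The "hard" condition moves the AD profile most of the way toward the
control profile; "null" uses identical profiles, so labels carry no
information — this condition underpins the no-leakage checks. Default
recording length is 30 s per subject (≈31 patches), a compromise between
statistical content and test runtime; default corpus size is 10 subjects
per class, a scaled-down version of the balanced class design typical of
this task. Per-subject seeds are
`SeedSequence([corpus_seed, class_index, subject_index])`, so corpora
are reproducible subject by subject and generation is a pure function of
the spec.

**What the synthetic corpus shows — and does not.** It carries exactly
the pause/rate/intonation cues the two systems are designed to detect,
with subjects i.i.d. within a class. It has no formant structure, no
lexical content, no recording-channel variability, no within-subject
drift, and its class differences are larger and cleaner than clinical
reality. Passing tests therefore demonstrate that the pipelines are
implemented correctly and can exploit prosodic differences when present;
they say nothing about accuracy on clinical audio.

## Embedding pipeline

- **Patches:** non-overlapping 0.96 s slices; the trailing remainder is
  discarded (no padding), recordings shorter than one patch yield no
  segments. Segments inherit the subject label (segment-level
  supervision); subject decisions are made later by majority vote.
- **Log-mel:** 25 ms Hann window, 10 ms hop, FFT 512, 64 triangular
  filters on the HTK mel scale (m = 2595 log10(1 + f/700)) spanning
  125–7500 Hz, log(energy + 0.01). A 15360-sample patch yields 94 frames
  under this framing, so each patch is reflect-padded by 120 samples per
  side (to 15600) to produce exactly 96 frames. The offset 0.01 bounds
  the log at silence: an all-zero patch maps to the constant log(0.01).
- **Embedder:** an interface (deterministic MelPatch → R^128). The
  built-in surrogate is a fixed seeded Gaussian random projection of the
  flattened patch scaled by 1/√6144, followed by tanh. A random
  projection approximately preserves distances between log-mel patches,
  which is the property the downstream classifiers need; an adapter
  wrapping pretrained weights can be substituted without touching the
  rest of the pipeline.
- **Whitening:** PCA to 128 components with unit-variance scaling,
  fitted on training-subject embeddings only (the experiment runner
  enforces the order; test statistics are never re-estimated).
  Rank-deficient training sets raise an instructive error rather than
  producing infinite scalings.
- **Classifiers:** scikit-learn estimators behind a thin contract
  (feature width 128, labels {AD, NONAD}, deterministic given the spec
  seed). The MLP reading "hidden width 20" (not 20 layers) is
  deliberate: a 20-layer unregularized stack with step 0.001 and 600
  iterations would not train, and the width reading matches the common
  tooling parameter; width is configurable. The RBF bandwidth uses the
  variance-scaled heuristic γ = 1/(d · Var X). Cosine distance is
  1 − cosine similarity.

## DemCNN

- **Decimation:** per stage, zero-phase (forward-backward) order-8
  Butterworth at 0.9 × the new Nyquist, then take every f-th sample;
  lengths floor at each stage. Zero-phase filtering avoids group delay
  distorting the pause structure. Per-stage stopband attenuation is
  verified ≥ 40 dB by tone probes.
- **Input length:** 2^14 = 16384 samples at 500 Hz (≈32.8 s); longer
  recordings are center-cropped, shorter ones symmetrically
  zero-padded. Fixed length keeps batches rectangular.
- **Blocks:** channels (16, 32, 32, 64, 64, 128), kernel 9, stride 2,
  dropout 0.1 / 0.1 / 0.1 / 0.1 / 0.3 / 0.3 — the larger dropout in
  blocks 5–6 is a structural invariant (it is the model's main
  regularizer), all else is configurable. Global average pooling before
  the dense layer makes the head independent of input length. He
  initialization, seeded; batch-norm ε = 1e-5, momentum 0.1.
- **Training:** plain SGD, cross-entropy. Step 1: rate 0.1, batch 32,
  2 cycles × 8 epochs. Step 2: batch 2, 2 cycles × 8 epochs, rate
  selected automatically ("auto") or given. The 2/8 cycle split is one
  reading of a two-figure schedule notation; all four integers are
  exposed so the alternative reading is a configuration change. The
  "deployment" batch size 2 is treated as the step-2 training batch
  size — the only reading under which it affects optimization.
- **Rate selection:** the range test sweeps exponentially spaced rates,
  one mini-batch step each on a transient copy, recording
  bias-corrected exponentially smoothed loss; selection returns the
  rate of steepest negative slope of loss against log-rate, restricted
  to the region at or before the loss minimum. On a convex quadratic
  (loss ½cw²) this machinery reproduces the analytic behaviour: loss
  contracts for every rate below 2/c and first rises only above it. If
  no decreasing region exists (a converged model can produce this),
  `select_lr` raises; inside `fit_two_step` the auto path then falls
  back to step1_rate/10 with a logged warning, so an experiment is not
  aborted by a healthy plateau.
- **Batch-norm recalibration (opt-in):** batch-2 training leaves the
  running statistics as a noisy average of the last few tiny batches.
  `DemCNN.recalibrate_batchnorm` re-estimates population statistics
  over the training set with dropout off. It measurably stabilizes
  held-out accuracy on separable corpora but also makes per-run
  decisions more decisive, which widens the run-to-run dispersion of
  chance-level results on uninformative data. The default training
  procedure is the plain two-step scheme; the pass is available as
  `fit_two_step(..., recalibrate_bn=True)`.
- **Decision:** one whole-recording decision per subject (no
  majority vote for the CNN); class order (NONAD, AD) with argmax means
  an exact probability tie resolves to the healthy class, matching the
  vote tie rule.

## Evaluation protocol

Speakers are split 80/20, stratified by label, subject-disjoint,
deterministic given the seed (both partitions are forced non-empty per
class). AD is the positive class for precision/recall/F1; a per-class
breakdown is also reported. Zero-denominator ratios report 0 with a
warning. Reports contain the config echo, seeds, per-subject predictions
with vote counts, subject-level metrics and (for the embedding system)
segment-level metrics; serialization is key-sorted JSON with no
timestamps, so identical configurations produce byte-identical reports.

## Numerical choices and degenerate inputs

- All-zero recordings pass through `standardize` unnormalized (warning).
- WAV I/O is 16-bit PCM; round-trips preserve length exactly and values
  to one quantization step.
- The CNN runs in float32; experiment-level determinism holds for a
  fixed seed within one BLAS configuration.
- `decimate` requires the input to exceed the forward-backward filter's
  padding length (28 samples per stage) and integer rate divisibility.
- Problem sizes in the shipped tests and the acceptance script —
  corpora of 4–20 subjects per class at 30 s — were chosen so the full
  suite exercises every stage, including complete two-step CNN
  trainings, at desk scale.

## Known limitations

- The surrogate embedder preserves geometry but learns nothing; absolute
  accuracies with a pretrained embedder would differ.
- Synthetic prosody is far cleaner than clinical speech; reported
  accuracies characterize the implementation, not clinical performance.
- Per-run held-out accuracy on small test sets (4–8 subjects) is highly
  dispersed because all decisions share one trained model; averages over
  seeds should be read with that correlation in mind.
- Single-threaded CPU training only; the CNN is sized for minutes-scale
  experiments, not large corpora.
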