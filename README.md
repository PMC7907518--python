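# demscreen

Acoustic screening of Alzheimer's dementia (AD) from spontaneous speech.

Speech carries early markers of cognitive decline: people with AD tend to
speak more slowly, pause more often and for longer, and show flatter
intonation. `demscreen` implements two purely acoustic classifiers that
exploit these cues to label a speaker as AD or non-AD from a single mono
recording, plus a seeded synthetic speech-like corpus generator so the
whole pipeline is testable without access-controlled clinical audio
(real corpora of this kind, e.g. DementiaBank, are gated).

## The two systems

**1. Embedding pipeline (segment classify + majority vote).**
A recording is standardized (mono, 16 kHz, peak-normalized) and cut into
non-overlapping patches of 0.96 s. Each patch is converted to a log-mel
matrix

> X ∈ R^(96×64), X_tf = log(Σ_k M_fk |STFT(x)_tk|² + 0.01),

with 96 frames of 10 ms (25 ms analysis window) and 64 triangular
HTK-mel filters spanning 125–7500 Hz. A pluggable embedder maps each
patch to an embedding e ∈ R^128 (the built-in surrogate is a fixed
seeded random projection with a tanh nonlinearity; an adapter wrapping a
pretrained audio network fits behind the same interface). Embeddings are
PCA-whitened to 128 components — z = Λ^(-1/2) Uᵀ(e − μ), statistics
fitted on training speakers only — and one of five segment classifiers
is trained on them: an RBF-kernel SVM (γ = 1/(128·Var X)), a linear SVM,
a perceptron, an MLP (one hidden layer of width 20, SGD, 600 iterations,
step 0.001), or a 1-nearest-neighbour rule under cosine distance. A
subject's decision is the **majority vote** over their segments; ties
resolve to non-AD.

**2. DemCNN (raw-waveform CNN).**
The standardized waveform is anti-alias decimated in stages (factors
4, 4, 2; each stage low-passes at 0.9× the new Nyquist with a zero-phase
order-8 Butterworth before keeping every f-th sample), bringing 16 kHz
to 500 Hz. The 500 Hz signal, center-cropped/zero-padded to 2^14
samples, feeds six blocks of [Conv1D → ReLU → BatchNorm → Dropout]
(channels 16-32-32-64-64-128, kernel 9, stride 2; dropout 0.1 in blocks
1–4 and 0.3 in blocks 5–6), global average pooling, and a dense layer
with 2 outputs trained with cross-entropy. Training is **two-step**:
batch size 32 first, then batch size 2 with a learning rate selected
automatically from a learning-rate range test (exponential rate sweep,
one mini-batch step per rate; the chosen rate is the point of steepest
loss descent before the loss minimum). One decision per recording. The
network and its backpropagation are implemented directly on numpy.

## Worked example

```bash
$ demscreen generate --out demo --n-per-class 5 --duration 30 --seed 7
wrote 10 recordings and demo/manifest.csv

$ demscreen evaluate --system embed --data demo --seed 7 --out demo/report.json
embedding: accuracy 1.000, precision 1.000, recall 1.000, F1 1.000 on 2 held-out subjects
report -> demo/report.json
```

The generator wrote 5 AD-profile and 5 control-profile speakers of 30 s
each. `evaluate` split them 80/20 by speaker (8 train, 2 held out),
fitted whitening and a linear SVM on the training speakers' segments,
and voted per held-out subject. In `demo/report.json` the two held-out
speakers read:

```
ad003     true=AD     predicted=AD     votes {AD: 26, NONAD: 5}
nonad003  true=NONAD  predicted=NONAD  votes {AD: 9,  NONAD: 22}
```

i.e. 26 of ad003's 31 segments were individually classified as AD, so
the majority vote labels the speaker AD. Accuracy/precision/recall/F1
are computed over held-out subjects with AD as the positive class. The
same corpus can be run through the CNN with `--system cnn`, and
`demscreen train-seg` / `demscreen train-cnn` fit and persist individual
models.

The library mirrors the CLI: `run_experiment("embedding" | "demcnn",
CorpusSpec(...), seed=...)` returns a report object carrying per-subject
predictions, metrics and the full training history, and is byte-for-byte
reproducible for a fixed seed.

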