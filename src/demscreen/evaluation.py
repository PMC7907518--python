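"""Subject-level aggregation, metrics, and end-to-end experiment runners.

The embedding system produces one label per 0.96 s segment; a subject's
decision is the majority vote over their segments (tie -> NONAD, the
healthy class, so an undecided subject never raises a false alarm).
DemCNN classifies whole recordings, one decision per subject, so its
vote table is empty.

Metrics follow the standard binary definitions with AD as the positive
class; a per-class breakdown is also reported.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np

from demscreen.audio_io import (
    AudioRecording,
    CorpusManifest,
    LABELS,
    LABEL_AD,
    LABEL_NONAD,
    standardize,
)
from demscreen.classifiers import (
    ClassifierKind,
    ClassifierSpec,
    train_segment_classifier,
    predict_segments,
)
from demscreen.demcnn import (
    DemCNN,
    DemCNNConfig,
    TrainSchedule,
    fit_two_step,
    recordings_to_inputs,
)
from demscreen.embedding import (
    SurrogateEmbedder,
    apply_whitening,
    extract_features,
    fit_whitening,
)
from demscreen.segmentation import speaker_partition
from demscreen.synthetic import CorpusSpec, generate_corpus

logger = logging.getLogger(__name__)


@dataclass
class SubjectPrediction:
    """One subject's decision; ``vote_counts`` is empty for whole-recording models."""

    subject_id: str
    predicted: str
    vote_counts: dict[str, int] = field(default_factory=dict)
    true_label: str | None = None

    def __post_init__(self) -> None:
        if self.predicted not in LABELS:
            raise ValueError(f"predicted label must be one of {LABELS}")


@dataclass
class ConfusionCounts:
    """Binary confusion table with AD as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class Metrics:
    precision: float
    recall: float
    f1: float
    accuracy: float


def majority_vote(segment_labels: list[str]) -> str:
    """Label with the larger count; a tie resolves to NONAD."""
    if not segment_labels:
        raise ValueError("cannot vote over an empty label list")
    counts = Counter(segment_labels)
    bad = set(counts) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels in vote: {sorted(bad)}")
    if counts[LABEL_AD] > counts[LABEL_NONAD]:
        return LABEL_AD
    return LABEL_NONAD


def confusion_counts(preds: list[SubjectPrediction]) -> ConfusionCounts:
    """Tally a confusion table; every prediction must carry a true label."""
    tp = fp = fn = tn = 0
    for p in preds:
        if p.true_label is None:
            raise ValueError(f"prediction for {p.subject_id} has no true label")
        if p.true_label == LABEL_AD:
            if p.predicted == LABEL_AD:
                tp += 1
            else:
                fn += 1
        else:
            if p.predicted == LABEL_AD:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Precision, recall, F1 and accuracy; zero-denominator ratios are 0 with a warning."""
    if c.n < 1:
        raise ValueError("empty confusion table")

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
            return 0.0
        return num / den

    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = (c.tp + c.tn) / c.n
    return Metrics(precision=precision, recall=recall, f1=f1, accuracy=accuracy)


def metrics_by_class(preds: list[SubjectPrediction]) -> dict[str, Metrics]:
    """Per-class metrics (each class in turn treated as positive)."""
    c = confusion_counts(preds)
    flipped = ConfusionCounts(tp=c.tn, fp=c.fn, fn=c.fp, tn=c.tp)
    return {LABEL_AD: compute_metrics(c), LABEL_NONAD: compute_metrics(flipped)}


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------


@dataclass
class ExperimentReport:
    """Deterministic record of one end-to-end run (no timestamps)."""

    system: str
    seed: int
    config: dict
    train_subjects: list[str]
    test_subjects: list[str]
    predictions: list[SubjectPrediction]
    metrics: Metrics
    per_class: dict[str, Metrics]
    segment_metrics: Metrics | None = None
    history: list[dict] | None = None

    def to_json(self) -> str:
        payload = {
            "system": self.system,
            "seed": self.seed,
            "config": self.config,
            "train_subjects": self.train_subjects,
            "test_subjects": self.test_subjects,
            "predictions": [asdict(p) for p in self.predictions],
            "metrics": asdict(self.metrics),
            "per_class": {k: asdict(v) for k, v in self.per_class.items()},
            "segment_metrics": asdict(self.segment_metrics) if self.segment_metrics else None,
            "history": self.history,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def subjects_csv(self) -> str:
        lines = ["subject_id,true,predicted,votes_ad,votes_nonad"]
        for p in self.predictions:
            lines.append(
                f"{p.subject_id},{p.true_label},{p.predicted},"
                f"{p.vote_counts.get(LABEL_AD, '')},{p.vote_counts.get(LABEL_NONAD, '')}"
            )
        return "\n".join(lines) + "\n"


def _run_embedding_system(
    train_recs: list[AudioRecording],
    test_recs: list[AudioRecording],
    classifier_spec: ClassifierSpec,
    embedder_seed: int,
) -> tuple[list[SubjectPrediction], Metrics]:
    embedder = SurrogateEmbedder(seed=embedder_seed)
    # whitening statistics come from training subjects only
    X_train_raw, meta_train = extract_features(train_recs, embedder)
    whitening = fit_whitening(X_train_raw, n_components=128)
    X_train = apply_whitening(whitening, X_train_raw)
    X_test_raw, meta_test = extract_features(test_recs, embedder)
    X_test = apply_whitening(whitening, X_test_raw)

    model = train_segment_classifier(X_train, meta_train["label"].to_numpy(), classifier_spec)
    seg_pred = predict_segments(model, X_test)
    meta_test = meta_test.assign(predicted=seg_pred)

    seg_counts = confusion_counts(
        [
            SubjectPrediction(
                subject_id=f"{r.subject_id}:{r.segment_index}",
                predicted=r.predicted,
                true_label=r.label,
            )
            for r in meta_test.itertuples()
        ]
    )
    seg_metrics = compute_metrics(seg_counts)

    preds = []
    for sid, group in meta_test.groupby("subject_id", sort=True):
        votes = Counter(group["predicted"])
        preds.append(
            SubjectPrediction(
                subject_id=sid,
                predicted=majority_vote(list(group["predicted"])),
                vote_counts={lab: int(votes.get(lab, 0)) for lab in LABELS},
                true_label=group["label"].iloc[0],
            )
        )
    return preds, seg_metrics


def _run_demcnn_system(
    train_recs: list[AudioRecording],
    test_recs: list[AudioRecording],
    config: DemCNNConfig,
    schedule: TrainSchedule,
    seed: int,
) -> tuple[list[SubjectPrediction], list[dict]]:
    model = DemCNN(config)
    X_train, _ = recordings_to_inputs(train_recs, config)
    y_train = [r.label for r in train_recs]
    model, history = fit_two_step(model, X_train, y_train, schedule, seed=seed)
    X_test, sids = recordings_to_inputs(test_recs, config)
    labels = model.predict_labels(X_test)
    true_by_sid = {r.subject_id: r.label for r in test_recs}
    preds = [
        SubjectPrediction(subject_id=s, predicted=lab, true_label=true_by_sid[s])
        for s, lab in sorted(zip(sids, labels))
    ]
    return preds, history


def run_experiment(
    system: str,
    corpus: CorpusSpec | tuple[list[AudioRecording], CorpusManifest],
    train_fraction: float = 0.8,
    seed: int = 0,
    classifier_spec: ClassifierSpec | None = None,
    cnn_config: DemCNNConfig | None = None,
    schedule: TrainSchedule | None = None,
) -> ExperimentReport:
    """Run one end-to-end experiment on a synthetic or supplied corpus.

    ``system`` is ``"embedding"`` (patch/embed/whiten/classify/majority
    vote) or ``"demcnn"`` (decimate/CNN, one decision per subject).
    ``corpus`` is either a :class:`CorpusSpec` (generated here) or an
    already-loaded ``(recordings, manifest)`` pair. All randomness —
    the speaker split, classifier/CNN seeds, batch shuffling — derives
    from ``seed``, so two runs with the same arguments produce
    byte-identical reports. Training artifacts (whitening statistics,
    classifier fits, CNN weights) never see test subjects.
    """
    if system not in ("embedding", "demcnn"):
        raise ValueError(f"unknown system {system!r}; expected 'embedding' or 'demcnn'")

    ss = np.random.SeedSequence([seed, 0xE0 if system == "embedding" else 0xC0])
    split_seed, model_seed = (int(s & 0x7FFFFFFF) for s in ss.generate_state(2))

    if isinstance(corpus, CorpusSpec):
        recordings, manifest = generate_corpus(corpus)
        corpus_echo: dict = {
            "kind": "synthetic",
            "n_subjects_per_class": corpus.n_subjects_per_class,
            "duration_s": corpus.duration_s,
            "seed": corpus.seed,
        }
    else:
        recordings, manifest = corpus
        corpus_echo = {"kind": "loaded", "n_subjects": len(manifest)}

    recordings = [standardize(r) for r in recordings]
    train_manifest, test_manifest = speaker_partition(manifest, train_fraction, split_seed)
    train_ids, test_ids = set(train_manifest.subject_ids), set(test_manifest.subject_ids)
    by_sid = {r.subject_id: r for r in recordings}
    train_recs = [by_sid[s] for s in sorted(train_ids)]
    test_recs = [by_sid[s] for s in sorted(test_ids)]

    segment_metrics = None
    history = None
    if system == "embedding":
        spec = classifier_spec or ClassifierSpec(ClassifierKind.LINEAR_SVM, seed=model_seed)
        preds, segment_metrics = _run_embedding_system(train_recs, test_recs, spec, model_seed)
        config_echo = {
            "corpus": corpus_echo,
            "train_fraction": train_fraction,
            "classifier": json.loads(spec.to_json()),
            "embedder_seed": model_seed,
        }
    else:
        config = cnn_config or DemCNNConfig(seed=model_seed)
        sched = schedule or TrainSchedule()
        preds, history = _run_demcnn_system(train_recs, test_recs, config, sched, model_seed)
        config_echo = {
            "corpus": corpus_echo,
            "train_fraction": train_fraction,
            "cnn": config.to_dict(),
            "schedule": {
                "step1": asdict(sched.step1),
                "step2": asdict(sched.step2),
                "loss": sched.loss,
            },
        }

    metrics = compute_metrics(confusion_counts(preds))
    return ExperimentReport(
        system=system,
        seed=seed,
        config=config_echo,
        train_subjects=sorted(train_ids),
        test_subjects=sorted(test_ids),
        predictions=preds,
        metrics=metrics,
        per_class=metrics_by_class(preds),
        segment_metrics=segment_metrics,
        history=history,
    )
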