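"""The five segment-level classifiers operating on 128-D features.

Segment supervision: every 0.96 s segment inherits its speaker's label
and a classifier learns to predict it; per-subject decisions come later
via majority vote (see :mod:`demscreen.evaluation`).

Configurations
--------------
SVM_RBF    radial-basis-function SVM, bandwidth from the variance-scaled
           ("scale") heuristic gamma = 1 / (d * Var[X]).
LINEAR_SVM linear-kernel SVM.
PERCEPTRON classical perceptron.
MLP        multi-layer perceptron with one hidden layer of width 20,
           stochastic gradient descent, 600 iterations, step size 0.001.
           (Width, not depth: a 20-layer unregularized stack would not
           train under these settings; width is configurable.)
NN1        single nearest neighbor under cosine distance
           (1 - cosine similarity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import joblib
import numpy as np
from sklearn.linear_model import Perceptron
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC

from demscreen.audio_io import LABELS
from demscreen.embedding import EMBEDDING_DIM


class ClassifierKind(str, Enum):
    SVM_RBF = "SVM_RBF"
    LINEAR_SVM = "LINEAR_SVM"
    PERCEPTRON = "PERCEPTRON"
    MLP = "MLP"
    NN1 = "NN1"


#: Short CLI aliases.
KIND_ALIASES = {
    "svm": ClassifierKind.SVM_RBF,
    "lsvm": ClassifierKind.LINEAR_SVM,
    "perc": ClassifierKind.PERCEPTRON,
    "mlp": ClassifierKind.MLP,
    "1nn": ClassifierKind.NN1,
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus hyperparameter overrides and a seed."""

    kind: ClassifierKind
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind.value, "hyperparameters": self.hyperparameters, "seed": self.seed},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierSpec":
        d = json.loads(text)
        return cls(ClassifierKind(d["kind"]), d.get("hyperparameters", {}), d.get("seed", 0))


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.kind is ClassifierKind.SVM_RBF:
        return SVC(kernel="rbf", gamma="scale", random_state=spec.seed, **hp)
    if spec.kind is ClassifierKind.LINEAR_SVM:
        hp.setdefault("max_iter", 10000)
        hp.setdefault("dual", "auto")
        return LinearSVC(random_state=spec.seed, **hp)
    if spec.kind is ClassifierKind.PERCEPTRON:
        return Perceptron(random_state=spec.seed, **hp)
    if spec.kind is ClassifierKind.MLP:
        hp.setdefault("hidden_layer_sizes", (20,))
        hp.setdefault("solver", "sgd")
        hp.setdefault("max_iter", 600)
        hp.setdefault("learning_rate_init", 0.001)
        return MLPClassifier(random_state=spec.seed, **hp)
    if spec.kind is ClassifierKind.NN1:
        hp.setdefault("n_neighbors", 1)
        hp.setdefault("metric", "cosine")
        return KNeighborsClassifier(**hp)
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


@dataclass
class TrainedSegmentModel:
    spec: ClassifierSpec
    estimator: object
    classes: tuple[str, str] = LABELS

    @property
    def is_fitted(self) -> bool:
        return self.estimator is not None and hasattr(self.estimator, "classes_")


def train_segment_classifier(
    features: np.ndarray, labels, spec: ClassifierSpec
) -> TrainedSegmentModel:
    """Fit one of the five segment classifiers; deterministic given ``spec.seed``."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] != EMBEDDING_DIM:
        raise ValueError(
            f"features must be (n, {EMBEDDING_DIM}); got {X.shape}"
        )
    if len(y) != X.shape[0]:
        raise ValueError("features and labels length mismatch")
    present = set(np.unique(y))
    if len(present) < 2:
        raise ValueError(f"training set contains a single class {sorted(present)}")
    if not present <= set(LABELS):
        raise ValueError(f"labels must be drawn from {LABELS}; got {sorted(present)}")
    est = _build_estimator(spec)
    est.fit(X, y)
    return TrainedSegmentModel(spec=spec, estimator=est)


def predict_segments(model: TrainedSegmentModel, features: np.ndarray) -> list[str]:
    """Predict one label per feature row."""
    if not model.is_fitted:
        raise RuntimeError("model is not fitted")
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != EMBEDDING_DIM:
        raise ValueError(f"features must be (n, {EMBEDDING_DIM}); got {X.shape}")
    return list(model.estimator.predict(X))


def save_model(model: TrainedSegmentModel, path: str | Path) -> None:
    """Persist the fitted estimator plus a JSON sidecar with its spec."""
    path = Path(path)
    joblib.dump({"format_version": 1, "estimator": model.estimator}, path)
    Path(str(path) + ".json").write_text(model.spec.to_json())


def load_model(path: str | Path) -> TrainedSegmentModel:
    path = Path(path)
    payload = joblib.load(path)
    spec = ClassifierSpec.from_json(Path(str(path) + ".json").read_text())
    return TrainedSegmentModel(spec=spec, estimator=payload["estimator"])
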