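"""Activity classifiers and the two cross-validation protocols.

Three gait activities are distinguished per stride: level walking, stairs
ascending and stairs descending.  Two model families are supported: an RBF
support-vector machine in a one-vs-rest configuration (ties resolved by the
highest decision score, then by the fixed class order walk < stairs_up <
stairs_down) and a depth-3 decision tree.  No class re-weighting is applied
even though level walking typically contributes about twice as many strides
as either stairs class.

Evaluation follows two subject-aware protocols:

* leave-one-subject-out (LOSO): one run per subject; that subject's strides
  form the test fold, everyone else's the training fold;
* leave-one-trial-out (LOTO): one run per trial; the test fold is one trial
  and the training fold contains all trials of all OTHER subjects, so a
  subject never appears on both sides of a split.

The min-max scaler is refitted on the training fold of every run.  Reports
carry per-run accuracy and macro-averaged precision/recall/F1 over the three
targets, their mean/std/min/max across runs, and the sum of the per-run 3x3
confusion matrices (rows = true class, columns = predicted class).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Sequence

import joblib
import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import InvalidInputError
from .features import ScalerParams, apply_scaler, fit_scaler


class ActivityClass(str, Enum):
    WALK = "walk"
    STAIRS_UP = "stairs_up"
    STAIRS_DOWN = "stairs_down"


#: Fixed class order used for confusion matrices and tie-breaking.
CLASS_ORDER: List[ActivityClass] = [ActivityClass.WALK, ActivityClass.STAIRS_UP, ActivityClass.STAIRS_DOWN]
_CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}

MODEL_KINDS = ("svm_ovr", "tree_depth3")


@dataclass(frozen=True)
class LabeledSample:
    """One stride: raw (unscaled) feature vector, activity label, provenance."""

    features: np.ndarray
    label: ActivityClass
    subject_id: str
    trial_id: str

    def __post_init__(self):
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        object.__setattr__(self, "label", ActivityClass(self.label))


class _ConstantClassifier:
    """Fallback when the training fold contains a single class."""

    def __init__(self, class_index: int):
        self.class_index = class_index

    def predict(self, X):
        return np.full(len(X), self.class_index, dtype=int)


@dataclass
class TrainedModel:
    """Estimator plus the scaler fitted on its training fold."""

    estimator: object
    scaler: ScalerParams
    model_kind: str
    seed: int

    def predict(self, raw_features: np.ndarray) -> List[ActivityClass]:
        X = np.asarray(raw_features, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        idx = self.estimator.predict(apply_scaler(self.scaler, X))
        return [CLASS_ORDER[int(i)] for i in idx]

    def save(self, path) -> None:
        joblib.dump({"estimator": self.estimator, "scaler": self.scaler, "model_kind": self.model_kind, "seed": self.seed}, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        return cls(**blob)


def _canonical_order(samples: Sequence[LabeledSample]) -> List[LabeledSample]:
    # Sort by provenance then feature bytes so shuffled inputs train identically.
    return sorted(
        samples,
        key=lambda s: (s.subject_id, s.trial_id, _CLASS_INDEX[s.label], tuple(np.round(s.features, 12))),
    )


def train_classifier(samples: Sequence[LabeledSample], model_kind: str = "svm_ovr", seed: int = 0) -> TrainedModel:
    """Fit scaler + classifier on the given samples; deterministic for a seed."""
    if model_kind not in MODEL_KINDS:
        raise InvalidInputError(f"model_kind must be one of {MODEL_KINDS}")
    samples = _canonical_order(samples)
    if not samples:
        raise InvalidInputError("empty training set")
    X = np.vstack([s.features for s in samples])
    y = np.array([_CLASS_INDEX[s.label] for s in samples])
    scaler = fit_scaler(X)
    Xs = apply_scaler(scaler, X)
    classes = np.unique(y)
    if len(classes) == 1:
        estimator = _ConstantClassifier(int(classes[0]))
    elif model_kind == "svm_ovr":
        estimator = OneVsRestClassifier(SVC(kernel="rbf", C=1.0, random_state=seed))
        estimator.fit(Xs, y)
    else:
        estimator = DecisionTreeClassifier(max_depth=3, random_state=seed)
        estimator.fit(Xs, y)
    return TrainedModel(estimator=estimator, scaler=scaler, model_kind=model_kind, seed=seed)


# -- metrics ----------------------------------------------------------------


def confusion_from_predictions(y_true: Sequence[ActivityClass], y_pred: Sequence[ActivityClass]) -> np.ndarray:
    """3x3 integer confusion matrix in CLASS_ORDER (rows true, columns predicted)."""
    cm = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[_CLASS_INDEX[ActivityClass(t)], _CLASS_INDEX[ActivityClass(p)]] += 1
    return cm


def macro_metrics(confusion: np.ndarray) -> Dict[str, float]:
    """Accuracy and macro precision/recall/F1 over the three targets.

    Per-class ratios with a zero denominator contribute 0 to the macro mean.
    """
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else 0.0
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    diag = np.diag(cm)
    precision = np.divide(diag, col, out=np.zeros(3), where=col > 0)
    recall = np.divide(diag, row, out=np.zeros(3), where=row > 0)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom, out=np.zeros(3), where=denom > 0)
    return {
        "accuracy": accuracy,
        "precision": float(precision.mean()),
        "recall": float(recall.mean()),
        "f1": float(f1.mean()),
    }


@dataclass
class EvaluationReport:
    """Per-run metrics, summary statistics across runs, summed confusion matrix."""

    protocol: str
    model_kind: str
    runs: List[Dict] = field(default_factory=list)
    confusion: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=int))

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def summary(self) -> Dict[str, Dict[str, float]]:
        out = {}
        for metric in ("accuracy", "precision", "recall", "f1"):
            vals = np.array([r[metric] for r in self.runs], dtype=float)
            out[metric] = {
                "mean": float(vals.mean()),
                "std": float(vals.std()),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        return out

    def to_dict(self) -> Dict:
        return {
            "protocol": self.protocol,
            "model_kind": self.model_kind,
            "n_runs": self.n_runs,
            "runs": self.runs,
            "summary": self.summary(),
            "confusion": {
                "labels": [c.value for c in CLASS_ORDER],
                "rows_are": "true_class",
                "columns_are": "predicted_class",
                "matrix": self.confusion.tolist(),
            },
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _evaluate_folds(samples, folds, model_kind, seed, protocol) -> EvaluationReport:
    report = EvaluationReport(protocol=protocol, model_kind=model_kind)
    for fold_id, train, test in folds:
        model = train_classifier(train, model_kind=model_kind, seed=seed)
        test = _canonical_order(test)
        y_true = [s.label for s in test]
        y_pred = model.predict(np.vstack([s.features for s in test]))
        cm = confusion_from_predictions(y_true, y_pred)
        run = {"fold": fold_id, "n_test": len(test), **macro_metrics(cm)}
        report.runs.append(run)
        report.confusion = report.confusion + cm
    return report


def evaluate_loso(samples: Sequence[LabeledSample], model_kind: str = "svm_ovr", seed: int = 0) -> EvaluationReport:
    """Leave-one-subject-out evaluation: one run per subject."""
    samples = list(samples)
    subjects = sorted({s.subject_id for s in samples})
    if len(subjects) < 2:
        raise InvalidInputError("LOSO needs at least 2 distinct subjects")
    folds = []
    for subject in subjects:
        train = [s for s in samples if s.subject_id != subject]
        test = [s for s in samples if s.subject_id == subject]
        folds.append((subject, train, test))
    return _evaluate_folds(samples, folds, model_kind, seed, "loso")


def evaluate_loto(samples: Sequence[LabeledSample], model_kind: str = "svm_ovr", seed: int = 0) -> EvaluationReport:
    """Leave-one-trial-out evaluation: one run per trial.

    The training fold holds all trials of all other subjects, so other trials
    of the tested subject are excluded as well.
    """
    samples = list(samples)
    trials = sorted({(s.subject_id, s.trial_id) for s in samples})
    if len(trials) < 2:
        raise InvalidInputError("LOTO needs at least 2 trials")
    folds = []
    for subject, trial in trials:
        train = [s for s in samples if s.subject_id != subject]
        test = [s for s in samples if s.subject_id == subject and s.trial_id == trial]
        folds.append((f"{subject}/{trial}", train, test))
    return _evaluate_folds(samples, folds, model_kind, seed, "loto")
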