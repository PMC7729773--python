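"""Stage-two classifiers and detection metrics.

The NSRP feature vector D = (gamma, epsilon, tau) is fed to one of six
classifiers: SVM with linear / polynomial / RBF kernel, K-nearest
neighbours, a decision tree, or a random forest.  Kernel defaults follow
the evaluation protocol the detector was designed against: p = 1/3
(one over the number of features) for the poly and RBF kernels, poly
coef0 r = 0 and degree u = 3.  The decision tree uses the entropy
criterion as the closest widely available stand-in for C4.5.

Because gamma, epsilon and tau live on scales an order of magnitude
apart, features are standardised (fit on training folds only) before
SVM/KNN by default; this is switchable.

Metrics use FALL as the positive class unless stated otherwise.
``confusion_metrics`` collapses a per-action count table to 2x2 and can
evaluate either positive-class convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .detector import NsrpFeatureVector

FALL = "FALL"
ADL = "ADL"

FEATURE_NAMES = ("gamma", "epsilon", "tau")


class ClassifierKind(str, Enum):
    SVM_LINEAR = "svm_linear"
    SVM_POLY = "svm_poly"
    SVM_RBF = "svm_rbf"
    KNN = "knn"
    DT = "dt"
    RF = "rf"


@dataclass(frozen=True)
class LabeledSample:
    features: NsrpFeatureVector
    label: str  # FALL or ADL

    def __post_init__(self) -> None:
        if self.label not in (FALL, ADL):
            raise ValueError(f"label must be {FALL} or {ADL}, got {self.label!r}")
        if not np.all(np.isfinite(self.features.as_array())):
            raise ValueError("sample features must be finite")


@dataclass(frozen=True)
class ClassifierConfig:
    kind: ClassifierKind = ClassifierKind.SVM_LINEAR
    kernel_p: float = 1.0 / 3.0  # gamma-like scale of the poly/RBF kernels
    poly_coef0_r: float = 0.0
    poly_degree_u: int = 3
    knn_k: int = 5
    rf_trees: int = 100
    svm_C: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knn_k < 1 or self.rf_trees < 1 or self.poly_degree_u < 1:
            raise ValueError("knn_k, rf_trees and poly_degree_u must be >= 1")
        if self.svm_C <= 0 or self.kernel_p <= 0:
            raise ValueError("svm_C and kernel_p must be positive")


@dataclass
class MetricsReport:
    """Detection metrics with FALL (or the stated class) as positive.

    ``confusion`` is [[TN, FP], [FN, TP]].  For an aggregate
    cross-validation report, accuracy/precision/recall are fold means
    and f1 is the harmonic mean of those means, so the report satisfies
    f1 = 2pr/(p+r) with its own fields.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    per_fold: list["MetricsReport"] = field(default_factory=list)
    positive_label: str = FALL

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": np.asarray(self.confusion).tolist(),
            "positive_label": self.positive_label,
        }
        if self.per_fold:
            d["per_fold"] = [f.to_dict() for f in self.per_fold]
        return d

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def samples_to_xy(samples: Sequence[LabeledSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([s.features.as_array() for s in samples])
    y = np.array([s.label for s in samples])
    return X, y


def _build_estimator(cfg: ClassifierConfig):
    kind = cfg.kind
    if kind is ClassifierKind.SVM_LINEAR:
        est = SVC(kernel="linear", C=cfg.svm_C, random_state=cfg.seed)
    elif kind is ClassifierKind.SVM_POLY:
        est = SVC(
            kernel="poly",
            C=cfg.svm_C,
            gamma=cfg.kernel_p,
            coef0=cfg.poly_coef0_r,
            degree=cfg.poly_degree_u,
            random_state=cfg.seed,
        )
    elif kind is ClassifierKind.SVM_RBF:
        est = SVC(kernel="rbf", C=cfg.svm_C, gamma=cfg.kernel_p, random_state=cfg.seed)
    elif kind is ClassifierKind.KNN:
        est = KNeighborsClassifier(n_neighbors=cfg.knn_k)
    elif kind is ClassifierKind.DT:
        est = DecisionTreeClassifier(criterion="entropy", random_state=cfg.seed)
    elif kind is ClassifierKind.RF:
        est = RandomForestClassifier(
            n_estimators=cfg.rf_trees, criterion="entropy", random_state=cfg.seed
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown classifier kind {kind}")
    if cfg.standardize and kind not in (ClassifierKind.DT, ClassifierKind.RF):
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


class FallClassifier:
    """A trained stage-two model: predicts FALL/ADL from D = (gamma, epsilon, tau)."""

    def __init__(self, estimator, cfg: ClassifierConfig):
        self._est = estimator
        self.cfg = cfg

    @property
    def classes_(self) -> np.ndarray:
        est = self._est[-1] if isinstance(self._est, Pipeline) else self._est
        return est.classes_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._est.predict(np.asarray(X, dtype=float))

    def predict_one(self, fv: NsrpFeatureVector) -> str:
        return str(self.predict(fv.as_array()[None, :])[0])

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Real-valued score, larger meaning more FALL-like."""
        X = np.asarray(X, dtype=float)
        if hasattr(self._est, "decision_function"):
            scores = self._est.decision_function(X)
            # binary decision_function is oriented toward classes_[1]
            return scores if self.classes_[1] == FALL else -scores
        proba = self._est.predict_proba(X)
        fall_col = int(np.flatnonzero(self.classes_ == FALL)[0])
        return proba[:, fall_col]

    def save(self, path: Union[str, Path]) -> None:
        joblib.dump({"estimator": self._est, "config": self.cfg}, path)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "FallClassifier":
        blob = joblib.load(path)
        return cls(blob["estimator"], blob["config"])


def train(
    samples: Sequence[LabeledSample], cfg: ClassifierConfig = ClassifierConfig()
) -> FallClassifier:
    """Fit one classifier on the full sample set (deterministic given cfg.seed)."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to train")
    X, y = samples_to_xy(samples)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both FALL and ADL samples")
    est = _build_estimator(cfg)
    est.fit(X, y)
    return FallClassifier(est, cfg)


def _binary_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str = FALL
) -> MetricsReport:
    pos = y_true == positive
    pred_pos = y_pred == positive
    tp = int(np.sum(pos & pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return MetricsReport(
        acc, prec, rec, f1, np.array([[tn, fp], [fn, tp]]), positive_label=positive
    )


def cross_validate(
    samples: Sequence[LabeledSample],
    cfg: ClassifierConfig = ClassifierConfig(),
    folds: int = 3,
) -> tuple[MetricsReport, np.ndarray, np.ndarray]:
    """Stratified k-fold cross-validation (seeded fold assignment).

    Returns the aggregate report (fold-mean metrics, per-fold reports
    attached, confusion summed over folds) together with the pooled
    out-of-fold labels and decision scores, from which an ROC curve can
    be drawn.
    """
    if len(samples) < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    X, y = samples_to_xy(samples)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation requires both classes present")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    fold_reports = []
    oof_labels = np.empty(len(y), dtype=y.dtype)
    oof_scores = np.empty(len(y))
    for train_idx, test_idx in skf.split(X, y):
        model = FallClassifier(_build_estimator(cfg), cfg)
        model._est.fit(X[train_idx], y[train_idx])
        y_pred = model.predict(X[test_idx])
        fold_reports.append(_binary_metrics(y[test_idx], y_pred))
        oof_labels[test_idx] = y[test_idx]
        oof_scores[test_idx] = model.decision_scores(X[test_idx])
    acc = float(np.mean([r.accuracy for r in fold_reports]))
    prec = float(np.mean([r.precision for r in fold_reports]))
    rec = float(np.mean([r.recall for r in fold_reports]))
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    confusion = np.sum([r.confusion for r in fold_reports], axis=0)
    report = MetricsReport(acc, prec, rec, f1, confusion, per_fold=fold_reports)
    return report, oof_labels, oof_scores


def confusion_metrics(
    counts: Mapping[str, tuple[int, int]],
    fall_actions: Iterable[str],
    positive: str = FALL,
) -> MetricsReport:
    """Collapse a per-action (predicted_nonfall, predicted_fall) count table.

    ``counts`` maps action name -> (n predicted non-falling, n predicted
    falling); ``fall_actions`` names the actions whose ground truth is a
    fall.  With ``positive=FALL`` the report treats falls as the positive
    class; ``positive=ADL`` gives the opposite convention (accuracy is
    identical either way).
    """
    if not counts:
        raise ValueError("empty count table")
    fall_actions = set(fall_actions)
    tp = tn = fp = fn = 0
    for action, (n_nonfall, n_fall) in counts.items():
        if n_nonfall < 0 or n_fall < 0:
            raise ValueError(f"negative count for action {action!r}")
        if action in fall_actions:
            tp += n_fall
            fn += n_nonfall
        else:
            tn += n_nonfall
            fp += n_fall
    if positive == ADL:  # swap the roles of the two classes
        tp, tn = tn, tp
        fp, fn = fn, fp
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("count table sums to zero")
    acc = (tp + tn) / n
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return MetricsReport(
        acc, prec, rec, f1, np.array([[tn, fp], [fn, tp]]), positive_label=positive
    )


def roc_points(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR) and trapezoid AUC with FALL as positive."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC undefined for a single-class sample set")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float), pos_label=FALL)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def roc_from_model(
    model: FallClassifier, samples: Sequence[LabeledSample]
) -> tuple[np.ndarray, np.ndarray, float]:
    X, y = samples_to_xy(samples)
    return roc_points(y, model.decision_scores(X))
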