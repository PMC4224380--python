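"""Nucleosome/linker discrimination and its evaluation.

A radial-basis-kernel SVM (scikit-learn's libsvm binding) is trained on
8-component positioning feature vectors, min-max scaled to [0,1] with statistics of
the training fold only.  Evaluation follows the standard confusion-table
metrics

    Accuracy  = (TP+TN)/(TP+TN+FP+FN)
    Sensitivity = TP/(TP+FN)
    Precision = TP/(TP+FP)
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus the ROC curve and its area (Mann-Whitney tie-corrected), under
stratified 5-fold cross-validation with a pooled ROC over the
concatenated held-out decision scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .features import InvalidParameterError

POSITIVE, NEGATIVE = 1, -1


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM settings, kept explicit and recorded in every report so runs
    are reproducible."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float = 1.0 / 8.0


@dataclass
class LabeledDataset:
    """Feature vectors with +/-1 labels (+1 nucleosomal, -1 linker)."""

    X: np.ndarray
    y: np.ndarray
    ids: List[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not (len(self.X) == len(self.y) == len(self.ids)):
            raise InvalidParameterError("X, y and ids must have equal lengths")
        if set(np.unique(self.y)) - {POSITIVE, NEGATIVE}:
            raise InvalidParameterError("labels must be +1 or -1")

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class CvReport:
    """Per-fold and pooled cross-validation results."""

    fold_counts: List[ConfusionCounts]
    fold_metrics: List[Dict[str, float]]
    fold_auc: List[float]
    pooled_counts: ConfusionCounts
    pooled_metrics: Dict[str, float]
    pooled_auc: float
    seed: int
    config: ClassifierConfig
    scores: np.ndarray = field(repr=False, default=None)  # held-out decision scores
    labels: np.ndarray = field(repr=False, default=None)


def stratified_kfold_split(
    dataset: LabeledDataset, folds: int = 5, seed: int = 0
) -> List[np.ndarray]:
    """Deterministic stratified partition into test-index sets.

    Class balance within each fold is preserved to +/-1 item.
    """
    if folds < 2:
        raise InvalidParameterError("need at least 2 folds")
    for label in (POSITIVE, NEGATIVE):
        if int(np.sum(dataset.y == label)) < folds:
            raise InvalidParameterError(
                f"class {label:+d} has fewer members than folds={folds}"
            )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(dataset.X, dataset.y)]


def train_classifier(train: LabeledDataset, config: ClassifierConfig | None = None) -> Pipeline:
    """Fit the scaled RBF-SVM; returns a pipeline with .predict and
    .decision_function (larger score = more nucleosome-like)."""
    config = config or ClassifierConfig()
    if len(set(train.y.tolist())) < 2:
        raise InvalidParameterError("training data must contain both classes")
    model = Pipeline(
        [
            ("scale", MinMaxScaler()),
            ("svm", SVC(kernel=config.kernel, C=config.C, gamma=config.gamma)),
        ]
    )
    model.fit(train.X, train.y)
    return model


def evaluate_metrics(c: ConfusionCounts) -> Dict[str, float]:
    """Accuracy, Sensitivity, Precision and MCC from a confusion table.

    Any 0/0 (including the MCC denominator) is defined as 0.
    """
    if c.total == 0:
        raise InvalidParameterError("empty confusion table")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    acc = (tp + tn) / (tp + tn + fp + fn)
    sens = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {"accuracy": acc, "sensitivity": sens, "precision": prec, "mcc": mcc}


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE))),
        tn=int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE))),
        fp=int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE))),
        fn=int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE))),
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC with the Mann-Whitney tie convention, plus (fpr, tpr) points.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise InvalidParameterError("ROC needs both labels present")
    fpr, tpr, _ = _skm.roc_curve(labels, scores, pos_label=POSITIVE)
    return float(_skm.roc_auc_score(labels == POSITIVE, scores)), fpr, tpr


def cross_validate(
    dataset: LabeledDataset,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    folds: int = 5,
) -> CvReport:
    """Stratified k-fold CV; every sequence is tested exactly once and the
    pooled ROC is computed over the concatenated held-out scores."""
    config = config or ClassifierConfig()
    test_sets = stratified_kfold_split(dataset, folds=folds, seed=seed)
    all_idx = np.arange(len(dataset))
    fold_counts, fold_metrics, fold_auc = [], [], []
    pooled_scores = np.empty(len(dataset))
    pooled_pred = np.empty(len(dataset), dtype=int)
    for test_idx in test_sets:
        train_idx = np.setdiff1d(all_idx, test_idx)
        model = train_classifier(
            LabeledDataset(
                dataset.X[train_idx],
                dataset.y[train_idx],
                [dataset.ids[i] for i in train_idx],
            ),
            config,
        )
        pred = model.predict(dataset.X[test_idx])
        score = model.decision_function(dataset.X[test_idx])
        pooled_scores[test_idx] = score
        pooled_pred[test_idx] = pred
        counts = confusion_from_predictions(dataset.y[test_idx], pred)
        fold_counts.append(counts)
        fold_metrics.append(evaluate_metrics(counts))
        fold_auc.append(roc_auc(score, dataset.y[test_idx])[0])
    pooled_counts = confusion_from_predictions(dataset.y, pooled_pred)
    return CvReport(
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        fold_auc=fold_auc,
        pooled_counts=pooled_counts,
        pooled_metrics=evaluate_metrics(pooled_counts),
        pooled_auc=roc_auc(pooled_scores, dataset.y)[0],
        seed=seed,
        config=config,
        scores=pooled_scores,
        labels=dataset.y.copy(),
    )
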