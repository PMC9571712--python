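"""Per-participant normalisation, SVM cross-validation and binary metrics.

Classification is binary (one workload pair at a time) with stratified
5-fold cross-validation.  Features are min-max scaled to [-1, 1] per
participant before CV, replicating the original processing order; a
subject-wise fold option keeps each participant's samples in one fold.
The positive class is the higher workload level.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datatypes import LOAD_RANK, ConfusionCounts, CVReport, FeatureMatrix

__all__ = ["normalize_per_participant", "GroupMinMaxScaler", "crossval",
           "metrics", "roc_auc", "make_classifier"]


class GroupMinMaxScaler(TransformerMixin, BaseEstimator):
    """Min-max scaling to ``feature_range`` fitted separately per group.

    Groups (participants) are passed explicitly to both :meth:`fit` and
    :meth:`transform`; columns that are constant within a group map to the
    midpoint (0 for the default [-1, 1] range).
    """

    def __init__(self, feature_range: Tuple[float, float] = (-1.0, 1.0)):
        self.feature_range = feature_range

    def fit(self, X, y=None, groups=None):
        X = np.asarray(X, dtype=float)
        if groups is None:
            raise ValueError("groups (participant ids) are required")
        groups = np.asarray(groups)
        self.group_range_ = {}
        for g in np.unique(groups):
            sub = X[groups == g]
            if sub.shape[0] < 2:
                raise ValueError(f"participant {g!r} has fewer than 2 samples")
            self.group_range_[g] = (sub.min(axis=0), sub.max(axis=0))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, groups=None):
        X = np.asarray(X, dtype=float)
        if groups is None:
            raise ValueError("groups (participant ids) are required")
        groups = np.asarray(groups)
        lo, hi = self.feature_range
        out = np.empty_like(X)
        for g in np.unique(groups):
            mn, mx = self.group_range_[g]
            span = mx - mn
            mask = groups == g
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = (X[mask] - mn) / span
            unit[:, span == 0] = 0.5  # constant column -> midpoint
            out[mask] = lo + unit * (hi - lo)
        return out

    def fit_transform(self, X, y=None, groups=None):
        return self.fit(X, groups=groups).transform(X, groups=groups)


def normalize_per_participant(fm: FeatureMatrix) -> FeatureMatrix:
    """Scale each column to [-1, 1] independently within each participant."""
    if "participant" not in fm.provenance.columns:
        raise ValueError("feature matrix lacks participant identifiers")
    groups = fm.provenance["participant"].to_numpy()
    scaled = GroupMinMaxScaler().fit_transform(fm.values, groups=groups)
    return FeatureMatrix(scaled, list(fm.descriptors), fm.labels, fm.provenance)


def make_classifier(name: str, seed: int = 0):
    """Factory for the comparator classifiers."""
    if name == "svm-rbf":
        return SVC(C=1.0, kernel="rbf", gamma="scale")
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "tree":
        return DecisionTreeClassifier(max_depth=5, random_state=seed)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown classifier {name!r}")


def _positive_label(classes: Sequence[str]) -> str:
    """Higher workload level when labels are task names, else the larger label."""
    try:
        return max(classes, key=lambda c: LOAD_RANK[c])
    except KeyError:
        return max(classes)


def _scores(clf, X: np.ndarray, positive, classes) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        s = clf.decision_function(X)
        # sklearn's decision function is oriented toward clf.classes_[1]
        return s if clf.classes_[1] == positive else -s
    proba = clf.predict_proba(X)
    col = list(clf.classes_).index(positive)
    return proba[:, col]


def crossval(fm: Union[FeatureMatrix, np.ndarray], labels=None,
             classifier: str = "svm-rbf", k: int = 5, seed: int = 0,
             subject_wise: bool = False,
             groups: Optional[np.ndarray] = None) -> CVReport:
    """Stratified k-fold cross-validation of one binary workload task.

    Accepts a :class:`FeatureMatrix` (labels/groups taken from it) or a
    plain array plus ``labels``.  Decision scores are pooled across folds
    for the ROC; the reported accuracy is the mean of the per-fold
    accuracies, in percent.
    """
    if isinstance(fm, FeatureMatrix):
        X = fm.values
        y = fm.labels if labels is None else np.asarray(labels)
        if groups is None:
            groups = fm.provenance["participant"].to_numpy()
    else:
        X = np.asarray(fm, dtype=float)
        y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"binary task expected, got classes {classes}")
    counts = np.array([(y == c).sum() for c in classes])
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class count {counts.min()}")
    positive = _positive_label(classes)

    if subject_wise:
        if groups is None:
            raise ValueError("subject-wise CV needs participant groups")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X, y)

    fold_acc = []
    pooled_scores = np.empty(len(y))
    pooled_pred = np.empty(len(y), dtype=object)
    for train, test in split:
        clf = make_classifier(classifier, seed)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        fold_acc.append(float(np.mean(pred == y[test])))
        pooled_pred[test] = pred
        pooled_scores[test] = _scores(clf, X[test], positive, classes)

    is_pos = y == positive
    pred_pos = pooled_pred == positive
    confusion = ConfusionCounts(
        tp=int(np.sum(pred_pos & is_pos)),
        tn=int(np.sum(~pred_pos & ~is_pos)),
        fp=int(np.sum(pred_pos & ~is_pos)),
        fn=int(np.sum(~pred_pos & is_pos)),
    )
    accu, sens, spec = metrics(confusion)
    roc_points, auc = roc_auc(pooled_scores, y, positive=positive)
    return CVReport(
        fold_accuracies=np.asarray(fold_acc),
        confusion=confusion,
        accuracy=float(np.mean(fold_acc) * 100.0),
        sensitivity=sens,
        specificity=spec,
        roc_points=roc_points,
        auc=auc,
        classifier=classifier,
        seed=seed,
        positive_label=str(positive),
    )


def metrics(c: ConfusionCounts) -> Tuple[float, float, float]:
    """(Accuracy, Sensitivity, Specificity) in percent.

    Accuracy = (TP+TN)/total, Sensitivity = TP/(TP+FN),
    Specificity = TN/(TN+FP).  A zero denominator yields NaN rather than
    an exception.
    """
    def ratio(num: int, den: int) -> float:
        return num / den * 100.0 if den > 0 else float("nan")

    return (ratio(c.tp + c.tn, c.total), ratio(c.tp, c.tp + c.fn),
            ratio(c.tn, c.tn + c.fp))


def roc_auc(scores, labels, positive=None) -> Tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a threshold sweep, and trapezoidal AUC.

    Ties in the scores produce simultaneous steps.  The curve starts at
    (0, 0) and ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("ROC needs exactly two classes")
    if positive is None:
        positive = _positive_label(classes)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, pos_label=positive,
                                drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(np.trapezoid(tpr, fpr))
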