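"""Classifier training and evaluation.

Four standard classifiers (RBF support vector machine, decision tree,
k-nearest neighbors with k=5, Gaussian naive Bayes) are evaluated under
stratified 10-fold cross-validation; each metric is reported as mean +/-
SD across folds. An optional held-out 20% split is available. Malignant is
the positive class throughout. By default feature normalization and ANOVA
selection are fitted inside each training fold to avoid leakage;
``global_fit`` fits them once on the full table instead.

Threshold metrics come from the confusion matrix; the ROC curve is a
threshold sweep over classifier scores (decision function, or posterior
probability of the positive class) and the AUC its trapezoid area, which
equals the Mann-Whitney pair statistic with ties counted one-half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import SelectKBest
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ProtocolError, ValidationError
from .selection import anova_score

__all__ = [
    "CLASSIFIERS",
    "POSITIVE_LABEL",
    "EvalMetrics",
    "RocCurve",
    "CVResult",
    "confusion_metrics",
    "roc_auc",
    "cross_validate",
    "evaluate_all",
]

CLASSIFIERS = ("svm", "dt", "knn", "nb")
POSITIVE_LABEL = "malignant"
METRICS = ("accuracy", "precision", "sensitivity", "specificity", "auc")


@dataclass(frozen=True)
class EvalMetrics:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    flags: frozenset = frozenset()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class CVResult:
    classifier: str
    per_fold: pd.DataFrame  # one row per fold, columns = METRICS
    summary: pd.DataFrame  # rows mean/sd, columns = METRICS

    def mean(self, metric: str) -> float:
        return float(self.summary.loc["mean", metric])

    def sd(self, metric: str) -> float:
        return float(self.summary.loc["sd", metric])

    def format(self) -> str:
        cells = [f"{m}={self.mean(m) * (100 if m == 'accuracy' else 1):.2f} "
                 f"± {self.sd(m) * (100 if m == 'accuracy' else 1):.2f}"
                 for m in METRICS]
        return f"{self.classifier}: " + ", ".join(cells)


def _binarize(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "ifub":
        return (y.astype(float) > 0).astype(int)
    return (y == POSITIVE_LABEL).astype(int)


def confusion_metrics(y_true, y_pred) -> EvalMetrics:
    """Accuracy, precision, sensitivity, specificity from the confusion
    matrix (positive = malignant). A metric whose denominator is zero is
    reported as 0 with a flag instead of NaN."""
    t, p = _binarize(y_true), _binarize(y_pred)
    if len(t) != len(p) or len(t) == 0:
        raise ValidationError("y_true and y_pred must be equal-length and nonempty")
    tp = int(((t == 1) & (p == 1)).sum())
    tn = int(((t == 0) & (p == 0)).sum())
    fp = int(((t == 0) & (p == 1)).sum())
    fn = int(((t == 1) & (p == 0)).sum())
    flags = set()

    def ratio(num, den, name):
        if den == 0:
            flags.add(f"undefined_{name}")
            return 0.0
        return num / den

    return EvalMetrics(
        accuracy=(tp + tn) / len(t),
        precision=ratio(tp, tp + fp, "precision"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        flags=frozenset(flags),
    )


def roc_auc(y_true, scores) -> RocCurve:
    """ROC by sweeping a threshold over the unique scores; AUC by the
    trapezoid rule. The curve runs from (0,0) to (1,1) and is
    nondecreasing in both coordinates."""
    t = _binarize(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(t.sum()), int((1 - t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ProtocolError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    # collapse ties: cumulative counts at each distinct threshold
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    idx = np.concatenate((distinct, [len(s_sorted) - 1]))
    tps = np.cumsum(t_sorted)[idx]
    fps = np.cumsum(1 - t_sorted)[idx]
    tpr = np.concatenate(([0.0], tps / n_pos))
    fpr = np.concatenate(([0.0], fps / n_neg))
    thresholds = np.concatenate(([np.inf], s_sorted[idx]))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def make_classifier(name: str, seed: int = 0):
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "nb":
        return GaussianNB()
    raise ValidationError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def _build_pipeline(name: str, seed: int, k_features: int | None) -> Pipeline:
    steps = [("scale", StandardScaler())]
    if k_features is not None:
        steps.append(("select", SelectKBest(score_func=anova_score, k=k_features)))
    steps.append(("clf", make_classifier(name, seed)))
    return Pipeline(steps)


def _fold_metrics(model, X_test, y_test) -> dict:
    pred = model.predict(X_test)
    m = confusion_metrics(y_test, pred).as_dict()
    m["auc"] = roc_auc(y_test, _scores(model, X_test)).auc
    return m


def _table_xy(table: pd.DataFrame):
    if "label" not in table.columns:
        raise ValidationError("table must carry a 'label' column")
    X = table.drop(columns="label").to_numpy(dtype=float)
    y = _binarize(table["label"].to_numpy())
    if len(np.unique(y)) < 2:
        raise ProtocolError("evaluation needs both classes in the table")
    return X, y


def cross_validate(
    table: pd.DataFrame,
    classifier: str = "svm",
    n_splits: int = 10,
    k_features: int | None = None,
    seed: int = 0,
    global_fit: bool = False,
    holdout: float | None = None,
) -> CVResult:
    """Stratified k-fold CV (default) or a held-out split of the table.

    ``k_features`` turns on in-fold ANOVA selection; ``global_fit`` fits
    normalization and selection once on the full table before splitting.
    The fold count is reduced (with a warning) when a class has fewer
    members than ``n_splits``.
    """
    X, y = _table_xy(table)
    if global_fit:
        X = StandardScaler().fit_transform(X)
        if k_features is not None:
            X = SelectKBest(score_func=anova_score, k=k_features).fit_transform(X, y)
        k_in_fold = None
        scale_in_fold = False
    else:
        k_in_fold = k_features
        scale_in_fold = True

    def fit_eval(train, test) -> dict:
        if scale_in_fold:
            model = _build_pipeline(classifier, seed, k_in_fold)
        else:
            model = make_classifier(classifier, seed)
        model.fit(X[train], y[train])
        return _fold_metrics(model, X[test], y[test])

    if holdout is not None:
        if not 0 < holdout < 1:
            raise ValidationError("holdout fraction must be in (0, 1)")
        idx = np.arange(len(y))
        train, test = train_test_split(idx, test_size=holdout, stratify=y, random_state=seed)
        rows = [fit_eval(train, test)]
    else:
        min_class = int(np.bincount(y).min())
        splits = min(n_splits, min_class)
        if splits < n_splits:
            warnings.warn(
                f"reducing folds from {n_splits} to {splits}: smallest class has "
                f"{min_class} members", stacklevel=2)
        if splits < 2:
            raise ProtocolError("smallest class too small for cross-validation")
        cv = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
        rows = [fit_eval(train, test) for train, test in cv.split(X, y)]

    per_fold = pd.DataFrame(rows, columns=list(METRICS))
    summary = pd.DataFrame(
        {m: [per_fold[m].mean(), per_fold[m].std(ddof=0)] for m in METRICS},
        index=["mean", "sd"],
    )
    return CVResult(classifier=classifier, per_fold=per_fold, summary=summary)


def evaluate_all(
    table: pd.DataFrame,
    classifiers=CLASSIFIERS,
    n_splits: int = 10,
    k_features: int | None = None,
    seed: int = 0,
    global_fit: bool = False,
    holdout: float | None = None,
) -> dict[str, CVResult]:
    """Run :func:`cross_validate` for each classifier."""
    return {
        name: cross_validate(table, name, n_splits=n_splits, k_features=k_features,
                             seed=seed, global_fit=global_fit, holdout=holdout)
        for name in classifiers
    }
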