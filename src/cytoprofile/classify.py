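"""Supervised phenotype classification of cytoprofile tables.

Five classifier families (random forest, logistic regression, SVM, kNN,
Gaussian naive Bayes) evaluated by stratified 50/50 hold-out and pooled
stratified 10-fold cross-validation; per-class accuracy is class recall
(the diagonal of the row-percentage confusion matrix).

Features are normalised to [0, 1] with min/max statistics fitted on the
training partition only (inside each CV fold): kNN, SVM and logistic
regression are scale-sensitive and raw cytoprofile scales span orders of
magnitude. Min-max normalisation with the classic libsvm RBF width
(gamma = 1/n_features) follows the conventions of the data-mining
toolchains these pipelines were historically built on; modern
variance-adaptive kernel-width heuristics materially change RBF-SVM
behaviour on morphometric tables and are deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

CLASS_ORDER = ("M1", "M2", "naive_mac", "mono_d0", "mono_d6")
METHODS = ("random_forest", "logistic_regression", "svm", "knn", "naive_bayes")

PROVENANCE_COLS = ("image_id", "object_id", "class")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus its hyperparameters.

    Defaults: random forest with 20 trees (unlimited depth); kNN k=5
    (Euclidean on standardised features); SVM RBF C=1; L2 logistic
    regression; Gaussian naive Bayes.
    """

    method: str
    params: Mapping[str, float] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "random_forest" and self.params.get("n_trees", 20) < 1:
            raise ValueError("n_trees must be >= 1")
        if self.method == "knn" and self.params.get("k", 5) < 1:
            raise ValueError("k must be >= 1")


def default_specs(seed: int = 0) -> dict[str, ClassifierSpec]:
    return {m: ClassifierSpec(method=m, rng_seed=seed) for m in METHODS}


def make_estimator(spec: ClassifierSpec) -> Pipeline:
    """Normalisation + classifier pipeline (no test-set leakage: the
    scaler is fitted on whatever partition ``fit`` receives)."""
    p = dict(spec.params)
    if spec.method == "random_forest":
        clf = RandomForestClassifier(n_estimators=int(p.get("n_trees", 20)),
                                     random_state=spec.rng_seed)
    elif spec.method == "logistic_regression":
        clf = LogisticRegression(C=float(p.get("C", 1.0)),  # L2 default
                                 max_iter=int(p.get("max_iter", 3000)))
    elif spec.method == "svm":
        clf = SVC(kernel=p.get("kernel", "rbf"), C=float(p.get("C", 1.0)),
                  gamma=p.get("gamma", "auto"),  # classic 1/n_features
                  decision_function_shape="ovr", random_state=spec.rng_seed)
    elif spec.method == "knn":
        clf = KNeighborsClassifier(n_neighbors=int(p.get("k", 5)))
    else:
        clf = GaussianNB()
    return Pipeline([("scale", MinMaxScaler()), ("clf", clf)])


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in PROVENANCE_COLS]


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = table[feature_columns(table)].to_numpy(dtype=float)
    y = table["class"].to_numpy()
    return X, y


def split_train_test(table: pd.DataFrame, fraction: float, seed: int,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random split; per class floor(n * fraction) rows to train."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls, grp in table.groupby("class", sort=True):
        if len(grp) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 rows")
        perm = rng.permutation(grp.index.to_numpy())
        n_train = int(np.floor(len(grp) * fraction))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = table.loc[np.concatenate(train_idx)].sort_index()
    test = table.loc[np.concatenate(test_idx)].sort_index()
    return train, test


@dataclass
class CVResult:
    per_class_accuracy: dict[str, float]  # percent (class recall)
    overall_accuracy: float               # percent
    confusion_percent: pd.DataFrame       # rows sum to 100
    y_true: np.ndarray
    y_pred: np.ndarray


def cross_validate(spec: ClassifierSpec, table: pd.DataFrame, k: int = 10,
                   seed: int = 0) -> CVResult:
    """Pooled stratified k-fold CV accuracies for one classifier."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y = _xy(table)
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise ValueError("every class must have at least k rows")
    classes = [c for c in CLASS_ORDER if c in counts.index] or \
        sorted(counts.index)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = cross_val_predict(make_estimator(spec), X, y, cv=cv)
    cm = confusion_matrix_percent(y, y_pred, classes=classes)
    per_class = {c: float(cm.loc[c, c]) for c in classes}
    overall = 100.0 * float((y_pred == y).mean())
    return CVResult(per_class_accuracy=per_class, overall_accuracy=overall,
                    confusion_percent=cm, y_true=y, y_pred=y_pred)


def confusion_matrix_percent(y_true: Sequence, y_pred: Sequence,
                             classes: Sequence[str] | None = None,
                             ) -> pd.DataFrame:
    """Row-percentage confusion matrix: entry (i, j) = % of true class i
    predicted as class j; every non-empty row sums to 100."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = list(classes) if classes is not None else list(CLASS_ORDER)
    seen = set(y_true) | set(y_pred)
    unknown = seen - set(classes)
    if unknown:
        raise ValueError(f"label(s) outside the class set: {sorted(unknown)}")
    counts = _sk_confusion(y_true, y_pred, labels=classes).astype(float)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    return pd.DataFrame(pct, index=classes, columns=classes)


def roc_one_vs_rest(scores: pd.DataFrame, y_true: Sequence,
                    ) -> dict[str, dict]:
    """Per-class one-vs-rest ROC curves and trapezoidal AUCs.

    ``scores`` columns are class names holding per-class probabilities or
    decision values. Requires at least two distinct true classes.
    """
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC undefined for single-class truth")
    out: dict[str, dict] = {}
    for cls in scores.columns:
        pos = (y_true == cls).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            continue
        fpr, tpr, _ = _sk_roc_curve(pos, scores[cls].to_numpy())
        out[cls] = {"fpr": fpr, "tpr": tpr,
                    "auc": float(_trapezoid_auc(fpr, tpr))}
    return out


def classifier_scores(fitted: Pipeline, X: np.ndarray,
                      classes: Sequence[str]) -> pd.DataFrame:
    """Per-class score matrix (probabilities, or one-vs-rest decision
    values for margin classifiers without probability estimates)."""
    clf = fitted
    if hasattr(clf, "predict_proba"):
        s = clf.predict_proba(X)
    else:
        s = clf.decision_function(X)
        if s.ndim == 1:
            s = np.stack([-s, s], axis=1)
    model_classes = list(fitted.classes_)
    df = pd.DataFrame(s, columns=model_classes)
    return df[[c for c in classes if c in model_classes]]


def learning_curve(spec: ClassifierSpec, table: pd.DataFrame,
                   fractions: Sequence[float], repeats: int = 3,
                   seed: int = 0) -> dict[float, float]:
    """Mean held-out accuracy (%) vs training fraction.

    For each fraction a stratified training subset is drawn and the model
    evaluated on the held-out remainder, averaged over ``repeats``.
    """
    out: dict[float, float] = {}
    ss = np.random.SeedSequence(seed).generate_state(len(fractions) * repeats)
    si = 0
    for frac in fractions:
        accs = []
        for _ in range(repeats):
            train, test = split_train_test(table, frac,
                                           seed=int(ss[si] % (2 ** 31)))
            si += 1
            if len(test) == 0 or len(train) == 0:
                raise ValueError(f"fraction {frac} leaves an empty partition")
            est = make_estimator(spec)
            Xtr, ytr = _xy(train)
            Xte, yte = _xy(test)
            est.fit(Xtr, ytr)
            accs.append(100.0 * float((est.predict(Xte) == yte).mean()))
        out[float(frac)] = float(np.mean(accs))
    return out


@dataclass
class FittedModel:
    """A trained pipeline bundled with its feature schema and class set."""

    pipeline: Pipeline
    feature_names: list[str]
    classes: list[str]
    spec: ClassifierSpec


def train_classifier(spec: ClassifierSpec, table: pd.DataFrame) -> FittedModel:
    X, y = _xy(table)
    est = make_estimator(spec)
    est.fit(X, y)
    classes = [c for c in CLASS_ORDER if c in set(y)] or sorted(set(y))
    return FittedModel(pipeline=est, feature_names=feature_columns(table),
                       classes=classes, spec=spec)


def predict_blind(model: FittedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Predict labels + per-class scores for an unlabeled table."""
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    if len(table) == 0:
        return pd.DataFrame(columns=["predicted"] +
                            [f"score_{c}" for c in model.classes])
    X = table[model.feature_names].to_numpy(dtype=float)
    pred = model.pipeline.predict(X)
    scores = classifier_scores(model.pipeline, X, model.classes)
    out = pd.DataFrame({"predicted": pred}, index=table.index)
    for c in model.classes:
        out[f"score_{c}"] = scores[c].to_numpy()
    return out


@dataclass
class EvaluationReport:
    """Evaluation artefacts for one classifier."""

    method: str
    cv: CVResult
    holdout_confusion: pd.DataFrame
    holdout_per_class: dict[str, float]
    roc: dict[str, dict]
    learning: dict[float, float]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "cv_per_class_accuracy": self.cv.per_class_accuracy,
            "cv_overall_accuracy": self.cv.overall_accuracy,
            "cv_confusion_percent": self.cv.confusion_percent.to_dict(),
            "holdout_per_class_accuracy": self.holdout_per_class,
            "holdout_confusion_percent": self.holdout_confusion.to_dict(),
            "roc_auc": {c: r["auc"] for c, r in self.roc.items()},
            "learning_curve": self.learning,
        }


def evaluate_classifier(spec: ClassifierSpec, table: pd.DataFrame,
                        split_fraction: float = 0.5, cv_folds: int = 10,
                        seed: int = 0,
                        learning_fractions: Sequence[float] = (),
                        learning_repeats: int = 2) -> EvaluationReport:
    """Full protocol for one classifier: pooled k-fold CV on the whole
    table, plus a stratified 50/50 hold-out fit for the confusion matrix
    and one-vs-rest ROC curves, plus an optional learning curve."""
    cvres = cross_validate(spec, table, k=cv_folds, seed=seed)
    train, test = split_train_test(table, split_fraction, seed=seed)
    model = train_classifier(spec, train)
    Xte, yte = _xy(test)
    pred = model.pipeline.predict(Xte)
    cm = confusion_matrix_percent(yte, pred, classes=model.classes)
    per_class = {c: float(cm.loc[c, c]) for c in model.classes}
    scores = classifier_scores(model.pipeline, Xte, model.classes)
    roc = roc_one_vs_rest(scores, yte)
    learning = learning_curve(spec, table, learning_fractions,
                              repeats=learning_repeats, seed=seed) \
        if learning_fractions else {}
    return EvaluationReport(method=spec.method, cv=cvres,
                            holdout_confusion=cm, holdout_per_class=per_class,
                            roc=roc, learning=learning)
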