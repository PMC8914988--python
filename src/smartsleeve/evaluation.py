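"""Classifier evaluation: min-max normalization, six classical
classifiers, 10-fold and leave-one-subject-out cross-validation,
macro-averaged metrics, and the normalization/feature-set ablation grid.

Metrics follow the usual multiclass definitions: per-class precision
``P_i`` and recall ``R_i`` are averaged with equal class weight into
``Macro_P`` and ``Macro_R``, and ``Macro_F1`` is their harmonic mean
``2 * Macro_P * Macro_R / (Macro_P + Macro_R)``.  Fold metrics are
averaged over folds; confusion matrices are pooled over all test
predictions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES
from .types import EvalResult

CLASSIFIER_IDS = ("svm", "knn", "lr", "rf", "dt", "nb")


def make_classifier(algorithm: str):
    """Instantiate one of the six classical classifiers.

    Hyperparameters: SVM with a polynomial kernel; KNN with 5 neighbors;
    logistic regression with l2 penalty and up to 8000 iterations;
    random forest with balanced class weights, Gini criterion and log2
    feature subsampling; plain decision tree; Gaussian naive Bayes.
    Seeded estimators use a fixed random state of 40; everything not
    listed keeps the toolkit default.
    """
    algorithm = algorithm.lower()
    if algorithm == "svm":
        return SVC(kernel="poly")
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if algorithm == "lr":
        return LogisticRegression(penalty="l2", max_iter=8000, random_state=40)
    if algorithm == "rf":
        return RandomForestClassifier(
            class_weight="balanced",
            criterion="gini",
            max_features="log2",
            random_state=40,
        )
    if algorithm == "dt":
        return DecisionTreeClassifier(random_state=40)
    if algorithm == "nb":
        return GaussianNB()
    raise ValueError(f"unknown classifier {algorithm!r}; expected one of {CLASSIFIER_IDS}")


def minmax_normalize(
    train: np.ndarray | pd.DataFrame, other: np.ndarray | pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max scale both splits using the training split's column ranges.

    Constant training columns map to 0 everywhere; values outside the
    training range (in ``other``) are clipped to [0, 1].
    """
    if isinstance(train, pd.DataFrame) or isinstance(other, pd.DataFrame):
        if not isinstance(train, pd.DataFrame) or not isinstance(other, pd.DataFrame):
            raise ValueError("train and other must both be DataFrames or both arrays")
        if list(train.columns) != list(other.columns):
            raise ValueError("feature columns of train and other do not match")
        train, other = train.to_numpy(float), other.to_numpy(float)
    train = np.asarray(train, dtype=float)
    other = np.asarray(other, dtype=float)
    if train.shape[1] != other.shape[1]:
        raise ValueError("train and other have different feature counts")
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    safe = np.where(span > 0, span, 1.0)
    train_n = np.where(span > 0, (train - lo) / safe, 0.0)
    other_n = np.where(span > 0, np.clip((other - lo) / safe, 0.0, 1.0), 0.0)
    return train_n, other_n


def macro_metrics(cm: np.ndarray) -> tuple[float, float, float, float]:
    """(accuracy, Macro_P, Macro_R, Macro_F1) from a confusion matrix
    (rows = true class, columns = predicted class)."""
    cm = np.asarray(cm, dtype=float)
    if cm.size == 0 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square and non-empty")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        r = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
    macro_p = float(p.mean())
    macro_r = float(r.mean())
    denom = macro_p + macro_r
    macro_f1 = 2 * macro_p * macro_r / denom if denom > 0 else 0.0
    return float(diag.sum() / total), macro_p, macro_r, macro_f1


def _evaluate_splits(X, y, splits, algorithm, scheme) -> EvalResult:
    labels = sorted(set(y))
    pooled = np.zeros((len(labels), len(labels)), dtype=int)
    per_fold = []
    for train_idx, test_idx in splits:
        Xtr, Xte = minmax_normalize(X[train_idx], X[test_idx])
        clf = make_classifier(algorithm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xtr, np.asarray(y)[train_idx])
            pred = clf.predict(Xte)
        cm = confusion_matrix(np.asarray(y)[test_idx], pred, labels=labels)
        pooled += cm
        acc, mp, mr, mf1 = macro_metrics(cm)
        per_fold.append(
            {"accuracy": acc, "macro_p": mp, "macro_r": mr, "macro_f1": mf1}
        )
    mean = {k: float(np.mean([f[k] for f in per_fold])) for k in per_fold[0]}
    macro_f1 = (
        2 * mean["macro_p"] * mean["macro_r"] / (mean["macro_p"] + mean["macro_r"])
        if mean["macro_p"] + mean["macro_r"] > 0
        else 0.0
    )
    return EvalResult(
        scheme=scheme,
        classifier=algorithm,
        accuracy=mean["accuracy"],
        macro_p=mean["macro_p"],
        macro_r=mean["macro_r"],
        macro_f1=macro_f1,
        per_fold=per_fold,
        confusion=pooled,
        labels=list(labels),
    )


def run_kfold(
    X: np.ndarray,
    y,
    algorithm: str = "svm",
    k: int = 10,
    seed: int = 0,
) -> EvalResult:
    """Stratified k-fold cross-validation with per-fold normalization.

    The shuffle is seeded; normalization statistics are fitted on each
    training split only.  Warns when a class has fewer samples than folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"some class has only {counts.min()} samples for {k} folds",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return _evaluate_splits(X, y, skf.split(X, y), algorithm, "kfold")


def run_loso(X: np.ndarray, y, subject_ids, algorithm: str = "svm") -> EvalResult:
    """Leave-one-subject-out cross-validation: one fold per subject."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(subject_ids)
    if len(np.unique(groups)) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    logo = LeaveOneGroupOut()
    return _evaluate_splits(X, y, logo.split(X, y, groups), algorithm, "loso")


# ---------------------------------------------------------------------------
# ablation harness

#: 38-feature baseline: the statistical block plus the basic geometric
#: descriptors (location, area, Hu moments, coverages, top contour).  This
#: is a documented stand-in for the external 38-feature spatial set the
#: full 100-feature descriptor is compared against; that set's exact
#: membership is not published alongside it.
BASELINE_38 = (
    [f"Feat{i}" for i in range(1, 9)]  # statistical
    + [f"Feat{i}" for i in range(9, 22)]  # location + area
    + [f"Feat{i}" for i in range(22, 29)]  # Hu moments
    + [f"Feat{i}" for i in range(29, 33)]  # coverage + quantile coverages
    + [f"Feat{i}" for i in range(33, 37)]  # region coverages
    + ["Feat37", "Feat38"]  # contour count, max contour area
)
assert len(BASELINE_38) == 38


def _select(features: pd.DataFrame, use_normalized: bool, names: list[str]):
    cols = [f"smoothed/{n}" for n in names]
    if use_normalized:
        cols += [f"normalized/{n}" for n in names]
    return features[cols].to_numpy(float)


def run_ablation(
    features: pd.DataFrame,
    labels,
    subject_ids,
    classifiers=CLASSIFIER_IDS,
    schemes=("kfold", "loso"),
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy grid over {normalization on/off} x {full vs 38-feature set}.

    ``features`` must hold the 200 named columns produced by
    :func:`smartsleeve.features.extract_sample`.  "Normalization on" uses
    both images' features; "off" drops the body-size-normalized image and
    keeps only the smoothed one.  Returns one row per classifier with one
    accuracy column per (scheme, normalization, feature-set) cell, mirror-
    ing the usual 8-column ablation layout.
    """
    feature_sets = {"full": FEATURE_NAMES, "baseline38": BASELINE_38}
    rows = {}
    for clf in classifiers:
        row = {}
        for scheme in schemes:
            for norm_on in (True, False):
                for set_name, names in feature_sets.items():
                    X = _select(features, norm_on, names)
                    if scheme == "kfold":
                        res = run_kfold(X, labels, algorithm=clf, k=k, seed=seed)
                    else:
                        res = run_loso(X, labels, subject_ids, algorithm=clf)
                    norm_tag = "norm" if norm_on else "nonorm"
                    row[f"{scheme}/{norm_tag}/{set_name}"] = res.accuracy
        rows[clf] = row
    return pd.DataFrame.from_dict(rows, orient="index")
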