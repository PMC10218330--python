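"""Classification metrics and the stratified k-fold evaluation harness.

class1 is the positive class. Accuracy is the standard (TP+TN)/total.
The default F1 variant is the sensitivity/specificity harmonic mean
2*Sens*Spec/(Sens+Spec); ``f1_variant='standard'`` gives the usual
precision/recall harmonic mean.

Four classifier backends are supported, mirroring a typical microarray
benchmark configuration: a Mahalanobis k-nearest-neighbour (k = 20, pooled
within-class covariance with a 1e-6 ridge), a 20-tree random forest
(max_depth 15, Gini, at most 100 features per split), an RBF-kernel SVM
(C = 0.01, dimension-scaled gamma) and a multinomial naive Bayes with Lidstone
smoothing (features min-shifted per training fold to be non-negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .containers import ExpressionMatrix
from .errors import EmptyClassError, FoldTooSmallError

log = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("knn", "rf", "svm", "nb")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "knn": {"k": 20, "ridge": 1e-6},
    "rf": {"n_estimators": 20, "max_features": 100, "max_depth": 15,
           "criterion": "gini"},
    # gamma follows the dimension-aware e1071/sklearn convention; a fixed
    # numeric value (e.g. 0.1) can be configured for a known feature scale
    "svm": {"kernel": "rbf", "C": 0.01, "gamma": "scale"},
    "nb": {"alpha": 1.0},
}


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass
class ClassifierSpec:
    kind: str = "svm"
    hyperparameters: dict = field(default_factory=dict)
    folds: int = 10
    repeats: int = 1
    seed: int = 42
    f1_variant: str = "sens_spec"

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.kind])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def metrics(counts: ConfusionCounts, f1_variant: str = "sens_spec") -> dict:
    """TPR, FPR, accuracy and F1 from confusion counts.

    Metrics with a zero denominator come back as None with a warning.
    """
    if f1_variant not in ("sens_spec", "standard"):
        raise ValueError(f"unknown f1 variant {f1_variant!r}")
    if counts.total == 0:
        raise EmptyClassError("no evaluated samples")

    def ratio(num, den, name):
        if den == 0:
            log.warning("metric %s undefined (zero denominator)", name)
            return None
        return num / den

    tpr = ratio(counts.tp, counts.tp + counts.fn, "tpr")
    fpr = ratio(counts.fp, counts.tn + counts.fp, "fpr")
    acc = ratio(counts.tp + counts.tn, counts.total, "acc")
    if f1_variant == "sens_spec":
        sens = tpr
        spec = None if fpr is None else 1.0 - fpr
        if sens is None or spec is None or sens + spec == 0:
            f1 = None
        else:
            f1 = 2 * sens * spec / (sens + spec)
    else:
        prec = ratio(counts.tp, counts.tp + counts.fp, "precision")
        rec = tpr
        if prec is None or rec is None or prec + rec == 0:
            f1 = None
        else:
            f1 = 2 * prec * rec / (prec + rec)
    return {"tpr": tpr, "fpr": fpr, "acc": acc, "f1": f1}


class _MahalanobisKNN:
    """KNN under a Mahalanobis metric with pooled within-class covariance.

    The covariance of a wide expression matrix is singular, so a small ridge
    keeps the inverse defined.
    """

    def __init__(self, k: int, ridge: float):
        self.k, self.ridge = k, ridge

    def fit(self, X, y):
        mus = {c: X[y == c].mean(axis=0) for c in np.unique(y)}
        D = X - np.vstack([mus[c] for c in y])
        S = D.T @ D / len(y) + self.ridge * np.eye(X.shape[1])
        VI = np.linalg.inv(S)
        k = min(self.k, len(y))
        self._knn = KNeighborsClassifier(
            n_neighbors=k, metric="mahalanobis", metric_params={"VI": VI}
        ).fit(X, y)
        return self

    def predict(self, X):
        return self._knn.predict(X)


class _ShiftedMultinomialNB:
    """Multinomial NB on min-shifted (non-negative) features."""

    def __init__(self, alpha: float):
        self.alpha = alpha

    def fit(self, X, y):
        self._shift = X.min()
        self._nb = MultinomialNB(alpha=self.alpha).fit(X - self._shift, y)
        return self

    def predict(self, X):
        return self._nb.predict(np.clip(X - self._shift, 0.0, None))


def make_classifier(spec: ClassifierSpec, n_features: int, seed: int):
    hp = spec.hyperparameters
    if spec.kind == "knn":
        return _MahalanobisKNN(hp["k"], hp["ridge"])
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"],
            max_features=min(hp["max_features"], n_features),
            max_depth=hp["max_depth"],
            criterion=hp["criterion"],
            random_state=seed,
        )
    if spec.kind == "svm":
        return SVC(kernel=hp["kernel"], C=hp["C"], gamma=hp["gamma"])
    return _ShiftedMultinomialNB(hp["alpha"])


def cross_validate(matrix: ExpressionMatrix, spec: ClassifierSpec) -> dict:
    """Repeated stratified k-fold CV; class1 = positive.

    Returns per-metric mean and SD over folds x repeats plus metrics on the
    aggregated confusion counts. Deterministic given ``spec.seed``.
    """
    if matrix.labels is None:
        raise ValueError("matrix has no labels")
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    classes = sorted(matrix.labels.unique())
    if len(classes) != 2:
        raise EmptyClassError(f"need 2 classes, found {len(classes)}")
    pos = classes[0]  # 'class1' sorts first
    y = (matrix.labels.to_numpy() == pos).astype(int)
    n_per_class = min(int(y.sum()), int((1 - y).sum()))
    if spec.folds > n_per_class:
        raise FoldTooSmallError(
            f"{spec.folds} folds but the smaller class has only "
            f"{n_per_class} samples"
        )
    fold_metrics: list[dict] = []
    total = ConfusionCounts()
    for rep in range(spec.repeats):
        skf = StratifiedKFold(
            n_splits=spec.folds, shuffle=True,
            random_state=(spec.seed + rep) % 2**31,
        )
        for fold_i, (tr, te) in enumerate(skf.split(X, y)):
            clf = make_classifier(
                spec, X.shape[1], (spec.seed + 31 * rep + fold_i) % 2**31
            )
            clf.fit(X[tr], y[tr])
            pred = np.asarray(clf.predict(X[te]))
            c = ConfusionCounts(
                tp=int(((pred == 1) & (y[te] == 1)).sum()),
                fp=int(((pred == 0) & (y[te] == 1)).sum()),
                tn=int(((pred == 0) & (y[te] == 0)).sum()),
                fn=int(((pred == 1) & (y[te] == 0)).sum()),
            )
            total = total + c
            try:
                fold_metrics.append(metrics(c, spec.f1_variant))
            except EmptyClassError:
                log.warning("fold with a single class; skipped in per-fold "
                            "averages")
    frame = pd.DataFrame(fold_metrics, dtype=float)
    summary = {
        "classifier": spec.kind,
        "folds": spec.folds,
        "repeats": spec.repeats,
        "seed": spec.seed,
        "n_samples": int(len(y)),
        "n_genes": int(X.shape[1]),
        "aggregated": metrics(total, spec.f1_variant),
        "counts": {"tp": total.tp, "fp": total.fp, "tn": total.tn,
                   "fn": total.fn},
        "mean": {k: float(frame[k].mean()) for k in frame.columns},
        "sd": {k: float(frame[k].std(ddof=0)) for k in frame.columns},
    }
    return summary
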