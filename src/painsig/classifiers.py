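"""The three pain-intensity classifiers.

* LDA in a one-vs-rest arrangement: one binary linear discriminant per
  pain state, predicting the state with the highest discriminant output.
* KNN with k = 3, Euclidean metric, and inverse-distance vote weighting
  (a zero-distance neighbor claims the query outright).
* Soft-margin SVM with an RBF kernel exp(-||x-y||^2 / (2 sigma^2)),
  defaults C = 5 and sigma = 2.58, one-vs-rest; an optional stratified-CV
  grid search over (C, sigma) with ties broken toward smaller C then
  larger sigma.

All models standardize features to zero mean and unit variance using
training-set statistics. Implemented over scikit-learn estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CLASSIFIER_KINDS = ("lda", "knn", "svm")


def sigma_to_gamma(sigma: float) -> float:
    """RBF width sigma -> scikit-learn's gamma = 1 / (2 sigma^2)."""
    if sigma <= 0:
        raise ValueError("kernel width must be positive")
    return 1.0 / (2.0 * sigma**2)


@dataclass(frozen=True)
class ClassifierConfig:
    kind: str = "lda"
    knn_k: int = 3
    svm_C: float = 5.0
    svm_sigma: float = 2.58
    grid_search: bool = False
    grid_C: tuple[float, ...] = (0.1, 1.0, 5.0, 10.0, 100.0)
    grid_sigma: tuple[float, ...] = (0.5, 1.0, 2.58, 5.0, 10.0)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier {self.kind!r}; expected one of {CLASSIFIER_KINDS}"
            )
        if self.knn_k < 1:
            raise ValueError("knn_k must be at least 1")
        if self.svm_C <= 0 or self.svm_sigma <= 0:
            raise ValueError("svm_C and svm_sigma must be positive")


@dataclass
class TrainedModel:
    kind: str
    pipeline: Pipeline
    classes: np.ndarray
    n_features: int
    svm_params: tuple[float, float] | None = None  # (C, sigma) actually used


def make_estimator(cfg: ClassifierConfig) -> Pipeline:
    """Unfitted scikit-learn pipeline (standardization + classifier)."""
    if cfg.kind == "lda":
        clf = OneVsRestClassifier(LinearDiscriminantAnalysis())
    elif cfg.kind == "knn":
        clf = KNeighborsClassifier(
            n_neighbors=cfg.knn_k,
            weights="distance",
            metric="euclidean",
            algorithm="brute",
        )
    else:
        clf = OneVsRestClassifier(
            SVC(C=cfg.svm_C, kernel="rbf", gamma=sigma_to_gamma(cfg.svm_sigma))
        )
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _fit(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig) -> TrainedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    pipe = make_estimator(cfg)
    pipe.fit(X, y)
    svm_params = (cfg.svm_C, cfg.svm_sigma) if cfg.kind == "svm" else None
    return TrainedModel(
        kind=cfg.kind,
        pipeline=pipe,
        classes=np.unique(y),
        n_features=X.shape[1],
        svm_params=svm_params,
    )


def train(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig) -> TrainedModel:
    if cfg.kind == "svm" and cfg.grid_search:
        return train_svm_grid(X, y, cfg)
    return _fit(X, y, cfg)


def train_lda_ovr(X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """One-vs-rest LDA: a binary discriminant per class, argmax decision."""
    return _fit(X, y, ClassifierConfig(kind="lda"))


def train_knn(X: np.ndarray, y: np.ndarray, k: int = 3) -> TrainedModel:
    return _fit(X, y, ClassifierConfig(kind="knn", knn_k=k))


def train_svm_grid(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig) -> TrainedModel:
    """RBF SVM, with the default (C, sigma) used directly unless grid
    search is enabled, in which case stratified-CV accuracy picks the pair
    (ties: smaller C, then larger sigma)."""
    if cfg.kind != "svm":
        cfg = ClassifierConfig(**{**cfg.__dict__, "kind": "svm"})
    if not cfg.grid_search:
        return _fit(X, y, cfg)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    best: tuple[float, float, float] | None = None  # (score, C, sigma)
    for C in sorted(cfg.grid_C):
        for sigma in sorted(cfg.grid_sigma, reverse=True):
            est = make_estimator(
                ClassifierConfig(kind="svm", svm_C=C, svm_sigma=sigma)
            )
            accs = []
            for tr, te in cv.split(X, y):
                m = clone(est)
                m.fit(X[tr], y[tr])
                accs.append(float(np.mean(m.predict(X[te]) == y[te])))
            score = float(np.mean(accs))
            if best is None or score > best[0]:
                best = (score, C, sigma)
    assert best is not None
    chosen = ClassifierConfig(kind="svm", svm_C=best[1], svm_sigma=best[2])
    model = _fit(X, y, chosen)
    model.svm_params = (best[1], best[2])
    return model


def predict(model: TrainedModel, rows: np.ndarray) -> np.ndarray:
    """Standardize with the stored training statistics and apply the
    model's decision rule to each row."""
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"row width {X.shape[1]} does not match training width {model.n_features}"
        )
    return model.pipeline.predict(X)


def knn_classify(model: TrainedModel, query: np.ndarray) -> object:
    """Label of a single query row under the inverse-distance KNN vote."""
    if model.kind != "knn":
        raise ValueError("knn_classify requires a KNN model")
    return predict(model, np.atleast_2d(query))[0]
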