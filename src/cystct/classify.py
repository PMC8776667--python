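"""Base classifiers, majority voting, and random-forest probability stacking.

The fusion scheme ("MMRF"): three base classifiers — k-nearest-neighbors,
softmax (multinomial logistic regression), and Gaussian naive Bayes — each
emit a posterior probability for the positive class; a random-forest
meta-classifier is trained on those probabilities and produces the fused
decision.  To avoid target leakage the meta-model is trained on
*out-of-fold* base probabilities obtained by stratified cross-validation on
the training set; the base models are then refit on the full training set
for inference.  Classifiers whose probabilities carry more signal earn more
weight in the forest's splits, which is the point of the stack.

The positive class is MCN throughout (the clinically actionable lesion).
Every fit is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "POSITIVE_LABEL",
    "BASE_KINDS",
    "BaseClassifierConfig",
    "RandomForestConfig",
    "StackedModel",
    "SingleClassError",
    "fit_base",
    "predict_proba",
    "positive_proba",
    "majority_vote",
    "fit_meta",
    "fit_mmrf",
    "predict_mmrf",
]

POSITIVE_LABEL = "MCN"
BASE_KINDS = ("knn", "softmax", "bayes", "svm")


class SingleClassError(ValueError):
    """Raised when a training set (or fold) contains only one class."""


@dataclass(frozen=True)
class BaseClassifierConfig:
    kind: str = "knn"
    k: int = 5
    regularization: float = 1.0
    kernel: str = "rbf"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in BASE_KINDS:
            raise ValueError(f"kind must be one of {BASE_KINDS}, got {self.kind!r}")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1 (avoids neighbor-vote ties)")
        if self.regularization <= 0:
            raise ValueError("regularization must be > 0")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")


@dataclass(frozen=True)
class RandomForestConfig:
    n_estimators: int = 200
    max_depth: int | None = None
    seed: int = 0


DEFAULT_BASE_CONFIGS = (
    BaseClassifierConfig(kind="knn"),
    BaseClassifierConfig(kind="softmax"),
    BaseClassifierConfig(kind="bayes"),
)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D feature matrix")
    if len(y) != X.shape[0]:
        raise ValueError(f"{len(y)} labels for {X.shape[0]} rows")
    if np.isnan(X).any():
        raise ValueError("X contains NaN values")
    if len(np.unique(y)) < 2:
        raise SingleClassError("training labels contain a single class")
    return X, y


def _make_estimator(config: BaseClassifierConfig) -> Pipeline:
    """Standardizing pipeline around the requested classifier.

    The scaler learns train-set statistics only (sklearn Pipeline semantics),
    so no test information leaks into the fit.
    """
    kind = config.kind
    if kind == "knn":
        clf = KNeighborsClassifier(n_neighbors=config.k)
    elif kind == "softmax":
        clf = LogisticRegression(
            C=config.regularization, max_iter=2000, random_state=config.seed
        )
    elif kind == "bayes":
        clf = GaussianNB()
    else:  # svm: Platt-style sigmoid calibration turns margins into probabilities
        from sklearn.calibration import CalibratedClassifierCV

        clf = CalibratedClassifierCV(
            SVC(
                C=config.regularization,
                kernel=config.kernel,
                random_state=config.seed,
            ),
            method="sigmoid",
            ensemble=False,
        )
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def fit_base(
    kind: str, X: np.ndarray, y: np.ndarray, config: BaseClassifierConfig | None = None
) -> Pipeline:
    """Fit one base classifier; returns a pipeline exposing ``predict_proba``."""
    if config is None:
        config = BaseClassifierConfig(kind=kind)
    elif config.kind != kind:
        raise ValueError(f"config.kind {config.kind!r} does not match {kind!r}")
    X, y = _validate_xy(X, y)
    return _make_estimator(config).fit(X, y)


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    """Per-row class probabilities (columns ordered as ``model.classes_``)."""
    X = np.asarray(X, dtype=float)
    n_expected = model.named_steps["scale"].n_features_in_
    if X.shape[1] != n_expected:
        raise ValueError(f"X has {X.shape[1]} features, model expects {n_expected}")
    return model.predict_proba(X)


def positive_proba(model, X: np.ndarray, positive_label: str = POSITIVE_LABEL) -> np.ndarray:
    """Probability of the positive class for each row."""
    proba = predict_proba(model, X)
    classes = list(model.classes_)
    if positive_label not in classes:
        raise ValueError(f"model classes {classes} lack positive label {positive_label!r}")
    return proba[:, classes.index(positive_label)]


def majority_vote(labels) -> object:
    """Modal label of exactly three binary votes (no tie is possible)."""
    labels = list(labels)
    if len(labels) != 3:
        raise ValueError(f"majority vote requires exactly 3 votes, got {len(labels)}")
    uniq = set(labels)
    if len(uniq) > 2:
        raise ValueError(f"votes must be binary, got {sorted(map(str, uniq))}")
    return max(uniq, key=labels.count)


@dataclass
class StackedModel:
    """Fitted MMRF stack: three base pipelines + random-forest meta-model."""

    base_models: list
    base_configs: tuple
    meta_model: RandomForestClassifier
    classes: np.ndarray
    positive_label: str
    cv_folds: int
    seed: int
    oof_probabilities: np.ndarray = field(repr=False, default=None)


def fit_meta(
    prob_matrix: np.ndarray,
    y: np.ndarray,
    rf_config: RandomForestConfig | None = None,
) -> RandomForestClassifier:
    """Fit the random-forest meta-classifier on base-probability columns."""
    rf_config = rf_config or RandomForestConfig()
    prob_matrix = np.asarray(prob_matrix, dtype=float)
    if prob_matrix.ndim != 2:
        raise ValueError("probability matrix must be 2-D (rows x base models)")
    rf = RandomForestClassifier(
        n_estimators=rf_config.n_estimators,
        max_depth=rf_config.max_depth,
        random_state=rf_config.seed,
    )
    return rf.fit(prob_matrix, y)


def fit_mmrf(
    X: np.ndarray,
    y: np.ndarray,
    base_configs: tuple = DEFAULT_BASE_CONFIGS,
    rf_config: RandomForestConfig | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    positive_label: str = POSITIVE_LABEL,
) -> StackedModel:
    """Train the stacked model.

    1. For each base classifier, collect out-of-fold positive-class
       probabilities over the training set via stratified ``cv_folds``-fold
       cross-validation (seeded shuffle).
    2. Fit the random forest on the resulting (n, n_bases) matrix vs y.
    3. Refit every base classifier on the full training set.
    """
    X, y = _validate_xy(X, y)
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    class_counts = np.unique(y, return_counts=True)[1]
    if class_counts.min() < cv_folds:
        raise SingleClassError(
            f"smallest class has {class_counts.min()} samples; stratified "
            f"{cv_folds}-fold CV would leave a fold with one class — reduce "
            "cv_folds or add data"
        )
    rf_config = rf_config or RandomForestConfig(seed=seed)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    classes = np.unique(y)
    pos_col = list(classes).index(positive_label) if positive_label in classes else 1

    oof_cols = []
    for config in base_configs:
        est = _make_estimator(config)
        oof = cross_val_predict(est, X, y, cv=skf, method="predict_proba")
        oof_cols.append(oof[:, pos_col])
    oof_matrix = np.column_stack(oof_cols)

    meta = fit_meta(oof_matrix, y, rf_config)
    bases = [_make_estimator(c).fit(X, y) for c in base_configs]
    return StackedModel(
        base_models=bases,
        base_configs=tuple(base_configs),
        meta_model=meta,
        classes=classes,
        positive_label=positive_label,
        cv_folds=cv_folds,
        seed=seed,
        oof_probabilities=oof_matrix,
    )


def predict_mmrf(model: StackedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fused positive-class probability and hard label for each row.

    The decision threshold is 0.5; an exact tie goes to the positive class.
    """
    X = np.asarray(X, dtype=float)
    base_probs = np.column_stack(
        [positive_proba(m, X, model.positive_label) for m in model.base_models]
    )
    meta_classes = list(model.meta_model.classes_)
    pos_idx = meta_classes.index(model.positive_label)
    fused = model.meta_model.predict_proba(base_probs)[:, pos_idx]
    negative = next(c for c in meta_classes if c != model.positive_label)
    labels = np.where(fused >= 0.5, model.positive_label, negative)
    return fused, labels
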