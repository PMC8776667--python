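"""Dataset splitting and the six evaluation indicators.

Metrics, all derived from the 2x2 confusion table against the declared
positive class (MCN):

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / N
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

plus the AUC of the positive-class score, i.e. the Mann–Whitney probability
that a random positive outscores a random negative (ties count 1/2).

Two split modes are provided.  ``image`` mode splits slices at random with
label stratification — simple, but slices of one patient can land on both
sides, which inflates test scores when slices within a patient are
correlated.  ``patient`` mode (the default) assigns whole patients to one
side, approximating the requested fraction at the image level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "SplitSpec",
    "split_dataset",
    "confusion_counts",
    "compute_metrics",
    "f1_from_precision_sensitivity",
    "roc_auc",
    "roc_points",
    "compare_auc_permutation",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
        }

    def formatted(self) -> dict:
        """Percentages to 2 d.p. (AUC to 2 d.p. as a fraction)."""
        out = {k: f"{v * 100:.2f}%" for k, v in self.as_dict().items()
               if k != "auc" and v is not None}
        if self.auc is not None:
            out["auc"] = f"{self.auc:.2f}"
        return out


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    mode: str = "patient"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mode not in ("image", "patient"):
            raise ValueError("mode must be 'image' or 'patient'")


def split_dataset(
    manifest: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index split of a manifest.

    Image mode: stratified random split of rows.  Patient mode: every
    patient's rows land wholly on one side; the train fraction is
    approximated at the image level per class.  Positional indices returned;
    deterministic given ``spec.seed``.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    labels = manifest["label"].to_numpy()
    idx = np.arange(len(manifest))
    if spec.mode == "image":
        train, test = train_test_split(
            idx,
            train_size=spec.train_fraction,
            stratify=labels,
            random_state=spec.seed,
        )
        return np.sort(train), np.sort(test)

    if "patient_id" not in manifest.columns:
        raise ValueError("patient-mode split requires a patient_id column")
    rng = np.random.default_rng(spec.seed)
    train_mask = np.zeros(len(manifest), dtype=bool)
    for label in np.unique(labels):
        sub = manifest[labels == label]
        patients = sub["patient_id"].unique()
        rng.shuffle(patients)
        target = spec.train_fraction * len(sub)
        count = 0
        for pid in patients:
            pid_rows = sub.index[sub["patient_id"] == pid]
            if count < target:
                train_mask[manifest.index.get_indexer(pid_rows)] = True
                count += len(pid_rows)
    return idx[train_mask], idx[~train_mask]


def confusion_counts(y_true, y_pred, positive_label) -> ConfusionCounts:
    """Standard 2x2 tally against the declared positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"{len(y_true)} truths vs {len(y_pred)} predictions")
    tpos = y_true == positive_label
    ppos = y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def f1_from_precision_sensitivity(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (0 when both are 0)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """The five threshold-based indicators from confusion counts (AUC unset)."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    accuracy = (counts.tp + counts.tn) / counts.total
    f1 = f1_from_precision_sensitivity(precision, sensitivity)
    return MetricsReport(
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        f1=f1,
    )


def _binarize(y_true, positive_label) -> np.ndarray:
    y = np.asarray(y_true) == positive_label
    if y.all() or not y.any():
        raise ValueError("roc_auc requires both classes present in y_true")
    return y.astype(int)


def roc_auc(y_true, scores, positive_label="MCN") -> float:
    """Area under the ROC curve of ``scores`` for the positive class."""
    y = _binarize(y_true, positive_label)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_points(y_true, scores, positive_label="MCN") -> pd.DataFrame:
    """Empirical ROC curve (fpr, tpr, threshold) for reporting."""
    y = _binarize(y_true, positive_label)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def compare_auc_permutation(
    y_true,
    scores_a,
    scores_b,
    positive_label="MCN",
    n_permutations: int = 2000,
    seed: int = 0,
) -> float:
    """Paired permutation p-value for AUC(a) != AUC(b) on the same test set.

    Per permutation the two score columns are swapped sample-wise with
    probability 1/2; the p-value is the fraction of permuted |AUC
    differences| at least as large as the observed one.
    """
    y = _binarize(y_true, positive_label)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    observed = abs(roc_auc_score(y, a) - roc_auc_score(y, b))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        swap = rng.random(len(y)) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        if abs(roc_auc_score(y, pa) - roc_auc_score(y, pb)) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
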