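"""End-to-end experiment orchestration: segment -> preprocess -> extract ->
train -> predict -> evaluate.

An :class:`ExperimentConfig` names one arm of a comparison: a data source
(phantom parameters or a manifest on disk), a preprocessing mode (manual
masked outline vs multichannel rectangle), a feature extractor (one of the
texture families or a CNN backend), and a classifier (a single base kind,
3-voter majority voting, or the MMRF random-forest stack).  A single global
seed fans out to per-stage seeds by hashing the stage name, so any stage
can be re-run in isolation and two runs of the same config are identical
except for timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    DEFAULT_BASE_CONFIGS,
    POSITIVE_LABEL,
    BaseClassifierConfig,
    RandomForestConfig,
    fit_base,
    fit_mmrf,
    majority_vote,
    positive_proba,
    predict_mmrf,
)
from .deepfeat import ExtractorConfig, extract_deep_features
from .evaluate import (
    MetricsReport,
    SplitSpec,
    compute_metrics,
    confusion_counts,
    roc_auc,
    roc_points,
    split_dataset,
)
from .multichannel import (
    DEFAULT_CANNY,
    DEFAULT_WINDOW,
    CannyParams,
    WindowSpec,
    assemble_multichannel,
    window_image,
)
from .phantoms import (
    PhantomParams,
    PhantomSample,
    generate_cohort,
    load_image_png,
    load_mask_png,
    read_manifest,
)
from .roi import expand_box, extract_patch, masked_roi_image, tight_bounding_box
from .texture import EXTRACTORS, extract_features

logger = logging.getLogger("cystct.pipeline")

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "stage_seed",
    "preprocess_sample",
    "build_feature_matrix",
    "run_experiment",
    "compare_table",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = ("precision", "sensitivity", "specificity", "accuracy", "f1", "auc")

PREPROCESS_MODES = ("manual_roi", "multichannel")
CLASSIFIER_KINDS = ("knn", "softmax", "bayes", "svm", "voting", "mmrf")
DEEP_EXTRACTORS = ("tiny_cnn", "resnet_pool", "alexnet_pool")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived by hashing the stage name with the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment arm.  Exactly one of manifest_path / phantom data source."""

    preprocessing: str = "multichannel"
    extractor: str = "glcm"
    classifier: str = "mmrf"
    manifest_path: str | None = None
    phantom_params: PhantomParams | None = None
    n_per_class: int = 20
    slices_per_patient: int = 5
    window: WindowSpec = DEFAULT_WINDOW
    canny: CannyParams = DEFAULT_CANNY
    split: SplitSpec = SplitSpec()
    extractor_kwargs: tuple = ()
    margin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preprocessing not in PREPROCESS_MODES:
            raise ValueError(f"preprocessing must be one of {PREPROCESS_MODES}")
        if self.classifier not in CLASSIFIER_KINDS:
            raise ValueError(f"classifier must be one of {CLASSIFIER_KINDS}")
        if self.extractor not in EXTRACTORS and self.extractor not in DEEP_EXTRACTORS:
            raise ValueError(
                f"extractor {self.extractor!r} not registered; texture: "
                f"{sorted(EXTRACTORS)}, deep: {list(DEEP_EXTRACTORS)}"
            )


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    metrics: MetricsReport
    predictions: pd.DataFrame
    roc: pd.DataFrame
    n_train: int
    n_test: int
    out_dir: Path | None = None


def _load_samples(config: ExperimentConfig) -> list[PhantomSample]:
    if config.manifest_path is not None:
        root = Path(config.manifest_path).parent
        manifest = read_manifest(config.manifest_path)
        samples = []
        for _, row in manifest.iterrows():
            samples.append(
                PhantomSample(
                    image=load_image_png(root / row["path"]),
                    mask=load_mask_png(root / row["mask_path"]),
                    label=row["label"],
                    patient_id=str(row["patient_id"]),
                    slice_index=int(row["slice_index"]),
                )
            )
        return samples
    params = config.phantom_params or PhantomParams(
        seed=stage_seed(config.seed, "phantoms")
    )
    return generate_cohort(config.n_per_class, config.slices_per_patient, params)


def preprocess_sample(
    sample: PhantomSample, config: ExperimentConfig
):
    """One slice -> the input its extractor consumes.

    manual_roi: blank outside the outline, crop the tight box — the
    "manual outline" arm.  multichannel: expand the tight box by the margin
    (default 2 px), crop the rectangle, assemble the 3-channel image.
    Texture extractors consume the windowed plane (channel 1); deep
    extractors consume all three channels.
    """
    box = tight_bounding_box(sample.mask)
    if config.preprocessing == "manual_roi":
        masked = masked_roi_image(sample.image, sample.mask, fill=config.window.lower)
        patch = extract_patch(masked, box)
    else:
        box = expand_box(box, margin=config.margin, image_shape=sample.image.shape)
        patch = extract_patch(sample.image, box)
    if config.extractor in DEEP_EXTRACTORS:
        return assemble_multichannel(patch, config.window, config.canny)
    return window_image(patch, config.window)


def build_feature_matrix(
    samples: list[PhantomSample], config: ExperimentConfig
) -> np.ndarray:
    """Stack one feature row per slice, in manifest order."""
    kwargs = dict(config.extractor_kwargs)
    if config.extractor in DEEP_EXTRACTORS:
        ext_cfg = ExtractorConfig(
            backend=config.extractor,
            weight_seed=stage_seed(config.seed, "deepfeat"),
            **kwargs,
        )
        rows = [
            extract_deep_features(preprocess_sample(s, config), ext_cfg)
            for s in samples
        ]
    else:
        rows = [
            extract_features(config.extractor, preprocess_sample(s, config), **kwargs).values
            for s in samples
        ]
    X = np.vstack(rows)
    logger.info("features: %d slices -> matrix %s", len(samples), X.shape)
    return X


def _fit_predict(
    config: ExperimentConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Train the configured classifier; return (positive scores, hard labels)."""
    seed = stage_seed(config.seed, "classifier")
    if config.classifier == "mmrf":
        model = fit_mmrf(X_train, y_train, seed=seed)
        return predict_mmrf(model, X_test)
    if config.classifier == "voting":
        bases = [
            fit_base(c.kind, X_train, y_train, BaseClassifierConfig(kind=c.kind, seed=seed))
            for c in DEFAULT_BASE_CONFIGS
        ]
        probs = np.column_stack([positive_proba(b, X_test) for b in bases])
        votes = probs >= 0.5
        labels_all = np.array(
            [
                majority_vote([
                    POSITIVE_LABEL if v else _negative(y_train) for v in row
                ])
                for row in votes
            ]
        )
        # score for ROC: mean base probability (voting itself is score-free)
        return probs.mean(axis=1), labels_all
    cfg = BaseClassifierConfig(kind=config.classifier, seed=seed)
    model = fit_base(config.classifier, X_train, y_train, cfg)
    scores = positive_proba(model, X_test)
    neg = _negative(y_train)
    labels = np.where(scores >= 0.5, POSITIVE_LABEL, neg)
    return scores, labels


def _negative(y) -> str:
    neg = [c for c in np.unique(y) if c != POSITIVE_LABEL]
    return neg[0] if neg else "SCN"


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> ExperimentResult:
    """Execute one arm end to end; optionally write report files.

    Writes (when ``out_dir`` is given): metrics.json, predictions.csv,
    roc.csv, and provenance.json embedding the full config.  Fully
    deterministic for a fixed config.
    """
    samples = _load_samples(config)
    logger.info("loaded %d slices", len(samples))
    manifest = pd.DataFrame(
        {
            "label": [s.label for s in samples],
            "patient_id": [s.patient_id for s in samples],
            "slice_index": [s.slice_index for s in samples],
        }
    )
    split = SplitSpec(
        train_fraction=config.split.train_fraction,
        mode=config.split.mode,
        seed=stage_seed(config.seed, "split"),
    )
    train_idx, test_idx = split_dataset(manifest, split)
    X = build_feature_matrix(samples, config)
    y = manifest["label"].to_numpy()

    scores, labels = _fit_predict(config, X[train_idx], y[train_idx], X[test_idx])
    y_test = y[test_idx]
    counts = confusion_counts(y_test, labels, POSITIVE_LABEL)
    metrics = compute_metrics(counts)
    metrics.auc = roc_auc(y_test, scores, POSITIVE_LABEL)
    roc = roc_points(y_test, scores, POSITIVE_LABEL)

    predictions = pd.DataFrame(
        {
            "patient_id": manifest["patient_id"].to_numpy()[test_idx],
            "slice_index": manifest["slice_index"].to_numpy()[test_idx],
            "y_true": y_test,
            "score": np.round(scores, 10),
            "y_pred": labels,
        }
    )
    result = ExperimentResult(
        config=config,
        metrics=metrics,
        predictions=predictions,
        roc=roc,
        n_train=len(train_idx),
        n_test=len(test_idx),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        predictions.to_csv(out_dir / "predictions.csv", index=False)
        roc.to_csv(out_dir / "roc.csv", index=False)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(metrics.as_dict(), fh, indent=2)
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(_provenance(config, result), fh, indent=2, default=str)
        result.out_dir = out_dir
    return result


def _provenance(config: ExperimentConfig, result: ExperimentResult) -> dict:
    from dataclasses import asdict

    return {
        "cystct_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("phantoms", "split", "deepfeat", "classifier")
        },
        "n_train": result.n_train,
        "n_test": result.n_test,
    }


def compare_table(
    configs: list[ExperimentConfig],
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Run several arms on the same data/split and tabulate the six indicators.

    All configs must share the data source and split seed so rows are a
    paired comparison; percentages to 2 d.p., AUC to 2 d.p.
    """
    if len(configs) < 2:
        raise ValueError("need at least two configs to compare")
    ref = configs[0]
    for c in configs[1:]:
        same_data = (
            c.manifest_path == ref.manifest_path
            and c.phantom_params == ref.phantom_params
            and c.n_per_class == ref.n_per_class
            and c.slices_per_patient == ref.slices_per_patient
            and c.seed == ref.seed
        )
        if not same_data:
            raise ValueError(
                "compare_table requires identical data source and seed across "
                "configs (paired comparison)"
            )
    names = names or [
        f"{c.preprocessing}/{c.extractor}/{c.classifier}" for c in configs
    ]
    rows = []
    for name, c in zip(names, configs):
        res = run_experiment(c)
        d = res.metrics.as_dict()
        rows.append(
            {
                "method": name,
                **{
                    k: (f"{d[k] * 100:.2f}%" if k != "auc" else f"{d[k]:.2f}")
                    for k in TABLE_COLUMNS
                },
            }
        )
    return pd.DataFrame(rows, columns=["method", *TABLE_COLUMNS])
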