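"""Screening metrics, cross-validation, and experiment sweeps.

Image-level screening is summarized by the usual confusion-matrix ratios —
accuracy, precision, sensitivity (recall on abnormals), specificity — plus
the rank-based AUROC (the probability that a randomly chosen abnormal image
outscores a randomly chosen normal one, ties counting one half).

Cross-validation follows the one-class training protocol: only the normal
pool is folded (rotating which normals train the encoders and which
calibrate the score scale), while a fixed labeled test pool is scored every
fold.  The sweep runner reproduces the shape of the published experiment
grids — single-resolution sizes crossed with similarity functions, and
multiresolution weight vectors — at whatever scale the dataset provides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .anomaly_map import Calibration, classify
from .exceptions import InvalidInputError
from .pipeline import (
    PipelineConfig,
    calibrate_pipeline,
    score_images,
    train_pipeline,
)

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvalReport",
    "confusion_metrics",
    "auroc",
    "counts_from_decisions",
    "evaluate_scores",
    "cross_validate",
    "run_sweep",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise InvalidInputError("confusion counts must be non-negative")
        if self.total == 0:
            raise InvalidInputError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class Metrics:
    """Closed-form confusion ratios; a ``None`` entry means the ratio's
    denominator was zero (undefined, deliberately not coerced to 0)."""

    accuracy: float
    precision: float | None
    sensitivity: float | None
    specificity: float | None


def confusion_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, precision, sensitivity and specificity of a count table."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return Metrics(
        accuracy=(counts.TP + counts.TN) / counts.total,
        precision=ratio(counts.TP, counts.TP + counts.FP),
        sensitivity=ratio(counts.TP, counts.TP + counts.FN),
        specificity=ratio(counts.TN, counts.TN + counts.FP),
    )


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUROC (Mann-Whitney statistic; ties count 1/2)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise InvalidInputError("labels and scores must be equal-length 1-D sequences")
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("AUROC requires both classes to be present")
    return float(roc_auc_score(labels, scores))


def counts_from_decisions(labels: Sequence[int], decisions: Sequence[str]) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=int)
    pred = np.asarray([1 if d == "abnormal" else 0 for d in decisions])
    return ConfusionCounts(
        TP=int(np.sum((labels == 1) & (pred == 1))),
        FP=int(np.sum((labels == 0) & (pred == 1))),
        TN=int(np.sum((labels == 0) & (pred == 0))),
        FN=int(np.sum((labels == 1) & (pred == 0))),
    )


def evaluate_scores(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> dict:
    """All image-level metrics for one (labels, scores) set at one threshold."""
    calibration = Calibration(quantiles={}, threshold=threshold)
    decisions = [classify(float(np.clip(s, 0, 1)), calibration) for s in scores]
    counts = counts_from_decisions(labels, decisions)
    m = confusion_metrics(counts)
    return {
        "accuracy": m.accuracy,
        "precision": m.precision,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "auroc": auroc(labels, scores),
    }


@dataclass
class EvalReport:
    """Per-fold metrics plus their arithmetic mean."""

    per_fold: pd.DataFrame
    config: dict

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.drop(columns=["fold"]).mean(numeric_only=True)

    def to_csv(self, path: str | Path) -> None:
        table = self.per_fold.copy()
        mean_row = self.mean.to_dict()
        mean_row["fold"] = "mean"
        table = pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
        table.to_csv(Path(path), index=False)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "config": self.config,
            "folds": self.per_fold.to_dict(orient="records"),
            "mean": {k: (None if pd.isna(v) else float(v)) for k, v in self.mean.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=float))


def cross_validate(
    normal_pool: Sequence[tuple[str, np.ndarray]],
    test_set: Sequence[tuple[str, np.ndarray, int]],
    config: PipelineConfig,
    n_folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """One-class k-fold cross-validation.

    The normal pool is split into ``n_folds`` near-equal folds (sizes differ
    by at most one image); each fold in turn calibrates the score scale
    while the remaining normals train the encoders and populate the
    reference database.  The labeled test pool is scored every fold.
    Encoders are retrained per fold; the whole procedure is seeded.
    """
    if n_folds < 2:
        raise InvalidInputError("need at least 2 folds")
    if len(normal_pool) < n_folds * 2:
        raise InvalidInputError("insufficient normal images for the requested folds")
    labels = [lab for _, _, lab in test_set]
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("test pool must contain both classes")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(normal_pool))
    folds = [sorted(order[i::n_folds]) for i in range(n_folds)]

    rows = []
    for f, val_idx in enumerate(folds):
        val_images = [normal_pool[i] for i in val_idx]
        train_images = [normal_pool[i] for i in sorted(set(order) - set(val_idx))]
        import dataclasses

        fold_config = dataclasses.replace(config, seed=int(seed * 1009 + f))
        encoders, db = train_pipeline(train_images, fold_config)
        calibration = calibrate_pipeline(encoders, db, val_images, fold_config)
        results = score_images(
            [(i, img) for i, img, _ in test_set], encoders, db, calibration, fold_config
        )
        metrics = evaluate_scores(labels, results["score"].to_numpy(), config.threshold)
        metrics["fold"] = f
        rows.append(metrics)

    report_config = {
        "patch_sizes": list(config.patch_sizes),
        "similarity": config.similarity,
        "weights": list(config.weights),
        "locality": dict(config.locality_config.d_per_size),
        "n_folds": n_folds,
        "seed": seed,
    }
    per_fold = pd.DataFrame(rows)[
        ["fold", "accuracy", "precision", "sensitivity", "specificity", "auroc"]
    ]
    return EvalReport(per_fold=per_fold, config=report_config)


def run_sweep(
    train_images: Sequence[tuple[str, np.ndarray]],
    val_normals: Sequence[tuple[str, np.ndarray]],
    test_set: Sequence[tuple[str, np.ndarray, int]],
    config: PipelineConfig,
    *,
    similarity_kinds: Sequence[str] = ("euclidean", "manhattan", "cosine", "mahalanobis"),
    weight_vectors: Sequence[Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Single-resolution and multiresolution experiment grid.

    Encoders and the reference database are trained once; each grid row
    re-scores the test set under one (resolution | weight vector,
    similarity) combination.  Output mirrors the shape of the published
    comparison tables: one row per configuration with all five metrics.
    """
    import dataclasses

    labels = [lab for _, _, lab in test_set]
    test_images = [(i, img) for i, img, _ in test_set]
    encoders, db = train_pipeline(train_images, config)

    rows = []
    for kind in similarity_kinds:
        kind_config = dataclasses.replace(config, similarity=kind)
        calibration = calibrate_pipeline(encoders, db, val_normals, kind_config)
        results = score_images(test_images, encoders, db, calibration, kind_config)
        # single-resolution rows: the calibrated max of each per-size map
        for s in config.patch_sizes:
            metrics = evaluate_scores(
                labels, results[f"score_s{s}"].to_numpy(), config.threshold
            )
            rows.append({"mode": "single", "similarity": kind, "patch_size": s,
                         "weights": "", **metrics})
        # multiresolution rows under each weight vector
        for wv in (weight_vectors or [config.weights]):
            wv_config = dataclasses.replace(kind_config, weights=tuple(wv))
            wv_results = score_images(test_images, encoders, db, calibration, wv_config)
            metrics = evaluate_scores(labels, wv_results["score"].to_numpy(), config.threshold)
            rows.append({"mode": "multi", "similarity": kind, "patch_size": 0,
                         "weights": str(tuple(wv)), **metrics})
    return pd.DataFrame(rows)
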