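"""Similarity functions and the locality-constrained patch anomaly score.

A query patch is scored against the reference database as the distance to
its nearest normal reference within the Chebyshev neighborhood of its own
grid location.  All four similarity kinds are expressed as distances with a
common orientation — larger means more anomalous: Euclidean, Manhattan and
Mahalanobis are used as-is, and cosine similarity is mapped to the
dissimilarity ``1 - cos``.  Any strictly decreasing transform of a
similarity yields the same nearest reference and the same ranking of
images, so this distance form is the numerically stable realization of
"anomaly score = inverse similarity".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    ConfigurationError,
    InvalidInputError,
    UndefinedSimilarityError,
)
from .reference_db import CovarianceModel, LocalityConfig, ReferenceDB

__all__ = [
    "SimilarityKind",
    "PatchScore",
    "distance",
    "distances_to_references",
    "patch_anomaly_score",
    "score_patches",
    "export_patch_scores",
]


class SimilarityKind(str, Enum):
    EUCLIDEAN = "euclidean"
    MANHATTAN = "manhattan"
    COSINE = "cosine"
    MAHALANOBIS = "mahalanobis"


@dataclass(frozen=True)
class PatchScore:
    """Anomaly score of one query patch plus its best-matching reference."""

    size: int
    gx: int
    gy: int
    score: float
    best_ref_image_id: str
    best_ref_index: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.score) or self.score < 0:
            raise InvalidInputError("patch score must be finite and >= 0")


def _check_pair(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape or X.ndim != 1:
        raise InvalidInputError(f"feature vectors must be 1-D and equal length, got {X.shape} vs {Y.shape}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise InvalidInputError("non-finite feature values")
    return X, Y


def distance(
    X: np.ndarray,
    Y: np.ndarray,
    kind: SimilarityKind | str,
    cov: CovarianceModel | None = None,
) -> float:
    """Distance between two feature vectors under one similarity kind.

    ``cov`` is required for (and only for) Mahalanobis. Cosine returns the
    dissimilarity ``1 - cos(X, Y)`` and is undefined for zero vectors.
    """
    kind = SimilarityKind(kind)
    X, Y = _check_pair(X, Y)
    if kind is SimilarityKind.MAHALANOBIS:
        if cov is None:
            raise ConfigurationError("Mahalanobis distance requires a CovarianceModel")
    elif cov is not None:
        raise ConfigurationError(f"covariance model is only meaningful for mahalanobis, not {kind.value}")

    if kind is SimilarityKind.EUCLIDEAN:
        d = (X - Y)[None, :]
        # same reduction as the Mahalanobis quadratic form, so that
        # Mahalanobis with identity covariance coincides bit-for-bit
        return float(np.sqrt(np.maximum(np.sum(d * d, axis=1), 0.0))[0])
    if kind is SimilarityKind.MANHATTAN:
        return float(np.abs(X - Y).sum())
    if kind is SimilarityKind.COSINE:
        nx, ny = np.linalg.norm(X), np.linalg.norm(Y)
        if nx == 0 or ny == 0:
            raise UndefinedSimilarityError("cosine similarity undefined for zero vectors")
        # clip guards rounding outside [-1, 1]; identical vectors give exactly 0
        return float(1.0 - np.clip(np.dot(X, Y) / (nx * ny), -1.0, 1.0))
    return float(cov.mahalanobis((X - Y)[None, :])[0])


def distances_to_references(
    q: np.ndarray,
    H: np.ndarray,
    kind: SimilarityKind | str,
    cov: CovarianceModel | None = None,
) -> np.ndarray:
    """Vectorized distances from one query feature to each row of ``H``."""
    kind = SimilarityKind(kind)
    q = np.asarray(q, dtype=np.float64)
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    if H.shape[1] != q.shape[0]:
        raise InvalidInputError("query/reference dimension mismatch")
    diffs = H - q[None, :]
    if kind is SimilarityKind.EUCLIDEAN:
        return np.sqrt(np.maximum(np.sum(diffs * diffs, axis=1), 0.0))
    if kind is SimilarityKind.MANHATTAN:
        return np.abs(diffs).sum(axis=1)
    if kind is SimilarityKind.COSINE:
        nq = np.linalg.norm(q)
        nh = np.linalg.norm(H, axis=1)
        if nq == 0 or np.any(nh == 0):
            raise UndefinedSimilarityError("cosine similarity undefined for zero vectors")
        return 1.0 - np.clip(H @ q / (nh * nq), -1.0, 1.0)
    if cov is None:
        raise ConfigurationError("Mahalanobis distance requires a CovarianceModel")
    return cov.mahalanobis(diffs)


def patch_anomaly_score(
    q: np.ndarray,
    size: int,
    gx: int,
    gy: int,
    db: ReferenceDB,
    kind: SimilarityKind | str,
    locality: LocalityConfig,
) -> PatchScore:
    """Nearest-reference anomaly score of one query patch.

    The minimum distance over all reference records within Chebyshev radius
    ``d(size)`` of (gx, gy).  Ties keep the earliest record in insertion
    order, so results are reproducible.
    """
    kind = SimilarityKind(kind)
    d = locality.d(size)
    idx = db.neighborhood_indices(size, gx, gy, d)
    if len(idx) == 0:
        raise ConfigurationError(
            f"empty reference neighborhood at size={size}, ({gx},{gy}), d={d}"
        )
    cov = db.covariance.get(size) if kind is SimilarityKind.MAHALANOBIS else None
    if kind is SimilarityKind.MAHALANOBIS and cov is None:
        raise ConfigurationError(f"no covariance model fitted for size {size}")
    H = db.features(size)[idx]
    dists = distances_to_references(q, H, kind, cov)
    best = int(np.argmin(dists))  # argmin keeps the first minimum -> deterministic
    store_idx = int(idx[best])
    image_id = db._consolidated(size)["image_ids"][store_idx]
    return PatchScore(
        size=size,
        gx=gx,
        gy=gy,
        score=float(max(dists[best], 0.0)),
        best_ref_image_id=image_id,
        best_ref_index=store_idx,
    )


def score_patches(
    features: np.ndarray,
    coords: Sequence[tuple[int, int]],
    size: int,
    db: ReferenceDB,
    kind: SimilarityKind | str,
    locality: LocalityConfig,
) -> list[PatchScore]:
    """Score every patch of one image at one resolution.

    ``features`` rows correspond to ``coords`` (gx, gy) pairs in row-major
    tiling order.
    """
    features = np.atleast_2d(features)
    if features.shape[0] != len(coords):
        raise InvalidInputError("one feature row per coordinate required")
    return [
        patch_anomaly_score(features[i], size, gx, gy, db, kind, locality)
        for i, (gx, gy) in enumerate(coords)
    ]


def export_patch_scores(scores: Sequence[PatchScore], path: str | Path) -> None:
    """Write per-patch scores as CSV (size, gx, gy, score, best reference)."""
    import pandas as pd

    pd.DataFrame(
        {
            "size": [s.size for s in scores],
            "gx": [s.gx for s in scores],
            "gy": [s.gy for s in scores],
            "score": [s.score for s in scores],
            "best_ref_image_id": [s.best_ref_image_id for s in scores],
        }
    ).to_csv(Path(path), index=False)
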