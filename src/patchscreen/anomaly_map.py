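"""Per-resolution anomaly maps, multiresolution fusion, and the image decision.

Each resolution produces a full-size map that is piecewise-constant on its
patch grid (every pixel carries the anomaly score of its unique covering
patch).  Raw nearest-reference distances live on a different scale at each
resolution, so before fusion each map is rescaled by calibration quantiles
estimated from patch scores on *normal validation images* — not per image,
which would destroy the cross-image comparability the fixed decision
threshold relies on.

Fusion multiplies the calibrated maps element-wise with per-resolution
weights.  The default ``geometric`` mode treats weights as exponents and
normalizes by the exponent sum (a weighted geometric mean), which keeps the
fused map in [0, 1], reduces to the plain element-wise product with k-th
root when all weights are 1, and makes the weights genuinely
ranking-relevant.  The ``literal`` mode multiplies each map by its scalar
weight before the product, for fidelity experiments; under any global
rescaling those scalars cancel, which is why it is not the default.

The image-level anomaly score is the maximum pixel of the fused map; an
image is called abnormal when that score strictly exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError
from .patch_grid import PatchSpec, resize_image, tile_image
from .reference_db import LocalityConfig, ReferenceDB
from .scoring import SimilarityKind, score_patches
from .ssl_encoder import EncoderState, embed_batch

__all__ = [
    "AnomalyMap",
    "FusionWeights",
    "Calibration",
    "fit_calibration",
    "resolution_map",
    "fuse",
    "image_score",
    "classify",
]

#: Floor applied to calibrated scores before multiplicative fusion, so that a
#: perfectly matched resolution cannot annihilate anomalies seen at others.
FUSION_EPS = 1e-6


@dataclass
class AnomalyMap:
    """A full-resolution per-pixel anomaly score array."""

    values: np.ndarray = field(repr=False)
    source: str = "fused"  # patch size as a string, or "fused"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise InvalidInputError("anomaly map must be 2-D")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise InvalidInputError("anomaly map entries must be finite and >= 0")
        self.values = v


@dataclass(frozen=True)
class FusionWeights:
    """Per-resolution fusion weights and the fusion mode."""

    weights: Mapping[int, float]
    mode: str = "geometric"

    def __post_init__(self) -> None:
        if self.mode not in ("geometric", "literal"):
            raise ConfigurationError(f"unknown fusion mode {self.mode!r}")
        w = dict(self.weights)
        if any(v < 0 for v in w.values()):
            raise ConfigurationError("fusion weights must be >= 0")
        if not any(v > 0 for v in w.values()):
            raise ConfigurationError("at least one fusion weight must be > 0")


@dataclass
class Calibration:
    """Reference scale statistics and the decision threshold.

    ``quantiles`` maps each patch size to (lo, hi) — by default the 1st and
    99th percentiles of patch anomaly scores over normal validation images.
    A calibrated score is ``clip((raw - lo) / (hi - lo), 0, 1)``.
    """

    quantiles: Mapping[int, tuple[float, float]]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ConfigurationError("threshold must lie in (0, 1)")

    def rescale(self, values: np.ndarray, size: int) -> np.ndarray:
        try:
            lo, hi = self.quantiles[size]
        except KeyError as exc:
            raise ConfigurationError(f"no calibration for patch size {size}") from exc
        span = hi - lo
        if span <= 0:
            span = 1.0  # degenerate normal-score distribution
        return np.clip((np.asarray(values, dtype=np.float64) - lo) / span, 0.0, 1.0)


def fit_calibration(
    normal_scores_per_size: Mapping[int, np.ndarray],
    *,
    q_lo: float = 0.01,
    q_hi: float = 0.99,
    threshold: float = 0.5,
) -> Calibration:
    """Estimate per-resolution scale quantiles from normal-image patch scores."""
    quantiles = {}
    for size, scores in normal_scores_per_size.items():
        scores = np.asarray(scores, dtype=np.float64)
        if scores.size == 0:
            raise InvalidInputError(f"no calibration scores for size {size}")
        quantiles[size] = (
            float(np.quantile(scores, q_lo)),
            float(np.quantile(scores, q_hi)),
        )
    return Calibration(quantiles=quantiles, threshold=threshold)


def resolution_map(
    image: np.ndarray,
    encoder: EncoderState,
    db: ReferenceDB,
    size: int,
    kind: SimilarityKind | str,
    locality: LocalityConfig,
) -> AnomalyMap:
    """Raw anomaly map of one image at one patch resolution.

    Every pixel carries the nearest-reference distance of its covering
    patch, so the map is piecewise-constant on the size-``s`` grid.
    """
    if encoder.patch_size != size:
        raise ConfigurationError("encoder patch size does not match requested size")
    side = db.provenance.get("image_side", np.asarray(image).shape[0])
    image = resize_image(np.asarray(image), side)
    spec = PatchSpec(size_px=size, image_side_px=side)
    patches = tile_image(image, spec)
    H = embed_batch(patches, encoder)
    scores = score_patches(
        H, [(p.gx, p.gy) for p in patches], size, db, kind, locality
    )
    out = np.empty((side, side), dtype=np.float64)
    for p, sc in zip(patches, scores):
        r0, r1, c0, c1 = p.bounds
        out[r0:r1, c0:c1] = sc.score
    return AnomalyMap(values=out, source=str(size))


def fuse(
    maps: Sequence[AnomalyMap],
    weights: FusionWeights,
    calibration: Calibration,
) -> AnomalyMap:
    """Weighted element-wise fusion of per-resolution maps into A_final.

    Maps are calibrated to [0, 1], floored at :data:`FUSION_EPS`, combined
    multiplicatively, and renormalized so the result stays in [0, 1].  Maps
    are processed in ascending patch-size order, so the result is invariant
    to the order in which they are passed.
    """
    if not maps:
        raise InvalidInputError("no maps to fuse")
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise InvalidInputError("all maps must share pixel dimensions")
    sizes = []
    for m in maps:
        try:
            sizes.append(int(m.source))
        except ValueError as exc:
            raise InvalidInputError("fuse expects per-resolution maps, not fused ones") from exc
    if len(set(sizes)) != len(sizes):
        raise InvalidInputError("duplicate patch size among maps")
    order = np.argsort(sizes)

    w = dict(weights.weights)
    for s in sizes:
        if s not in w:
            raise ConfigurationError(f"no fusion weight for patch size {s}")

    if weights.mode == "geometric":
        # accumulate in sorted-size order so fusion is bit-exactly
        # independent of the order the maps were passed in
        w_total = sum(w[s] for s in sorted(sizes))
        if w_total <= 0:
            raise ConfigurationError("sum of fusion weights must be > 0")
        log_acc = np.zeros(shape)
        for i in order:
            a = np.maximum(calibration.rescale(maps[i].values, sizes[i]), FUSION_EPS)
            log_acc = log_acc + (w[sizes[i]] / w_total) * np.log(a)
        fused = np.exp(log_acc)
    else:  # literal scalar weighting, k-th root renormalization
        k = len(maps)
        log_acc = np.zeros(shape)
        for i in order:
            a = np.maximum(calibration.rescale(maps[i].values, sizes[i]), FUSION_EPS)
            log_acc = log_acc + np.log(w[sizes[i]] * a)
        fused = np.clip(np.exp(log_acc / k), 0.0, 1.0)
    return AnomalyMap(values=np.clip(fused, 0.0, 1.0), source="fused")


def image_score(a_final: AnomalyMap) -> float:
    """Image-level anomaly score: the maximum pixel of the fused map."""
    return float(np.max(a_final.values))


def classify(score: float, calibration: Calibration) -> str:
    """'abnormal' iff the image score strictly exceeds the threshold."""
    if not (0 <= score <= 1):
        raise InvalidInputError("image score must lie in [0, 1]")
    return "abnormal" if score > calibration.threshold else "normal"
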