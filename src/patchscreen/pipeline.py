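"""End-to-end orchestration: train encoders, build the reference DB,
calibrate, and score images.

This module owns :class:`PipelineConfig`, the single structure that keeps
all stage parameters mutually consistent (patch sizes divide the image
side, every size has a locality radius and a fusion weight, one SSL config
per size).  Defaults are the desk-scale profile: 128² images with patch
sizes {16, 32, 64, 128}, Mahalanobis similarity, fusion weights
(0.1, 1.2, 1.2, 1.0) from the smallest to the largest patch, and decision
threshold 0.5.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .anomaly_map import (
    Calibration,
    FusionWeights,
    classify,
    fit_calibration,
    fuse,
    image_score,
    resolution_map,
)
from .exceptions import ConfigurationError, InvalidInputError
from .patch_grid import PatchSpec, resize_image, tile_image
from .reference_db import (
    LocalityConfig,
    ReferenceDB,
    build_reference,
    default_locality,
)
from .scoring import SimilarityKind, score_patches
from .ssl_encoder import EncoderState, SSLConfig, embed_batch, train_encoder

__all__ = [
    "PipelineConfig",
    "train_pipeline",
    "calibrate_pipeline",
    "score_image",
    "score_images",
]

#: Per-resolution fusion weights of the best-performing published setting,
#: listed from the smallest patch size to the largest.
DEFAULT_WEIGHTS = (0.1, 1.2, 1.2, 1.0)


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of the multiresolution screening pipeline."""

    image_side: int = 128
    patch_sizes: tuple[int, ...] = (16, 32, 64, 128)
    similarity: str = "mahalanobis"
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    fusion_mode: str = "geometric"
    threshold: float = 0.5
    shrinkage: float = 0.1
    locality: Mapping[int, int] | None = None
    ssl: SSLConfig = field(default_factory=SSLConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.patch_sizes) == 0:
            raise ConfigurationError("at least one patch size required")
        for s in self.patch_sizes:
            if self.image_side % s != 0:
                raise ConfigurationError(
                    f"patch size {s} does not divide image side {self.image_side}"
                )
        if len(self.weights) != len(self.patch_sizes):
            raise ConfigurationError("one fusion weight per patch size required")
        SimilarityKind(self.similarity)
        if self.locality is not None:
            missing = [s for s in self.patch_sizes if s not in self.locality]
            if missing:
                raise ConfigurationError(f"no locality radius for sizes {missing}")

    # -- derived views ----------------------------------------------------

    @property
    def specs(self) -> list[PatchSpec]:
        return [PatchSpec(size_px=s, image_side_px=self.image_side) for s in self.patch_sizes]

    @property
    def locality_config(self) -> LocalityConfig:
        if self.locality is not None:
            return LocalityConfig(d_per_size=dict(self.locality))
        return default_locality(self.patch_sizes, self.image_side)

    @property
    def fusion_weights(self) -> FusionWeights:
        ordered = sorted(self.patch_sizes)
        w = dict(zip(sorted(self.patch_sizes), [self.weights[self.patch_sizes.index(s)] for s in ordered]))
        return FusionWeights(weights=w, mode=self.fusion_mode)

    def ssl_for_size(self, size: int) -> SSLConfig:
        """Per-size SSL config: same hyper-parameters, decorrelated seed."""
        return replace(self.ssl, seed=int((self.seed * 100003 + size) % (2 ** 31 - 1)))

    # -- (de)serialization -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["patch_sizes"] = list(self.patch_sizes)
        doc["weights"] = list(self.weights)
        if self.locality is not None:
            doc["locality"] = {int(k): int(v) for k, v in self.locality.items()}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        ssl = SSLConfig(**doc.pop("ssl", {}))
        doc["patch_sizes"] = tuple(doc.get("patch_sizes", cls.patch_sizes))
        doc["weights"] = tuple(doc.get("weights", cls.weights))
        if doc.get("locality") is not None:
            doc["locality"] = {int(k): int(v) for k, v in doc["locality"].items()}
        return cls(ssl=ssl, **doc)


def train_pipeline(
    train_images: Sequence[tuple[str, np.ndarray]],
    config: PipelineConfig,
) -> tuple[dict[int, EncoderState], ReferenceDB]:
    """Train one encoder per patch size on normal images and build the DB."""
    if len(train_images) == 0:
        raise InvalidInputError("no training images")
    resized = [
        (image_id, resize_image(np.asarray(img), config.image_side))
        for image_id, img in train_images
    ]
    encoders: dict[int, EncoderState] = {}
    for spec in config.specs:
        patches = []
        for _, img in resized:
            patches.extend(tile_image(img, spec))
        encoders[spec.size_px] = train_encoder(patches, config.ssl_for_size(spec.size_px))
    db = build_reference(resized, encoders, config.specs, shrinkage=config.shrinkage)
    return encoders, db


def calibrate_pipeline(
    encoders: Mapping[int, EncoderState],
    db: ReferenceDB,
    val_normal_images: Sequence[tuple[str, np.ndarray]],
    config: PipelineConfig,
) -> Calibration:
    """Fit per-resolution score quantiles on held-out normal images."""
    if len(val_normal_images) == 0:
        raise InvalidInputError("no validation normals to calibrate on")
    locality = config.locality_config
    per_size: dict[int, list[float]] = {s: [] for s in config.patch_sizes}
    for _, img in val_normal_images:
        img = resize_image(np.asarray(img), config.image_side)
        for spec in config.specs:
            patches = tile_image(img, spec)
            H = embed_batch(patches, encoders[spec.size_px])
            scores = score_patches(
                H, [(p.gx, p.gy) for p in patches], spec.size_px, db,
                config.similarity, locality,
            )
            per_size[spec.size_px].extend(s.score for s in scores)
    return fit_calibration(
        {s: np.asarray(v) for s, v in per_size.items()}, threshold=config.threshold
    )


def score_image(
    image: np.ndarray,
    encoders: Mapping[int, EncoderState],
    db: ReferenceDB,
    calibration: Calibration,
    config: PipelineConfig,
    *,
    return_maps: bool = False,
):
    """Score one image: fused score, decision, and per-resolution max scores.

    Per-resolution scores are the calibrated maxima of the single-size maps
    (what a single-resolution variant of the method would report).
    """
    locality = config.locality_config
    maps = [
        resolution_map(image, encoders[s], db, s, config.similarity, locality)
        for s in config.patch_sizes
    ]
    fused = fuse(maps, config.fusion_weights, calibration)
    score = image_score(fused)
    record = {
        "score": score,
        "decision": classify(score, calibration),
    }
    for m, s in zip(maps, config.patch_sizes):
        record[f"score_s{s}"] = float(np.max(calibration.rescale(m.values, s)))
    if return_maps:
        return record, maps, fused
    return record


def score_images(
    images: Sequence[tuple[str, np.ndarray]],
    encoders: Mapping[int, EncoderState],
    db: ReferenceDB,
    calibration: Calibration,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Score a batch of images into a results table (one row per image)."""
    rows = []
    for image_id, img in images:
        rec = score_image(img, encoders, db, calibration, config)
        rec["image_id"] = image_id
        rows.append(rec)
    df = pd.DataFrame(rows)
    if rows:
        ordered = ["image_id", "score", "decision"] + [
            c for c in df.columns if c.startswith("score_s")
        ]
        df = df[ordered]
    return df
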