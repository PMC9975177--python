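"""Reference database of normal-patch embeddings.

After contrastive training, every patch of every normal training image is
embedded and stored as an n-tuple (patch size, grid x, grid y, image id,
feature vector h).  At query time only records whose grid location lies
within a Chebyshev radius ``d`` of the query location are searched — the
locality constraint that keeps comparisons anatomically plausible (patch
content at a given location varies between subjects, but not arbitrarily)
while bounding the search cost.  A pooled per-resolution covariance model
of the reference features supports Mahalanobis scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .exceptions import ConfigurationError, InvalidInputError
from .patch_grid import PatchSpec, resize_image, tile_image
from .ssl_encoder import EncoderState, embed_batch

__all__ = [
    "EmbeddingRecord",
    "CovarianceModel",
    "LocalityConfig",
    "ReferenceDB",
    "build_reference",
    "neighborhood",
    "fit_covariance",
    "default_locality",
]


@dataclass(frozen=True)
class EmbeddingRecord:
    """One stored normal-patch embedding."""

    patch_size: int
    gx: int
    gy: int
    image_id: str
    h: np.ndarray = field(repr=False)


@dataclass
class CovarianceModel:
    """Shrinkage-regularized sample covariance of one resolution's features.

    ``S`` is the raw sample covariance (n-1 denominator) pooled over all grid
    locations and training images of one patch size; the regularized matrix
    ``(1-shrinkage) * S + shrinkage * mean_var * I`` is what Mahalanobis
    distances are computed against (it is symmetric positive definite even
    when the feature dimension exceeds the record count).
    """

    S: np.ndarray
    shrinkage: float
    S_reg: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _chol: tuple = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=np.float64)
        if not np.all(np.isfinite(S)):
            raise InvalidInputError("covariance contains non-finite entries")
        if not (0 <= self.shrinkage <= 1):
            raise InvalidInputError("shrinkage must be in [0, 1]")
        if self.S_reg is None:
            mean_var = float(np.trace(S)) / S.shape[0]
            if mean_var <= 0:
                mean_var = 1.0  # degenerate all-zero features; keep PD
            self.S_reg = (1.0 - self.shrinkage) * S + self.shrinkage * mean_var * np.eye(
                S.shape[0]
            )
        try:
            self._chol = cho_factor(self.S_reg, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by shrinkage
            raise InvalidInputError("regularized covariance is not positive definite") from exc

    def whiten_solve(self, diffs: np.ndarray) -> np.ndarray:
        """Return S_reg^{-1} @ diffs.T for a (n, dim) array of differences."""
        return cho_solve(self._chol, diffs.T)

    def mahalanobis(self, diffs: np.ndarray) -> np.ndarray:
        """Mahalanobis lengths of the rows of ``diffs``."""
        diffs = np.atleast_2d(np.asarray(diffs, dtype=np.float64))
        sol = self.whiten_solve(diffs)
        return np.sqrt(np.maximum(np.sum(diffs * sol.T, axis=1), 0.0))


def fit_covariance(features: np.ndarray, shrinkage: float = 0.1) -> CovarianceModel:
    """Fit the pooled covariance model for one patch size.

    Requires at least two records; uses the unbiased (n-1) sample covariance.
    """
    H = np.asarray(features, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 2:
        raise InvalidInputError("need at least 2 feature vectors to fit a covariance")
    if not np.all(np.isfinite(H)):
        raise InvalidInputError("non-finite feature values")
    S = np.cov(H, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    return CovarianceModel(S=S, shrinkage=shrinkage)


@dataclass(frozen=True)
class LocalityConfig:
    """Per-resolution Chebyshev search radius ``d`` on the patch grid."""

    d_per_size: Mapping[int, int]

    def __post_init__(self) -> None:
        for size, d in self.d_per_size.items():
            if d < 0:
                raise ConfigurationError(f"patch distance for size {size} must be >= 0")

    def d(self, size: int) -> int:
        try:
            return self.d_per_size[size]
        except KeyError as exc:
            raise ConfigurationError(f"no patch distance configured for size {size}") from exc


def default_locality(sizes: Sequence[int], image_side: int) -> LocalityConfig:
    """Map grid dimension to search radius the way the reference setup does:
    an 8x8 grid gets d=2, a 4x4 grid d=1, coarser grids d=0."""
    d = {}
    for s in sizes:
        g = image_side // s
        d[s] = 2 if g >= 8 else (1 if g >= 4 else 0)
    return LocalityConfig(d_per_size=d)


class ReferenceDB:
    """Per-resolution store of normal-patch embeddings.

    Internally each patch size keeps column arrays (gx, gy, image id index,
    feature matrix) in insertion order, which doubles as the deterministic
    tie-break order for nearest-reference queries.
    """

    def __init__(self) -> None:
        self._sizes: dict[int, dict] = {}
        self.covariance: dict[int, CovarianceModel] = {}
        self.provenance: dict = {}

    # -- construction -----------------------------------------------------

    def add_records(
        self,
        patch_size: int,
        gx: np.ndarray,
        gy: np.ndarray,
        image_ids: Sequence[str],
        H: np.ndarray,
    ) -> None:
        H = np.asarray(H, dtype=np.float64)
        gx = np.asarray(gx, dtype=np.int64)
        gy = np.asarray(gy, dtype=np.int64)
        if not (len(gx) == len(gy) == len(image_ids) == H.shape[0]):
            raise InvalidInputError("record column lengths disagree")
        store = self._sizes.setdefault(
            patch_size,
            {"gx": [], "gy": [], "image_ids": [], "H": []},
        )
        store["gx"].append(gx)
        store["gy"].append(gy)
        store["image_ids"].extend(list(image_ids))
        store["H"].append(H)

    def _consolidated(self, patch_size: int) -> dict:
        if patch_size not in self._sizes:
            raise ConfigurationError(f"no records for patch size {patch_size}")
        store = self._sizes[patch_size]
        if isinstance(store["H"], list):
            store["gx"] = np.concatenate(store["gx"]) if store["gx"] else np.empty(0, int)
            store["gy"] = np.concatenate(store["gy"]) if store["gy"] else np.empty(0, int)
            store["H"] = np.vstack(store["H"]) if store["H"] else np.empty((0, 0))
        return store

    # -- introspection ----------------------------------------------------

    @property
    def sizes(self) -> list[int]:
        return sorted(self._sizes)

    def n_records(self, patch_size: int | None = None) -> int:
        if patch_size is not None:
            return len(self._consolidated(patch_size)["image_ids"])
        return sum(self.n_records(s) for s in self._sizes)

    def features(self, patch_size: int) -> np.ndarray:
        return self._consolidated(patch_size)["H"]

    def records(self, patch_size: int) -> list[EmbeddingRecord]:
        store = self._consolidated(patch_size)
        return [
            EmbeddingRecord(
                patch_size=patch_size,
                gx=int(store["gx"][i]),
                gy=int(store["gy"][i]),
                image_id=store["image_ids"][i],
                h=store["H"][i],
            )
            for i in range(len(store["image_ids"]))
        ]

    def grid_dim(self, patch_size: int) -> int:
        store = self._consolidated(patch_size)
        return int(max(store["gx"].max(), store["gy"].max())) + 1 if len(store["gx"]) else 0

    # -- querying ---------------------------------------------------------

    def neighborhood_indices(self, patch_size: int, gx: int, gy: int, d: int) -> np.ndarray:
        """Indices (insertion order) of records within Chebyshev radius d."""
        store = self._consolidated(patch_size)
        g = self.grid_dim(patch_size)
        if not (0 <= gx < g and 0 <= gy < g):
            raise InvalidInputError(f"grid location ({gx}, {gy}) outside {g}x{g} grid")
        mask = (np.abs(store["gx"] - gx) <= d) & (np.abs(store["gy"] - gy) <= d)
        return np.flatnonzero(mask)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist as one ``.npz`` container plus a JSON manifest next to it."""
        path = Path(path)
        payload: dict[str, np.ndarray] = {}
        manifest: dict = {"sizes": [], "provenance": self.provenance}
        for size in self.sizes:
            store = self._consolidated(size)
            payload[f"gx_{size}"] = store["gx"]
            payload[f"gy_{size}"] = store["gy"]
            payload[f"H_{size}"] = store["H"]
            payload[f"ids_{size}"] = np.array(store["image_ids"], dtype="U")
            entry = {"size": size, "n_records": len(store["image_ids"])}
            if size in self.covariance:
                cov = self.covariance[size]
                payload[f"cov_{size}"] = cov.S
                entry["shrinkage"] = cov.shrinkage
            manifest["sizes"].append(entry)
        np.savez(path, **payload)
        manifest_path = path.with_suffix(path.suffix + ".manifest.json")
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceDB":
        path = Path(path)
        manifest = json.loads(path.with_suffix(path.suffix + ".manifest.json").read_text())
        db = cls()
        db.provenance = manifest.get("provenance", {})
        with np.load(path) as data:
            for entry in manifest["sizes"]:
                size = int(entry["size"])
                db.add_records(
                    size,
                    data[f"gx_{size}"],
                    data[f"gy_{size}"],
                    [str(x) for x in data[f"ids_{size}"]],
                    data[f"H_{size}"],
                )
                if f"cov_{size}" in data.files:
                    db.covariance[size] = CovarianceModel(
                        S=data[f"cov_{size}"], shrinkage=float(entry["shrinkage"])
                    )
        return db


def neighborhood(
    db: ReferenceDB, size: int, gx: int, gy: int, d: int
) -> list[EmbeddingRecord]:
    """All records whose grid location is within Chebyshev distance ``d``
    of (gx, gy); clipped at the grid border, d=0 is the same location only."""
    idx = db.neighborhood_indices(size, gx, gy, d)
    records = db.records(size)
    return [records[i] for i in idx]


def build_reference(
    normal_images: Iterable[tuple[str, np.ndarray]],
    encoders: Mapping[int, EncoderState],
    specs: Sequence[PatchSpec],
    *,
    shrinkage: float = 0.1,
) -> ReferenceDB:
    """Embed every patch of every normal image and assemble the database.

    One record per (image, size, grid cell); a pooled covariance model is
    fitted per patch size over all of that size's records.
    """
    specs = list(specs)
    for spec in specs:
        if spec.size_px not in encoders:
            raise ConfigurationError(f"no encoder for patch size {spec.size_px}")
    db = ReferenceDB()
    n_images = 0
    for image_id, image in normal_images:
        n_images += 1
        image = resize_image(np.asarray(image), specs[0].image_side_px)
        for spec in specs:
            patches = tile_image(image, spec)
            H = embed_batch(patches, encoders[spec.size_px])
            db.add_records(
                spec.size_px,
                np.array([p.gx for p in patches]),
                np.array([p.gy for p in patches]),
                [image_id] * len(patches),
                H,
            )
    if n_images == 0:
        raise InvalidInputError("empty normal-image list")
    for spec in specs:
        H = db.features(spec.size_px)
        if H.shape[0] >= 2:
            db.covariance[spec.size_px] = fit_covariance(H, shrinkage=shrinkage)
    db.provenance = {
        "n_images": n_images,
        "sizes": [s.size_px for s in specs],
        "image_side": specs[0].image_side_px,
        "shrinkage": shrinkage,
        "encoder_checksums": {s: encoders[s].checksum() for s in encoders},
    }
    return db
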