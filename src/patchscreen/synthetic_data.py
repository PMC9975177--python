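"""Phantom radiograph generator with controlled, ground-truthed anomalies.

The generator emulates the gross structure of a frontal chest radiograph —
a bright body ellipse on a dark background, two darker lung fields, faint
periodic rib banding, mild per-image geometric jitter and additive Gaussian
pixel noise — at a configurable (small) resolution.  It is deliberately
geometric rather than photorealistic: the point is to exercise every stage
of the detection pipeline with checkable ground truth, not to imitate
pathology.

Anomalies are injected inside the body region as smooth-edged bright or
dark blobs (truncated Gaussian intensity profile) or as a local geometric
deformation, with the nominal disc returned as a binary ground-truth mask.
Diameters are sampled across a range spanning several patch resolutions so
multiresolution behavior is genuinely exercised.

Datasets are laid out on disk the way the detection task expects them:
a normal-only training split and balanced labeled validation/test splits,
with a manifest CSV recording the per-image seed and anomaly parameters so
any dataset can be regenerated bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter, map_coordinates

from .exceptions import InvalidInputError
from .patch_grid import load_image, save_image

__all__ = [
    "PhantomConfig",
    "AnomalySpec",
    "generate_normal",
    "inject_anomaly",
    "make_dataset",
    "load_manifest",
    "load_split",
]

#: Intensities are generated on a [0, 1] scale and written as 16-bit PNG.
WHITE_LEVEL = 65535.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise of the normal phantom population.

    Positions and axes are fractions of the image side; ``jitter`` is the
    half-width of the uniform per-image perturbation applied to them.
    """

    side: int = 128
    background: float = 0.08
    body_level: float = 0.55
    body_center: tuple[float, float] = (0.50, 0.52)
    body_axes: tuple[float, float] = (0.38, 0.44)
    lung_level: float = 0.30
    lung_offset_x: float = 0.16
    lung_center_y: float = 0.45
    lung_axes: tuple[float, float] = (0.12, 0.24)
    rib_period_px: float = 14.0
    rib_amplitude: float = 0.05
    noise_sigma: float = 0.01
    jitter: float = 0.02
    smooth_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side < 8:
            raise InvalidInputError("phantom side must be >= 8")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise sigma must be >= 0")


@dataclass(frozen=True)
class AnomalySpec:
    """Parameters of the injected-anomaly population."""

    kind: str = "bright-blob"  # bright-blob | dark-blob | shape-deformation
    diameter_range: tuple[float, float] = (8.0, 48.0)
    contrast_range: tuple[float, float] = (0.15, 0.45)
    count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("bright-blob", "dark-blob", "shape-deformation"):
            raise InvalidInputError(f"unknown anomaly kind {self.kind!r}")
        if self.diameter_range[0] < 2:
            raise InvalidInputError("minimum anomaly diameter is 2 px")
        if self.contrast_range[0] <= 0:
            raise InvalidInputError("contrast must be non-zero (magnitude > 0)")
        if self.count < 1:
            raise InvalidInputError("count must be >= 1")


def _ellipse_mask(side: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    return ((xx - cx * side) / (ax * side)) ** 2 + ((yy - cy * side) / (ay * side)) ** 2 <= 1.0


def generate_normal(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """One normal phantom on a [0, 1] intensity scale; deterministic under rng."""
    side = config.side
    j = lambda: float(rng.uniform(-config.jitter, config.jitter))  # noqa: E731

    bcx, bcy = config.body_center[0] + j(), config.body_center[1] + j()
    bax, bay = config.body_axes[0] + j(), config.body_axes[1] + j()
    lcy = config.lung_center_y + j()
    lox = config.lung_offset_x + j() * 0.5
    lax, lay = config.lung_axes[0] + j() * 0.5, config.lung_axes[1] + j() * 0.5
    phase = float(rng.uniform(0, 2 * np.pi))

    body = _ellipse_mask(side, bcx, bcy, bax, bay)
    lung_l = _ellipse_mask(side, bcx - lox, lcy, lax, lay)
    lung_r = _ellipse_mask(side, bcx + lox, lcy, lax, lay)
    lungs = lung_l | lung_r
    if np.any(lungs & ~body):
        raise InvalidInputError("invalid phantom geometry: lung field outside body")

    img = np.full((side, side), config.background, dtype=np.float64)
    img[body] = config.body_level
    img[lungs] = config.lung_level

    # periodic rib banding inside the lung fields
    yy = np.arange(side, dtype=np.float64)[:, None]
    ribs = config.rib_amplitude * np.sin(2 * np.pi * yy / config.rib_period_px + phase)
    img = np.where(lungs, img + ribs, img)

    img = gaussian_filter(img, sigma=config.smooth_sigma)
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _body_mask(image: np.ndarray, background: float) -> np.ndarray:
    smoothed = gaussian_filter(image, sigma=2.0)
    return smoothed > background + 0.1


def _truncated_gaussian(side: int, cx: int, cy: int, radius: float) -> np.ndarray:
    """Smooth radial profile supported on r < 2*radius, 1 at the center."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    sigma2 = (radius / 2.0) ** 2
    g = np.exp(-r2 / (2.0 * sigma2))
    g_edge = np.exp(-(2.0 * radius) ** 2 / (2.0 * sigma2))
    return np.maximum((g - g_edge) / (1.0 - g_edge), 0.0)


def inject_anomaly(
    image: np.ndarray,
    spec: AnomalySpec,
    rng: np.random.Generator,
    *,
    background: float = PhantomConfig.background,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Inject ``spec.count`` anomalies; returns (image', mask, parameters).

    The binary mask is the union of the nominal discs (radius = diameter/2);
    intensity edits have a smooth truncated-Gaussian profile whose support
    is confined to twice the nominal radius, so the changed-pixel set is a
    bounded neighborhood of the mask.
    """
    img = np.asarray(image, dtype=np.float64).copy()
    side = img.shape[0]
    mask = np.zeros(img.shape, dtype=bool)
    body = _body_mask(img, background)
    params: list[dict] = []

    for _ in range(spec.count):
        diameter = float(rng.uniform(*spec.diameter_range))
        contrast = float(rng.uniform(*spec.contrast_range))
        radius = diameter / 2.0
        margin = int(np.ceil(radius)) + 1
        allowed = binary_erosion(body, iterations=margin) if margin > 0 else body
        centers = np.flatnonzero(allowed)
        if centers.size == 0:
            raise InvalidInputError(
                f"anomaly of diameter {diameter:.1f} px does not fit inside the body region"
            )
        flat = int(centers[rng.integers(0, centers.size)])
        cy, cx = divmod(flat, side)

        profile = _truncated_gaussian(side, cx, cy, radius)
        if spec.kind == "bright-blob":
            img = img + contrast * profile
        elif spec.kind == "dark-blob":
            img = img - contrast * profile
        else:  # shape-deformation: push pixels radially outward under the bump
            yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
            dx, dy = xx - cx, yy - cy
            r = np.hypot(dx, dy) + 1e-9
            disp = contrast * radius * profile
            coords = np.array([yy - disp * dy / r, xx - disp * dx / r])
            img = map_coordinates(img, coords, order=1, mode="nearest")
        img = np.clip(img, 0.0, 1.0)

        yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
        params.append(
            {"kind": spec.kind, "diameter": diameter, "contrast": contrast, "cx": cx, "cy": cy}
        )
    return img, mask, params


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _mixed_kind_spec(spec: AnomalySpec, rng: np.random.Generator) -> AnomalySpec:
    """Sample an anomaly kind for one image (blobs dominate, both signs)."""
    kind = ["bright-blob", "dark-blob", "shape-deformation"][int(rng.integers(0, 3))]
    return AnomalySpec(
        kind=kind,
        diameter_range=spec.diameter_range,
        contrast_range=spec.contrast_range,
        count=spec.count,
    )


def make_dataset(
    root: str | Path,
    n_normal_train: int,
    n_val_pairs: int,
    n_test_pairs: int,
    phantom: PhantomConfig = PhantomConfig(),
    anomaly: AnomalySpec = AnomalySpec(),
    seed: int = 0,
    mixed_kinds: bool = False,
) -> pd.DataFrame:
    """Generate a dataset tree and its manifest.

    Layout: ``train/`` holds normals only; ``val/`` and ``test/`` each hold
    balanced normal/abnormal images, with ground-truth masks for the
    abnormal ones under ``masks/``.  The manifest records per-image seeds
    and anomaly parameters; regenerating from those seeds is bit-identical.

    Abnormal images follow the single anomaly population described by
    ``anomaly`` (its diameter range spans several patch resolutions);
    ``mixed_kinds=True`` instead draws each image's kind uniformly from the
    three supported kinds, keeping the diameter/contrast ranges.
    """
    if min(n_normal_train, n_val_pairs, n_test_pairs) < 1:
        raise InvalidInputError("all split counts must be >= 1")
    root = Path(root)
    for sub in ("train", "val", "test", "masks"):
        (root / sub).mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(seed)
    rows: list[dict] = []

    def emit(split: str, label: int, index: int) -> None:
        image_seed = int(master.integers(0, 2 ** 31 - 1))
        rng = np.random.default_rng(image_seed)
        img = generate_normal(phantom, rng)
        name = f"{split}_{'abn' if label else 'nrm'}_{index:04d}.png"
        row = {
            "filename": f"{split}/{name}",
            "split": split,
            "label": label,
            "image_seed": image_seed,
            "kind": "",
            "diameter": np.nan,
            "contrast": np.nan,
            "cx": -1,
            "cy": -1,
        }
        if label:
            spec_i = _mixed_kind_spec(anomaly, rng) if mixed_kinds else anomaly
            img, mask, params = inject_anomaly(
                img, spec_i, rng, background=phantom.background
            )
            save_image(root / "masks" / name, mask.astype(np.float64) * 255, bit_depth=8)
            row.update(
                kind=params[0]["kind"],
                diameter=params[0]["diameter"],
                contrast=params[0]["contrast"],
                cx=params[0]["cx"],
                cy=params[0]["cy"],
            )
        save_image(root / split / name, img * WHITE_LEVEL, bit_depth=16)
        rows.append(row)

    for i in range(n_normal_train):
        emit("train", 0, i)
    for i in range(n_val_pairs):
        emit("val", 0, i)
    for i in range(n_val_pairs):
        emit("val", 1, i)
    for i in range(n_test_pairs):
        emit("test", 0, i)
    for i in range(n_test_pairs):
        emit("test", 1, i)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest


def load_manifest(root: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(root) / "manifest.csv", keep_default_na=True)


def load_split(
    root: str | Path, split: str, label: int | None = None
) -> list[tuple[str, np.ndarray, int]]:
    """Load (image_id, array, label) triples for one split, in manifest order."""
    root = Path(root)
    manifest = load_manifest(root)
    sel = manifest[manifest["split"] == split]
    if label is not None:
        sel = sel[sel["label"] == label]
    return [
        (row["filename"], load_image(root / row["filename"]), int(row["label"]))
        for _, row in sel.iterrows()
    ]
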