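"""Deterministic tiling of square grayscale images into non-overlapping patches.

Every patch resolution ``s`` partitions the (resized) image into a
``grid_dim x grid_dim`` grid with ``grid_dim = image_side / s``.  The
convention throughout the package is 0-based row-major grid coordinates with
half-open pixel intervals: patch ``(gx, gy)`` covers rows
``[gy*s, (gy+1)*s)`` and columns ``[gx*s, (gx+1)*s)``.  Each pixel belongs to
exactly one patch per resolution, which is what makes the per-resolution
anomaly maps well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

from .exceptions import InvalidInputError, TilingError

__all__ = [
    "PatchSpec",
    "Patch",
    "resize_image",
    "tile_image",
    "assemble_tiles",
    "load_image",
    "save_image",
]


@dataclass(frozen=True)
class PatchSpec:
    """A patch resolution on a square image.

    Parameters
    ----------
    size_px : int
        Patch side length ``s`` in pixels.
    image_side_px : int
        Side of the square (resized) input image. Must be an exact multiple
        of ``size_px``.
    """

    size_px: int
    image_side_px: int

    def __post_init__(self) -> None:
        if self.size_px <= 0 or self.image_side_px <= 0:
            raise InvalidInputError("patch size and image side must be positive")
        if self.image_side_px % self.size_px != 0:
            raise TilingError(
                f"patch size {self.size_px} does not divide image side "
                f"{self.image_side_px}"
            )

    @property
    def grid_dim(self) -> int:
        """Number of patches along each image axis."""
        return self.image_side_px // self.size_px

    @property
    def n_patches(self) -> int:
        return self.grid_dim ** 2


@dataclass
class Patch:
    """One square crop with its grid coordinates at one resolution."""

    spec: PatchSpec
    gx: int
    gy: int
    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        g = self.spec.grid_dim
        if not (0 <= self.gx < g and 0 <= self.gy < g):
            raise InvalidInputError(
                f"grid coordinates ({self.gx}, {self.gy}) outside {g}x{g} grid"
            )
        if self.pixels.shape != (self.spec.size_px, self.spec.size_px):
            raise InvalidInputError(
                f"pixel block shape {self.pixels.shape} does not match patch "
                f"size {self.spec.size_px}"
            )

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        """(row_start, row_stop, col_start, col_stop), half-open."""
        s = self.spec.size_px
        return (self.gy * s, (self.gy + 1) * s, self.gx * s, (self.gx + 1) * s)


def resize_image(image: np.ndarray, target_side: int) -> np.ndarray:
    """Resize a single-channel image to ``target_side x target_side``.

    Bilinear resampling; intensities are preserved on their original scale
    (no rescaling or standardization). A same-size input is returned as an
    unmodified copy.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidInputError(
            f"expected a 2-D single-channel image, got ndim={image.ndim}"
        )
    if image.size == 0:
        raise InvalidInputError("empty image")
    if target_side <= 0:
        raise InvalidInputError("target side must be positive")
    image = image.astype(np.float64, copy=False)
    if image.shape == (target_side, target_side):
        return image.copy()
    return _sk_resize(
        image,
        (target_side, target_side),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    ).astype(np.float64)


def tile_image(image: np.ndarray, spec: PatchSpec) -> list[Patch]:
    """Split a square image into ``grid_dim**2`` disjoint patches, row-major.

    The tiles cover the image exactly; :func:`assemble_tiles` inverts the
    operation bit-exactly.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise InvalidInputError(f"expected a square 2-D image, got {image.shape}")
    if image.shape[0] != spec.image_side_px:
        raise TilingError(
            f"image side {image.shape[0]} does not match spec side "
            f"{spec.image_side_px}"
        )
    s = spec.size_px
    patches = []
    for gy in range(spec.grid_dim):
        for gx in range(spec.grid_dim):
            block = image[gy * s:(gy + 1) * s, gx * s:(gx + 1) * s]
            patches.append(Patch(spec=spec, gx=gx, gy=gy, pixels=block.copy()))
    return patches


def assemble_tiles(patches: list[Patch]) -> np.ndarray:
    """Reconstruct the full image from a complete row-major tile list."""
    if not patches:
        raise InvalidInputError("no patches to assemble")
    spec = patches[0].spec
    if len(patches) != spec.n_patches:
        raise InvalidInputError(
            f"expected {spec.n_patches} patches, got {len(patches)}"
        )
    out = np.empty((spec.image_side_px, spec.image_side_px), dtype=patches[0].pixels.dtype)
    for p in patches:
        r0, r1, c0, c1 = p.bounds
        out[r0:r1, c0:c1] = p.pixels
    return out


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG or TIFF as a float64 array.

    Intensities are kept on their stored integer scale (no normalization).
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise InvalidInputError(f"{path}: expected a grayscale image, got shape {arr.shape}")
    return arr.astype(np.float64)


def save_image(path: str | Path, image: np.ndarray, *, bit_depth: int = 16) -> None:
    """Write a float image as an 8- or 16-bit grayscale PNG, clipping to range."""
    if bit_depth == 16:
        arr = np.clip(image, 0, 65535).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.clip(image, 0, 255).astype(np.uint8)
    else:
        raise InvalidInputError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), arr)
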