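"""Whole-slide preprocessing: tissue bounding box, tiling, background filtering.

The preprocessing mirrors how gigapixel H&E slides are prepared for a
patch classifier.  A low-magnification thumbnail (nominally 1x) is
thresholded on gray intensity to locate the tissue; the minimal
axis-aligned bounding box of tissue pixels is upscaled to the working
magnification (nominally 40x); the boxed area is divided into fixed-size
tiles (default 2048 x 2048 px); tiles whose pixels are mostly (> 50 %)
white background are excluded; surviving tiles are area-averaged down to
512 x 512 px (about 10x objective magnification).

Rectangles are 0-based half-open ``[x0, x1) x [y0, y1)`` so grid
arithmetic is exact.  "White" is operationalized as gray intensity at or
above a threshold, by default Otsu's threshold computed on the
thumbnail.  Pyramidal slide formats are out of scope; a pre-extracted
raster stands in for one pyramid level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.filters import threshold_otsu

__all__ = [
    "Rect",
    "TilingConfig",
    "TileRecord",
    "load_gray_image",
    "tissue_bbox",
    "upscale_bbox",
    "tile_grid",
    "extract_tile",
    "background_filter",
    "downsize_patch",
    "tile_slide",
]


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass(frozen=True)
class TilingConfig:
    thumbnail_magnification: float = 1.0
    target_magnification: float = 40.0
    tile_size: int = 2048
    patch_size: int = 512
    white_fraction_cutoff: float = 0.5
    gray_threshold: float | str = "otsu"

    def __post_init__(self):
        if self.tile_size % self.patch_size:
            raise ValueError(
                f"tile_size {self.tile_size} must be divisible by "
                f"patch_size {self.patch_size}"
            )
        if not 0 <= self.white_fraction_cutoff <= 1:
            raise ValueError(
                f"white_fraction_cutoff must be in [0,1], got "
                f"{self.white_fraction_cutoff}"
            )
        if self.thumbnail_magnification <= 0 or self.target_magnification <= 0:
            raise ValueError("magnifications must be positive")


@dataclass(frozen=True)
class TileRecord:
    """One grid tile: origin in target-magnification pixel coordinates."""

    case_id: str
    x: int
    y: int
    white_fraction: float | None = None
    kept: bool | None = None


def load_gray_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF as 8-bit grayscale (RGB converted to luma)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def _resolve_threshold(image: np.ndarray, gray_threshold: float | str) -> float:
    if gray_threshold == "otsu":
        if np.ptp(image) == 0:
            # constant image: everything at or above the single value is
            # background, so no tissue is found
            return float(image.flat[0])
        t = float(threshold_otsu(image))
        # skimage's Otsu puts the lower class at intensities <= t while
        # our convention is tissue < threshold; shift by half a level on
        # integer images so boundary pixels stay tissue
        if np.issubdtype(image.dtype, np.integer):
            t += 0.5
        return t
    return float(gray_threshold)


def tissue_bbox(
    thumbnail: np.ndarray, gray_threshold: float | str = "otsu"
) -> Rect | None:
    """Minimal bounding box of sub-threshold (tissue) pixels.

    Pixels with intensity strictly below the threshold count as tissue.
    Returns ``None`` when the thumbnail contains no tissue.
    """
    if thumbnail.size == 0:
        raise ValueError("empty thumbnail")
    thr = _resolve_threshold(thumbnail, gray_threshold)
    tissue = thumbnail < thr
    if not tissue.any():
        return None
    rows = np.flatnonzero(tissue.any(axis=1))
    cols = np.flatnonzero(tissue.any(axis=0))
    return Rect(int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)


def upscale_bbox(rect: Rect, from_mag: float, to_mag: float) -> Rect:
    """Rescale a rectangle between magnifications.

    The origin corner is floored and the far corner ceiled after scaling
    by ``to_mag / from_mag`` so the scaled rectangle always covers the
    original area; a round trip up and back down is exact to within one
    pixel.
    """
    if from_mag <= 0 or to_mag <= 0:
        raise ValueError("magnifications must be positive")
    f = to_mag / from_mag
    return Rect(
        math.floor(rect.x0 * f),
        math.floor(rect.y0 * f),
        math.ceil(rect.x1 * f),
        math.ceil(rect.y1 * f),
    )


def tile_grid(rect: Rect, tile_size: int = 2048, case_id: str = "") -> list[TileRecord]:
    """Row-major grid of tile origins covering ``rect``.

    Partial edge tiles are included; they are padded with background
    when read.  The number of tiles is
    ``ceil(width / tile_size) * ceil(height / tile_size)``.
    """
    if rect is None:
        raise ValueError("cannot tile a null rectangle")
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    return [
        TileRecord(case_id=case_id, x=x, y=y)
        for y in range(rect.y0, rect.y1, tile_size)
        for x in range(rect.x0, rect.x1, tile_size)
    ]


def extract_tile(
    image: np.ndarray, x: int, y: int, tile_size: int, pad_value: int = 255
) -> np.ndarray:
    """Crop a tile at (x, y), padding out-of-bounds pixels with white."""
    h, w = image.shape[:2]
    tile = np.full((tile_size, tile_size), pad_value, dtype=image.dtype)
    x0, y0 = max(x, 0), max(y, 0)
    x1, y1 = min(x + tile_size, w), min(y + tile_size, h)
    if x1 > x0 and y1 > y0:
        tile[y0 - y : y1 - y, x0 - x : x1 - x] = image[y0:y1, x0:x1]
    return tile


def background_filter(
    tile: np.ndarray,
    gray_threshold: float,
    white_fraction_cutoff: float = 0.5,
) -> tuple[float, bool]:
    """White-background fraction of a tile and the keep decision.

    A pixel is white background iff its intensity is at or above
    ``gray_threshold``.  The tile is *excluded* only when white pixels
    form a strict majority: ``kept`` is true iff ``white_fraction <=
    white_fraction_cutoff`` (a tile at exactly the cutoff is kept).
    """
    white_fraction = float((tile >= gray_threshold).mean())
    return white_fraction, white_fraction <= white_fraction_cutoff


def downsize_patch(tile: np.ndarray, patch_size: int = 512) -> np.ndarray:
    """Area-average a square tile down to ``patch_size`` squared.

    The tile side must be an integer multiple of ``patch_size``; each
    output pixel is the mean of the corresponding input block (exact
    anti-aliased downscaling for the 2048 -> 512 factor of 4).  Returns
    float64; callers needing uint8 round explicitly.
    """
    if tile.ndim != 2 or tile.shape[0] != tile.shape[1]:
        raise ValueError(f"expected a square 2-D tile, got shape {tile.shape}")
    side = tile.shape[0]
    if side % patch_size:
        raise ValueError(
            f"tile side {side} is not an integer multiple of patch_size {patch_size}"
        )
    f = side // patch_size
    return tile.astype(float).reshape(patch_size, f, patch_size, f).mean(axis=(1, 3))


def tile_slide(
    slide: np.ndarray,
    config: TilingConfig = TilingConfig(),
    case_id: str = "",
    return_patches: bool = False,
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Run the full preprocessing chain on one raster slide.

    The thumbnail is obtained by area-averaging the slide down by the
    magnification ratio; its Otsu (or fixed) threshold locates the
    tissue bounding box, which is upscaled back to slide coordinates,
    tiled, and background-filtered.  Returns the tile manifest
    (``case_id, x, y, white_fraction, kept``) and, when requested, the
    downsized patches of the kept tiles.
    """
    factor = int(round(config.target_magnification / config.thumbnail_magnification))
    h, w = slide.shape[:2]
    th, tw = max(h // factor, 1), max(w // factor, 1)
    # crop to a multiple of the factor before block averaging
    thumb = (
        slide[: th * factor, : tw * factor]
        .astype(float)
        .reshape(th, factor, tw, factor)
        .mean(axis=(1, 3))
    )
    thr = _resolve_threshold(thumb, config.gray_threshold)
    bbox = tissue_bbox(thumb, thr)
    manifest_cols = ["case_id", "x", "y", "white_fraction", "kept"]
    if bbox is None:
        return pd.DataFrame(columns=manifest_cols), []
    bbox_40x = upscale_bbox(
        bbox, config.thumbnail_magnification, config.target_magnification
    )
    records = []
    patches = []
    for rec in tile_grid(bbox_40x, config.tile_size, case_id=case_id):
        tile = extract_tile(slide, rec.x, rec.y, config.tile_size)
        white_fraction, kept = background_filter(
            tile, thr, config.white_fraction_cutoff
        )
        records.append((case_id, rec.x, rec.y, white_fraction, kept))
        if kept and return_patches:
            patches.append(downsize_patch(tile, config.patch_size))
    manifest = pd.DataFrame(records, columns=manifest_cols)
    return manifest, patches
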