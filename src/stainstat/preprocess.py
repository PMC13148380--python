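"""Brightfield IHC image preprocessing: grayscale conversion, background
normalization, ROI tiling, empty/vein tile filtering, and block aggregation.

Polarity convention: brightfield — high values are empty/vein (bright),
low values are stain. Fluorescence-style inputs can be handled by
inverting (``1 - image``) before this pipeline.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left;
tile bounds are half-open.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "LUMA_WEIGHTS",
    "BackgroundPatch",
    "Tile",
    "TileSet",
    "read_image",
    "to_grayscale",
    "select_background_patch",
    "normalize_background",
    "tile_roi",
    "filter_tiles",
    "aggregate_tile",
]

#: Rec. 709 luminance weights for RGB -> gray conversion.
LUMA_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclasses.dataclass(frozen=True)
class BackgroundPatch:
    """A rectangular background window used for intensity normalization."""

    top: int
    left: int
    height: int = 200
    width: int = 200

    def pixels(self, image: np.ndarray) -> np.ndarray:
        h, w = image.shape
        if self.top < 0 or self.left < 0 or self.top + self.height > h or self.left + self.width > w:
            raise ValueError(f"background patch {self} does not fit in image of shape {image.shape}")
        return image[self.top : self.top + self.height, self.left : self.left + self.width]


@dataclasses.dataclass
class Tile:
    """One grid tile. Pixel bounds are absolute image coordinates, half-open."""

    row_idx: int
    col_idx: int
    top: int
    bottom: int
    left: int
    right: int
    keep: bool = True
    drop_reason: str | None = None

    @property
    def tile_id(self) -> str:
        return f"r{self.row_idx}c{self.col_idx}"

    def pixels(self, image: np.ndarray) -> np.ndarray:
        return image[self.top : self.bottom, self.left : self.right]


@dataclasses.dataclass
class TileSet:
    """Partition of a square ROI into an n x n grid of tiles."""

    roi_top: int
    roi_left: int
    roi_size: int
    grid: int
    row_bounds: list[int]
    col_bounds: list[int]
    tiles: list[Tile]

    @property
    def kept(self) -> list[Tile]:
        return [t for t in self.tiles if t.keep]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "roi_top": self.roi_top,
            "roi_left": self.roi_left,
            "roi_size": self.roi_size,
            "grid": self.grid,
            "row_bounds": self.row_bounds,
            "col_bounds": self.col_bounds,
            "tiles": [dataclasses.asdict(t) for t in self.tiles],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TileSet":
        payload = json.loads(Path(path).read_text())
        tiles = [Tile(**t) for t in payload.pop("tiles")]
        return cls(tiles=tiles, **payload)


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG raster as a float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    from PIL import Image

    return np.asarray(Image.open(path))


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 1- or 3-channel raster to a grayscale image in [0, 1].

    3-channel input is combined with fixed luminance weights
    (0.2126, 0.7152, 0.0722). Integer input is scaled by its dtype's
    maximum; float input is assumed to already be on a [0, 1]-like scale.
    """
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(image.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr @ np.asarray(LUMA_WEIGHTS)
    else:
        raise ValueError(f"expected 1 or 3 channels, got array of shape {arr.shape}")
    if gray.shape[0] < 2 or gray.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    if np.any(gray < 0) or np.any(np.isnan(gray)):
        raise ValueError("image has negative or NaN values")
    return gray


def select_background_patch(image: np.ndarray, size: int = 200) -> BackgroundPatch:
    """Automatically pick a bright, flat window to serve as background.

    Scans ``size x size`` windows on a stride of ``size // 2`` and returns
    the minimum-variance window among those whose mean lies in the top
    quartile of window means (bright + flat = empty background). Ties are
    broken by scan order (row-major, top-left first).
    """
    h, w = image.shape
    if h < size or w < size:
        raise ValueError(f"image shape {image.shape} smaller than patch size {size}")
    stride = max(1, size // 2)
    tops = list(range(0, h - size + 1, stride))
    lefts = list(range(0, w - size + 1, stride))
    if tops[-1] != h - size:
        tops.append(h - size)
    if lefts[-1] != w - size:
        lefts.append(w - size)
    stats = []
    for top in tops:
        for left in lefts:
            win = image[top : top + size, left : left + size]
            stats.append((top, left, float(win.mean()), float(win.var())))
    means = np.array([s[2] for s in stats])
    cutoff = np.quantile(means, 0.75)
    best = None
    for top, left, mean, var in stats:
        if mean >= cutoff and (best is None or var < best[2]):
            best = (top, left, var)
    top, left, _ = best
    return BackgroundPatch(top=top, left=left, height=size, width=size)


def normalize_background(image: np.ndarray, patch: BackgroundPatch) -> np.ndarray:
    """Divide the image by the mean intensity of its background patch."""
    mean = float(patch.pixels(image).mean())
    if mean < 1e-6:
        raise ValueError(f"background patch {patch} has near-zero mean ({mean:g})")
    return image / mean


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def grid_bounds(size: int, grid: int) -> list[int]:
    """Cut positions round(i * size / grid), half away from zero, i = 0..grid."""
    return [_round_half_away(i * size / grid) for i in range(grid + 1)]


def tile_roi(
    image: np.ndarray,
    roi_top: int = 0,
    roi_left: int = 0,
    roi_size: int = 1500,
    grid: int = 8,
) -> TileSet:
    """Partition a square ROI into a ``grid x grid`` tile set.

    For the default 1500-px ROI and 8x8 grid the cut positions are
    ``[0, 188, 375, 563, 750, 938, 1125, 1313, 1500]`` (187.5-px nominal
    tiles rounded to alternating 187/188-px widths so the grid exactly
    partitions the ROI). All tiles start with ``keep=True``.
    """
    h, w = image.shape
    if roi_top < 0 or roi_left < 0 or roi_top + roi_size > h or roi_left + roi_size > w:
        raise ValueError(
            f"ROI (top={roi_top}, left={roi_left}, size={roi_size}) out of bounds "
            f"for image of shape {image.shape}"
        )
    bounds = grid_bounds(roi_size, grid)
    tiles = [
        Tile(
            row_idx=i,
            col_idx=j,
            top=roi_top + bounds[i],
            bottom=roi_top + bounds[i + 1],
            left=roi_left + bounds[j],
            right=roi_left + bounds[j + 1],
        )
        for i in range(grid)
        for j in range(grid)
    ]
    return TileSet(
        roi_top=roi_top,
        roi_left=roi_left,
        roi_size=roi_size,
        grid=grid,
        row_bounds=bounds,
        col_bounds=bounds,
        tiles=tiles,
    )


def filter_tiles(
    tiles: TileSet,
    image: np.ndarray,
    blur_sigma: float = 2.0,
    frac_threshold: float = 0.10,
    top_quantile: float = 0.90,
) -> TileSet:
    """Flag tiles dominated by empty or vein (bright) regions.

    The ROI is Gaussian-blurred (``blur_sigma`` px) and the
    ``top_quantile`` value over all blurred ROI pixels is taken as a
    brightness cutoff; a tile is dropped iff the fraction of its blurred
    pixels strictly above that cutoff exceeds ``frac_threshold``.
    Returns a new TileSet; kept tiles from a previous filter pass that are
    now below threshold are kept (flags recomputed from scratch).
    """
    roi = image[
        tiles.roi_top : tiles.roi_top + tiles.roi_size,
        tiles.roi_left : tiles.roi_left + tiles.roi_size,
    ]
    blurred = ndimage.gaussian_filter(roi, sigma=blur_sigma)
    cutoff = float(np.quantile(blurred, top_quantile))
    out_tiles = []
    for t in tiles.tiles:
        win = blurred[
            t.top - tiles.roi_top : t.bottom - tiles.roi_top,
            t.left - tiles.roi_left : t.right - tiles.roi_left,
        ]
        frac = float((win > cutoff).mean())
        drop = frac > frac_threshold
        out_tiles.append(
            dataclasses.replace(
                t, keep=not drop, drop_reason="empty_or_vein" if drop else None
            )
        )
    n_drop = sum(not t.keep for t in out_tiles)
    if n_drop:
        logger.info("filter_tiles dropped %d/%d tiles as empty_or_vein", n_drop, len(out_tiles))
    return dataclasses.replace(tiles, tiles=out_tiles)


def aggregate_tile(pixels: np.ndarray, block: int = 3) -> np.ndarray:
    """Block-average a tile: output (i, j) is the mean of the ``block x
    block`` input block starting at (block*i, block*j); partial edge blocks
    average the pixels available. Output dims are ceil(h/block) x
    ceil(w/block)."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.size == 0:
        raise ValueError("empty tile")
    h, w = pixels.shape
    ridx = np.arange(0, h, block)
    cidx = np.arange(0, w, block)
    sums = np.add.reduceat(np.add.reduceat(pixels, ridx, axis=0), cidx, axis=1)
    rcounts = np.minimum(block, h - ridx)
    ccounts = np.minimum(block, w - cidx)
    return sums / np.outer(rcounts, ccounts)
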