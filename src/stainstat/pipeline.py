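"""End-to-end texture pipeline: raw brightfield image -> normalized ROI ->
filtered 8x8 tile grid -> 3x3-aggregated tiles -> moving-window GLCM maps
-> one 42-feature row per kept tile."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import glcm, preprocess

__all__ = ["image_features", "feature_columns"]


def feature_columns() -> list[str]:
    return glcm.feature_names()


def image_features(
    image: np.ndarray,
    roi_top: int = 0,
    roi_left: int = 0,
    roi_size: int = 1500,
    grid: int = 8,
    background: preprocess.BackgroundPatch | str = "auto",
    blur_sigma: float = 2.0,
    frac_threshold: float = 0.10,
    top_quantile: float = 0.90,
    block: int = 3,
    config: glcm.GlcmConfig | None = None,
    invert: bool = False,
    image_id: str = "",
    return_tiles: bool = False,
):
    """Compute the per-tile texture feature table of one image.

    Steps: grayscale conversion (if needed), optional polarity inversion,
    background normalization (auto-selected or user-supplied patch), ROI
    tiling, empty/vein tile filtering, per-tile block aggregation,
    moving-window GLCM texture maps, and the 6 summaries of each of the 7
    statistics. Returns a DataFrame with one row per kept tile (and the
    TileSet plus aggregated tile pixels if ``return_tiles``).
    """
    gray = preprocess.to_grayscale(image)
    if invert:
        gray = gray.max() - gray
    patch = (
        preprocess.select_background_patch(gray)
        if background == "auto"
        else background
    )
    norm = preprocess.normalize_background(gray, patch)
    tiles = preprocess.tile_roi(norm, roi_top=roi_top, roi_left=roi_left,
                                roi_size=roi_size, grid=grid)
    tiles = preprocess.filter_tiles(
        tiles, norm, blur_sigma=blur_sigma,
        frac_threshold=frac_threshold, top_quantile=top_quantile,
    )
    config = config or glcm.GlcmConfig()
    rows = []
    thumbs = {}
    for tile in tiles.kept:
        agg = preprocess.aggregate_tile(tile.pixels(norm), block=block)
        tmap = glcm.texture_map(agg, config)
        row: dict = {
            "image_id": image_id,
            "tile_id": f"{image_id}:{tile.tile_id}" if image_id else tile.tile_id,
            "row_idx": tile.row_idx,
            "col_idx": tile.col_idx,
        }
        row.update(glcm.summarize_tile(tmap))
        rows.append(row)
        thumbs[row["tile_id"]] = agg
    features = pd.DataFrame(rows)
    if return_tiles:
        return features, tiles, thumbs
    return features
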