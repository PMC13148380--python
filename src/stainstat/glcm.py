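"""Gray-level co-occurrence matrix (GLCM) texture features.

Implements the Haralick-style texture statistics used to quantify spatial
staining patterns in brightfield IHC images: per-tile quantization to a
small number of gray levels, co-occurrence counting over the four standard
pixel shifts (0°, 45°, 90°, 135°), seven scalar statistics of the
co-occurrence distribution, moving-window texture maps, and six summary
statistics of each map per tile (42 features per tile in total).

Conventions
-----------
* Quantization is equal-width over the tile's own ``[min, max]`` range and
  is computed once per tile, never per window, so a gray level means the
  same thing everywhere in the tile.
* The four shifts are pooled into a single co-occurrence distribution per
  window (counts are accumulated across angles before normalization).
* Co-occurrence matrices are symmetric by default (each pair is counted in
  both orders).
* Entropy uses the natural logarithm by default (``log_base='e'``).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "STATISTIC_NAMES",
    "SUMMARY_NAMES",
    "ANGLE_SHIFTS",
    "GlcmConfig",
    "TextureMap",
    "quantize",
    "cooccurrence",
    "glcm_statistics",
    "texture_map",
    "summarize_tile",
    "feature_names",
]

#: The seven co-occurrence statistics, in canonical order.
STATISTIC_NAMES = (
    "mean",
    "variance",
    "contrast",
    "dissimilarity",
    "homogeneity",
    "second_moment",
    "entropy",
)

#: The six per-tile summaries of each texture map, in canonical order.
SUMMARY_NAMES = ("mean", "sd", "q1", "q3", "kurtosis", "skewness")

#: (drow, dcol) pixel shifts for the four standard GLCM angles.
ANGLE_SHIFTS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

DEFAULT_SHIFTS = tuple(ANGLE_SHIFTS[a] for a in (0, 45, 90, 135))


@dataclasses.dataclass(frozen=True)
class GlcmConfig:
    """Parameters of the texture computation.

    Parameters
    ----------
    n_gray
        Number of gray levels after quantization (>= 2).
    window
        Side of the square moving window, odd and >= 3.
    shifts
        Nonempty sequence of (drow, dcol) co-occurrence offsets; pooled
        into one distribution per window.
    symmetric
        Count each pixel pair in both orders.
    log_base
        'e' (natural log) or '2' for the entropy statistic.
    """

    n_gray: int = 4
    window: int = 3
    shifts: tuple[tuple[int, int], ...] = DEFAULT_SHIFTS
    symmetric: bool = True
    log_base: str = "e"

    def __post_init__(self) -> None:
        if self.n_gray < 2:
            raise ValueError(f"n_gray must be >= 2, got {self.n_gray}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if not self.shifts:
            raise ValueError("shifts must be nonempty")
        if self.log_base not in ("e", "2"):
            raise ValueError(f"log_base must be 'e' or '2', got {self.log_base!r}")


@dataclasses.dataclass
class TextureMap:
    """Per-pixel texture maps for one tile.

    ``maps[name]`` has the same shape as the input tile; pixels whose
    moving window is incomplete are NaN and flagged False in ``valid``.
    """

    maps: dict[str, np.ndarray]
    valid: np.ndarray
    config: GlcmConfig

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def quantize(tile: np.ndarray, n_gray: int) -> np.ndarray:
    """Equal-width quantization of a tile to integer levels in [0, n_gray).

    Bins span the tile's own [min, max]; the maximum maps to
    ``n_gray - 1``; a constant tile maps to level 0 everywhere.
    """
    tile = np.asarray(tile, dtype=float)
    if not np.all(np.isfinite(tile)):
        raise ValueError("tile contains non-finite values")
    lo = tile.min()
    hi = tile.max()
    if hi == lo:
        return np.zeros(tile.shape, dtype=np.intp)
    levels = np.floor((tile - lo) / (hi - lo) * n_gray).astype(np.intp)
    np.minimum(levels, n_gray - 1, out=levels)
    return levels


def cooccurrence(
    levels: np.ndarray,
    shift: tuple[int, int],
    n_gray: int | None = None,
    symmetric: bool = True,
) -> np.ndarray:
    """Normalized co-occurrence matrix of ``levels`` at one pixel shift.

    Counts pairs ``(levels[r, c], levels[r+drow, c+dcol])`` over all
    in-bounds positions; if ``symmetric`` the transpose is added; the
    result is normalized to sum to 1.
    """
    levels = np.asarray(levels)
    if n_gray is None:
        n_gray = int(levels.max()) + 1 if levels.size else 1
    if levels.size and (levels.min() < 0 or levels.max() >= n_gray):
        raise ValueError("levels out of range for n_gray")
    dr, dc = shift
    h, w = levels.shape
    rlo, rhi = max(0, -dr), h - max(0, dr)
    clo, chi = max(0, -dc), w - max(0, dc)
    if rhi <= rlo or chi <= clo:
        raise ValueError(f"no pixel pairs for shift {shift} on shape {levels.shape}")
    src = levels[rlo:rhi, clo:chi].ravel()
    dst = levels[rlo + dr : rhi + dr, clo + dc : chi + dc].ravel()
    counts = np.bincount(src * n_gray + dst, minlength=n_gray * n_gray).astype(float)
    counts = counts.reshape(n_gray, n_gray)
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def glcm_statistics(P: np.ndarray, log_base: str = "e") -> dict[str, float]:
    """The seven scalar statistics of a co-occurrence distribution ``P``.

    mean = Σ i·P(i,j); variance = Σ (i−μ)²·P; contrast = Σ (i−j)²·P;
    dissimilarity = Σ |i−j|·P; homogeneity = Σ P/(1+(i−j)²);
    second_moment = Σ P²; entropy = −Σ P·log P (0·log 0 = 0).
    """
    P = np.asarray(P, dtype=float)
    if not np.isclose(P.sum(), 1.0):
        raise ValueError("P must sum to 1")
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    diff = i - j
    mu = float((i * P).sum())
    nz = P[P > 0]
    log = np.log if log_base == "e" else np.log2
    return {
        "mean": mu,
        "variance": float(((i - mu) ** 2 * P).sum()),
        "contrast": float((diff**2 * P).sum()),
        "dissimilarity": float((np.abs(diff) * P).sum()),
        "homogeneity": float((P / (1.0 + diff**2)).sum()),
        "second_moment": float((P**2).sum()),
        "entropy": float(-(nz * log(nz)).sum()),
    }


def _box_sum(arr: np.ndarray, ulo: int, uhi: int, vlo: int, vhi: int) -> np.ndarray:
    """out[p] = Σ arr[p + (u, v)] for u in [ulo, uhi], v in [vlo, vhi].

    Out-of-bounds source positions contribute 0. Computed with an
    integral image so the cost is independent of the box size.
    """
    h, w = arr.shape
    pt, pb = max(0, -ulo), max(0, uhi)
    pl, pr = max(0, -vlo), max(0, vhi)
    padded = np.zeros((h + pt + pb, w + pl + pr))
    padded[pt : pt + h, pl : pl + w] = arr
    c = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1))
    c[1:, 1:] = padded.cumsum(axis=0).cumsum(axis=1)
    r0, r1 = pt + ulo, pt + uhi + 1
    c0, c1 = pl + vlo, pl + vhi + 1
    return (
        c[r1 : r1 + h, c1 : c1 + w]
        - c[r0 : r0 + h, c1 : c1 + w]
        - c[r1 : r1 + h, c0 : c0 + w]
        + c[r0 : r0 + h, c0 : c0 + w]
    )


def texture_map(tile: np.ndarray, config: GlcmConfig | None = None) -> TextureMap:
    """Moving-window GLCM texture maps of a tile.

    The tile is quantized once; for every pixel a ``window × window``
    neighborhood is taken, pixel pairs for all configured shifts (both
    endpoints inside the window) are pooled into one co-occurrence
    distribution, and the seven statistics of that distribution become the
    pixel's map values. Border pixels with an incomplete window are masked.
    """
    config = config or GlcmConfig()
    tile = np.asarray(tile, dtype=float)
    h, w = tile.shape
    if h < config.window or w < config.window:
        raise ValueError(
            f"tile shape {tile.shape} smaller than window {config.window}"
        )
    n = config.n_gray
    levels = quantize(tile, n)
    half = config.window // 2

    # counts[k] holds, per center pixel, the pooled count of pair code
    # k = a*n + b over all shifts whose endpoints fall inside the window.
    counts = np.zeros((n * n, h, w))
    for dr, dc in config.shifts:
        rlo, rhi = max(0, -dr), h - max(0, dr)
        clo, chi = max(0, -dc), w - max(0, dc)
        if rhi <= rlo or chi <= clo:
            raise ValueError(f"no pixel pairs for shift {(dr, dc)}")
        src = levels[rlo:rhi, clo:chi]
        dst = levels[rlo + dr : rhi + dr, clo + dc : chi + dc]
        # source positions inside the window whose partner is also inside
        ulo, uhi = -half + max(0, -dr), half - max(0, dr)
        vlo, vhi = -half + max(0, -dc), half - max(0, dc)
        pair = src * n + dst
        for code in range(n * n):
            ind = np.zeros((h, w))
            ind[rlo:rhi, clo:chi] = pair == code
            add = _box_sum(ind, ulo, uhi, vlo, vhi)
            counts[code] += add
            if config.symmetric:
                a, b = divmod(code, n)
                counts[b * n + a] += add

    total = counts.sum(axis=0)
    valid = np.zeros((h, w), dtype=bool)
    valid[half : h - half, half : w - half] = True
    valid &= total > 0

    with np.errstate(invalid="ignore", divide="ignore"):
        P = counts / total
    P[:, ~valid] = np.nan

    i = np.arange(n * n) // n
    j = np.arange(n * n) % n
    diff = (i - j).astype(float)[:, None, None]
    iarr = i.astype(float)[:, None, None]
    mu = np.nansum(P * iarr, axis=0)
    log = np.log if config.log_base == "e" else np.log2
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(P > 0, P * log(np.where(P > 0, P, 1.0)), 0.0)
    maps = {
        "mean": mu,
        "variance": np.nansum((iarr - mu) ** 2 * P, axis=0),
        "contrast": np.nansum(diff**2 * P, axis=0),
        "dissimilarity": np.nansum(np.abs(diff) * P, axis=0),
        "homogeneity": np.nansum(P / (1.0 + diff**2), axis=0),
        "second_moment": np.nansum(P**2, axis=0),
        "entropy": -np.nansum(plogp, axis=0),
    }
    for name in maps:
        maps[name] = np.where(valid, maps[name], np.nan)
    return TextureMap(maps=maps, valid=valid, config=config)


def summarize_tile(tmap: TextureMap) -> dict[str, float]:
    """Six summaries of each texture map over the tile's valid pixels.

    Returns a flat dict keyed ``<statistic>_<summary>`` (42 entries) plus
    ``n_valid_pixels``. sd is the sample standard deviation (n−1); q1/q3
    are linear-interpolation (type-7) quantiles; kurtosis is excess
    kurtosis; skewness is the moment coefficient g1. Zero-variance or
    undersized maps yield NaN for sd/kurtosis/skewness rather than a fake 0.
    """
    if tmap.n_valid < 1:
        raise ValueError("texture map has no valid pixels")
    out: dict[str, float] = {}
    for stat in STATISTIC_NAMES:
        vals = tmap.maps[stat][tmap.valid]
        mean = float(vals.mean())
        q1, q3 = (float(q) for q in np.quantile(vals, [0.25, 0.75]))
        if vals.size < 2:
            sd = kurt = skew = float("nan")
        elif np.ptp(vals) == 0.0:
            sd = 0.0
            kurt = skew = float("nan")
        else:
            sd = float(vals.std(ddof=1))
            kurt = float(_sstats.kurtosis(vals, fisher=True, bias=True))
            skew = float(_sstats.skew(vals, bias=True))
        for name, val in zip(SUMMARY_NAMES, (mean, sd, q1, q3, kurt, skew)):
            out[f"{stat}_{name}"] = val
    out["n_valid_pixels"] = float(tmap.n_valid)
    return out


def feature_names() -> list[str]:
    """The 42 canonical feature column names, in order."""
    return [f"{s}_{m}" for s in STATISTIC_NAMES for m in SUMMARY_NAMES]
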