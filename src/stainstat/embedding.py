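"""PCA embedding of per-tile texture features, with loadings, explained
variance, and thumbnail scatter plots of tiles in PC space."""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PcaResult", "clean_feature_matrix", "fit_pca", "tile_scatter"]


@dataclasses.dataclass
class PcaResult:
    """SVD-based PCA of a tile x feature matrix.

    ``scores`` are tiles x components, ``loadings`` features x components
    (orthonormal columns), with the sign convention that each loading
    column's largest-magnitude entry is positive. ``mean`` and ``scale``
    are the centering/scaling vectors applied to the input columns.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mean: pd.Series
    scale: pd.Series
    dropped_columns: list[str]
    dropped_rows: list


def clean_feature_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Drop rows containing any NaN feature (flagged degenerate tiles)."""
    bad = matrix.index[matrix.isna().any(axis=1)].tolist()
    if bad:
        logger.info("dropping %d rows with NaN features", len(bad))
    return matrix.drop(index=bad), bad


def fit_pca(matrix: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of a numeric feature matrix (rows = tiles, columns = features).

    Columns are centered; if ``standardize`` they are scaled to unit
    variance (zero-variance columns dropped with a warning). Components
    come from the SVD of the centered/scaled matrix.
    """
    if matrix.columns.duplicated().any():
        raise ValueError("feature column names must be unique")
    matrix, dropped_rows = clean_feature_matrix(matrix)
    dropped_cols: list[str] = []
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    if standardize:
        dropped_cols = sd.index[sd == 0].tolist()
        if dropped_cols:
            warnings.warn(f"dropping {len(dropped_cols)} zero-variance columns")
            matrix = matrix.drop(columns=dropped_cols)
            mean = mean.drop(dropped_cols)
            sd = sd.drop(dropped_cols)
        scale = sd
    else:
        scale = pd.Series(1.0, index=matrix.columns)
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError(f"need >= 2 rows and columns after filtering, got {matrix.shape}")

    X = (matrix - mean) / scale
    U, S, Vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        idx = np.argmax(np.abs(Vt[k]))
        if Vt[k, idx] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    n_comp = min(len(S), X.shape[0] - 1, X.shape[1])
    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    scores = pd.DataFrame((U * S)[:, :n_comp], index=matrix.index, columns=comp_names)
    loadings = pd.DataFrame(Vt[:n_comp].T, index=matrix.columns, columns=comp_names)
    evr = S[:n_comp] ** 2 / (S**2).sum()
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=evr,
        mean=mean,
        scale=scale,
        dropped_columns=dropped_cols,
        dropped_rows=dropped_rows,
    )


def select_extreme_tiles(scores: pd.DataFrame, k: int = 3) -> list:
    """The k tiles of largest PC1/PC2 norm in each quadrant (clamped to
    the available tiles)."""
    pc1 = scores.iloc[:, 0]
    pc2 = scores.iloc[:, 1]
    norm = np.hypot(pc1, pc2)
    chosen = []
    for sx, sy in ((1, 1), (-1, 1), (-1, -1), (1, -1)):
        in_quad = scores.index[(sx * pc1 >= 0) & (sy * pc2 >= 0)]
        ranked = norm.loc[in_quad].sort_values(ascending=False)
        chosen.extend(ranked.index[:k].tolist())
    # preserve score order, drop duplicates from axis-boundary ties
    seen = set()
    return [t for t in chosen if not (t in seen or seen.add(t))]


def tile_scatter(
    pca: PcaResult,
    thumbnails: dict | None,
    path: str | Path,
    k: int = 3,
    zoom: float = 0.25,
):
    """Scatter tiles in (PC1, PC2), drawing the k most extreme tiles per
    quadrant as image thumbnails. Tiles without a thumbnail are drawn as
    plain points with a warning."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.offsetbox import AnnotationBbox, OffsetImage

    fig, ax = plt.subplots(figsize=(7, 7))
    sc = pca.scores
    ax.scatter(sc.iloc[:, 0], sc.iloc[:, 1], s=8, c="0.7", zorder=1)
    for tile_id in select_extreme_tiles(sc, k=k):
        x, y = sc.loc[tile_id].iloc[0], sc.loc[tile_id].iloc[1]
        thumb = (thumbnails or {}).get(tile_id)
        if thumb is None:
            warnings.warn(f"no thumbnail for tile {tile_id!r}; drawing point only")
            ax.scatter([x], [y], s=20, c="C1", zorder=2)
            continue
        ab = AnnotationBbox(
            OffsetImage(np.asarray(thumb), cmap="gray", zoom=zoom),
            (x, y),
            frameon=True,
            pad=0.1,
        )
        ax.add_artist(ab)
    ax.set_xlabel(f"PC1 ({100 * pca.explained_variance_ratio[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * pca.explained_variance_ratio[1]:.1f}%)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
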