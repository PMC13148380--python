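"""IHC positivity scoring: stratum cutoffs, percent-positive, H-scores,
500x500 vein-patch restriction, and one-way ANOVA across groups.

The H-score summarizes DAB staining over a region of cells as
``1*%low + 2*%moderate + 3*%high`` (range 0-300), where the four strata
are defined by three increasing intensity cutoffs. Cutoffs are inclusive
on the upper side: a cell exactly at a cutoff enters the higher stratum.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .synthetic import STRATA

logger = logging.getLogger(__name__)

__all__ = [
    "CUTOFF_PRESETS",
    "IntensityCutoffs",
    "VeinPatch",
    "AnovaResult",
    "stratify_cells",
    "h_score",
    "vein_patch_scores",
    "compare_groups",
]


@dataclasses.dataclass(frozen=True)
class IntensityCutoffs:
    """Three increasing intensity cutoffs delimiting neg/low/moderate/high."""

    low: float
    medium: float
    high: float
    marker: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.low < self.medium < self.high:
            raise ValueError(
                f"cutoffs must satisfy 0 < low < medium < high, got {self}"
            )


#: Marker-specific cutoffs (optical-density scale).
CUTOFF_PRESETS = {
    "f480": IntensityCutoffs(low=0.05, medium=0.4, high=0.6, marker="f480"),
    "cd3": IntensityCutoffs(low=0.2, medium=0.4, high=0.6, marker="cd3"),
}


@dataclasses.dataclass(frozen=True)
class VeinPatch:
    """A square patch centered on a vein; bounds are half-open pixels."""

    patch_id: str
    top: float
    left: float
    vein_type: str  # "central" or "portal"
    size: float = 500.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (y >= self.top)
            & (y < self.top + self.size)
            & (x >= self.left)
            & (x < self.left + self.size)
        )


@dataclasses.dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


def stratify_cells(cells: pd.DataFrame, cutoffs: IntensityCutoffs) -> pd.DataFrame:
    """Label each cell neg/low/moderate/high from its intensity.

    neg: intensity < low; low: low <= intensity < medium;
    moderate: medium <= intensity < high; high: intensity >= high.
    """
    out = cells.copy()
    bins = [-np.inf, cutoffs.low, cutoffs.medium, cutoffs.high, np.inf]
    out["stratum"] = pd.cut(
        out["intensity"], bins=bins, labels=STRATA, right=False
    ).astype(str)
    return out


def _score_one(group: pd.DataFrame) -> dict:
    n = len(group)
    frac = {
        s: 100.0 * (group["stratum"] == s).sum() / n for s in STRATA
    }
    h = frac["low"] + 2 * frac["moderate"] + 3 * frac["high"]
    return {
        "n_cells": n,
        "pct_neg": frac["neg"],
        "pct_low": frac["low"],
        "pct_moderate": frac["moderate"],
        "pct_high": frac["high"],
        "percent_positive": 100.0 - frac["neg"],
        "h_score": h,
    }


def h_score(cells: pd.DataFrame, by: str = "region_id") -> pd.DataFrame:
    """H-score and stratum fractions per region.

    ``cells`` must carry a ``stratum`` column (see :func:`stratify_cells`).
    Regions named in the grouping but containing no cells are skipped with
    a warning rather than zero-filled.
    """
    if "stratum" not in cells.columns:
        raise ValueError("cells must be stratified first (missing 'stratum' column)")
    rows = []
    for region, group in cells.groupby(by, observed=True, sort=True):
        if len(group) == 0:
            warnings.warn(f"region {region!r} has no cells; skipped")
            continue
        row = {by: region}
        # carry condition labels through if constant within the region
        for meta in ("condition", "sample_id", "vein_type"):
            if meta in group.columns and group[meta].nunique() == 1:
                row[meta] = group[meta].iloc[0]
        row.update(_score_one(group))
        rows.append(row)
    return pd.DataFrame(rows)


def vein_patch_scores(cells: pd.DataFrame, patches: list[VeinPatch]) -> pd.DataFrame:
    """H-scores restricted to square vein patches.

    Cells are assigned to each patch by half-open bounds (overlapping
    patches are allowed and logged; a cell can then count in several
    patches). Empty patches are skipped with a warning.
    """
    if "stratum" not in cells.columns:
        raise ValueError("cells must be stratified first (missing 'stratum' column)")
    x = cells["x"].to_numpy()
    y = cells["y"].to_numpy()
    masks = {p.patch_id: p.contains(x, y) for p in patches}
    for i, a in enumerate(patches):
        for b in patches[i + 1 :]:
            if (masks[a.patch_id] & masks[b.patch_id]).any():
                logger.info("patches %s and %s overlap", a.patch_id, b.patch_id)
    rows = []
    for p in patches:
        sub = cells[masks[p.patch_id]]
        if len(sub) == 0:
            warnings.warn(f"patch {p.patch_id!r} contains no cells; skipped")
            continue
        row = {"patch_id": p.patch_id, "vein_type": p.vein_type}
        if "condition" in sub.columns and sub["condition"].nunique() == 1:
            row["condition"] = sub["condition"].iloc[0]
        row.update(_score_one(sub))
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    scores: pd.DataFrame, group: str = "condition", value: str = "h_score"
) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA of scores across groups."""
    groups = [g[value].to_numpy(dtype=float) for _, g in scores.groupby(group, observed=True)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    grand = np.concatenate(groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ssb = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    df_b = len(groups) - 1
    df_w = len(grand) - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(F=float("nan"), df_between=df_b, df_within=df_w,
                               p=float("nan"), degenerate=True)
        return AnovaResult(F=float("inf"), df_between=df_b, df_within=df_w, p=0.0)
    res = _sstats.f_oneway(*groups)
    return AnovaResult(F=float(res.statistic), df_between=df_b, df_within=df_w,
                       p=float(res.pvalue))
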