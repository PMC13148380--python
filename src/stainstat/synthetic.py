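"""Synthetic ground-truth generators for every downstream stage.

Three generators:

* :func:`simulate_histology` — square brightfield images of dark stained
  cells on a bright background, with optional bright circular veins and
  either dispersed (uniform) or clustered (Thomas parent–offspring)
  spatial patterns. Emulates F4/80-style macrophage staining where
  dispersed vs aggregated patterning is the signal of interest.
* :func:`simulate_cell_intensities` — per-cell stain-intensity tables with
  four known intensity strata (neg/low/moderate/high), feeding the
  H-score computation.
* :func:`simulate_expression` — log2-scale genes x samples matrices for a
  2x2 genotype x treatment design with a planted up/down activity
  signature and planted 4-pattern interaction genes.

Every generator is deterministic given its seed and returns its ground
truth alongside the data; downstream modules never see the truth except
in tests.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "STRATA",
    "DEFAULT_GROUPS",
    "DEFAULT_INTERACTION_PATTERNS",
    "HistologySimConfig",
    "ExpressionSimConfig",
    "HistologySample",
    "ExpressionSample",
    "simulate_histology",
    "simulate_cell_intensities",
    "simulate_expression",
]

#: IHC intensity strata in increasing staining order.
STRATA = ("neg", "low", "moderate", "high")

#: The 2x2 genotype x treatment design, in fixed group order.
DEFAULT_GROUPS = (
    ("NTC", "Veh"),
    ("NTC", "CCl4"),
    ("sgBap1", "Veh"),
    ("sgBap1", "CCl4"),
)

#: Per-group mean templates for planted interaction genes (group order as
#: in DEFAULT_GROUPS): a genotype main effect, a treatment main effect, a
#: pure crossover interaction, and a single-group spike. Chosen to have
#: pairwise correlation well below 1 so correlation-distance clustering
#: can tell them apart.
DEFAULT_INTERACTION_PATTERNS = (
    (1.5, 1.5, -1.5, -1.5),
    (1.5, -1.5, 1.5, -1.5),
    (1.5, -1.5, -1.5, 1.5),
    (4.5, -1.5, -1.5, -1.5),
)


@dataclasses.dataclass(frozen=True)
class HistologySimConfig:
    """Parameters of the brightfield tissue simulator.

    Intensities are on a [0, 1] scale: the background sits at
    ``background_level`` and a fully stained pixel is darker by up to
    ``stain_intensity`` (scaled per cell by its stratum).
    """

    image_size: int = 1500
    cell_count: int = 400
    cell_radius_px: float = 6.0
    clustering_mode: str = "dispersed"
    cluster_count: int = 8
    cluster_sd_px: float = 40.0
    stain_intensity: float = 0.55
    background_level: float = 0.92
    vein_count: int = 0
    vein_radius_px: float = 60.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if not 0 < self.cell_radius_px < self.image_size / 2:
            raise ValueError("cell_radius_px must be in (0, image_size/2)")
        if self.clustering_mode not in ("dispersed", "clustered"):
            raise ValueError(f"unknown clustering_mode {self.clustering_mode!r}")
        if self.clustering_mode == "clustered" and self.cluster_count < 1:
            raise ValueError("clustered mode requires cluster_count >= 1")
        if not 0 < self.stain_intensity <= 1 or not 0 < self.background_level <= 1:
            raise ValueError("stain_intensity and background_level must be in (0, 1]")
        if self.noise_sd < 0 or self.cell_count < 0 or self.vein_count < 0:
            raise ValueError("counts and noise_sd must be nonnegative")
        area = self.cell_count * np.pi * self.cell_radius_px**2
        if area > self.image_size**2:
            raise ValueError(
                f"{self.cell_count} cells of radius {self.cell_radius_px} px cannot fit: "
                f"total cell area {area:.0f} exceeds image area {self.image_size ** 2}"
            )


@dataclasses.dataclass(frozen=True)
class ExpressionSimConfig:
    """Parameters of the log2 expression simulator (2x2 factorial design)."""

    n_genes: int = 2000
    n_samples_per_group: int = 3
    groups: tuple[tuple[str, str], ...] = DEFAULT_GROUPS
    n_signature_up: int = 100
    n_signature_down: int = 100
    signature_effect: float = 2.0
    n_interaction_genes: int = 400
    interaction_patterns: tuple[tuple[float, ...], ...] = DEFAULT_INTERACTION_PATTERNS
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) != 4:
            raise ValueError("exactly 4 groups (2x2 genotype x treatment) required")
        if self.n_signature_up + self.n_signature_down + self.n_interaction_genes > self.n_genes:
            raise ValueError("signature + interaction genes exceed n_genes")
        for pat in self.interaction_patterns:
            if len(pat) != len(self.groups):
                raise ValueError(
                    f"interaction pattern {pat} has length {len(pat)}, expected {len(self.groups)}"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclasses.dataclass
class HistologySample:
    """A simulated image plus its generating truth."""

    image: np.ndarray
    cells: pd.DataFrame
    vein_mask: np.ndarray
    vein_centers: np.ndarray
    clip_fraction: float
    config: HistologySimConfig


@dataclasses.dataclass
class ExpressionSample:
    """A simulated expression matrix plus its generating truth."""

    matrix: pd.DataFrame
    samples: pd.DataFrame
    gene_roles: pd.Series
    pattern_assignment: pd.Series
    config: ExpressionSimConfig


def _disk_mask(size: int, centers: np.ndarray, radius: float) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    r_int = int(np.ceil(radius)) + 1
    for cy, cx in centers:
        y0, y1 = max(0, int(cy) - r_int), min(size, int(cy) + r_int + 1)
        x0, x1 = max(0, int(cx) - r_int), min(size, int(cx) + r_int + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return mask


def _sample_positions(config: HistologySimConfig, rng: np.random.Generator,
                      vein_mask: np.ndarray) -> np.ndarray:
    """Cell centers: uniform (dispersed) or Thomas process (clustered);
    positions falling inside veins are resampled."""
    size = config.image_size
    r = config.cell_radius_px
    lo, hi = r, size - r

    parents = (
        rng.uniform(lo, hi, size=(config.cluster_count, 2))
        if config.clustering_mode == "clustered"
        else None
    )

    def draw(n: int) -> np.ndarray:
        if parents is None:
            return rng.uniform(lo, hi, size=(n, 2))
        idx = rng.integers(0, len(parents), size=n)
        pts = parents[idx] + rng.normal(0, config.cluster_sd_px, size=(n, 2))
        return np.clip(pts, lo, hi)

    pts = draw(config.cell_count)
    for _ in range(200):
        if len(pts) == 0:
            break
        inside = vein_mask[
            np.clip(pts[:, 0].astype(int), 0, size - 1),
            np.clip(pts[:, 1].astype(int), 0, size - 1),
        ]
        if not inside.any():
            break
        pts[inside] = draw(int(inside.sum()))
    else:
        raise RuntimeError("could not place all cells outside veins")
    return pts


def simulate_histology(config: HistologySimConfig) -> HistologySample:
    """Render a brightfield image of stained cells with known ground truth.

    Cells are anti-aliased filled disks (intensity falls off smoothly over
    one pixel at the rim) darker than the background; overlapping cells
    take the darker value. Veins are bright disks at ``background_level``
    containing no cells. Additive Gaussian noise is clipped to [0, 1] and
    the clipped fraction recorded.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size

    vein_centers = (
        rng.uniform(config.vein_radius_px, size - config.vein_radius_px,
                    size=(config.vein_count, 2))
        if config.vein_count
        else np.empty((0, 2))
    )
    vein_mask = _disk_mask(size, vein_centers, config.vein_radius_px)

    centers = _sample_positions(config, rng, vein_mask)
    strata_idx = rng.integers(0, 4, size=len(centers))
    depth = (strata_idx + 1) / 4.0 * config.stain_intensity

    image = np.full((size, size), config.background_level)
    r = config.cell_radius_px
    r_int = int(np.ceil(r)) + 1
    for (cy, cx), d in zip(centers, depth):
        y0, y1 = max(0, int(cy) - r_int), min(size, int(cy) + r_int + 1)
        x0, x1 = max(0, int(cx) - r_int), min(size, int(cx) + r_int + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        cover = np.clip(r + 0.5 - dist, 0.0, 1.0)
        np.minimum(
            image[y0:y1, x0:x1],
            config.background_level - d * cover,
            out=image[y0:y1, x0:x1],
        )
    image[vein_mask] = config.background_level

    if config.noise_sd > 0:
        image = image + rng.normal(0, config.noise_sd, size=image.shape)
    clipped = np.count_nonzero((image < 0) | (image > 1))
    clip_fraction = clipped / image.size
    if clip_fraction > 0:
        logger.info("simulate_histology clipped %.3g%% of pixels", 100 * clip_fraction)
    image = np.clip(image, 0.0, 1.0)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(centers)),
            "x": centers[:, 1],
            "y": centers[:, 0],
            "intensity": depth,
            "stratum": [STRATA[i] for i in strata_idx],
        }
    )
    return HistologySample(
        image=image,
        cells=cells,
        vein_mask=vein_mask,
        vein_centers=vein_centers,
        clip_fraction=clip_fraction,
        config=config,
    )


def simulate_cell_intensities(
    n_per_stratum: tuple[int, int, int, int],
    stratum_means: tuple[float, float, float, float],
    sd: float,
    seed: int = 0,
    region_id: str = "region0",
) -> pd.DataFrame:
    """Per-cell intensity table with known strata.

    Each of the four strata (neg/low/moderate/high) contributes
    ``n_per_stratum[k]`` cells with intensity ``stratum_means[k] +
    N(0, sd)``, floored at 0. Cell positions are uniform in a 500 px
    square so the table can also feed patch-restricted scoring.
    """
    if len(n_per_stratum) != 4 or len(stratum_means) != 4:
        raise ValueError("four strata required")
    if any(n < 0 for n in n_per_stratum):
        raise ValueError("negative stratum counts")
    if list(stratum_means) != sorted(stratum_means):
        raise ValueError("stratum means must be ordered increasing")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for name, n, mean in zip(STRATA, n_per_stratum, stratum_means):
        intensity = np.full(n, float(mean))
        if sd > 0:
            intensity = np.maximum(intensity + rng.normal(0, sd, size=n), 0.0)
        for val in intensity:
            rows.append((name, val))
    df = pd.DataFrame(rows, columns=["true_stratum", "intensity"])
    df.insert(0, "cell_id", np.arange(len(df)))
    df["x"] = rng.uniform(0, 500, size=len(df))
    df["y"] = rng.uniform(0, 500, size=len(df))
    df["region_id"] = region_id
    return df


def simulate_expression(config: ExpressionSimConfig) -> ExpressionSample:
    """Log2-scale expression matrix with a planted signature and planted
    genotype x treatment interaction patterns.

    Signature up-genes are shifted ``+signature_effect`` in the
    high-activity (NTC) groups and down-genes shifted ``+signature_effect``
    in the low-activity (knockout) groups, so the signed-sum activity
    score separates genotypes by construction. Interaction genes follow
    their assigned per-group template. All genes share a per-gene constant
    baseline; Gaussian noise of sd ``noise_sd`` is added on top.
    """
    rng = np.random.default_rng(config.seed)
    n_up, n_down = config.n_signature_up, config.n_signature_down
    n_int = config.n_interaction_genes
    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    sample_rows = []
    for genotype, treatment in config.groups:
        for k in range(config.n_samples_per_group):
            sample_rows.append(
                {
                    "sample": f"{genotype}_{treatment}_{k + 1}",
                    "genotype": genotype,
                    "treatment": treatment,
                    "group": f"{genotype}_{treatment}",
                }
            )
    samples = pd.DataFrame(sample_rows)
    n_samples = len(samples)
    group_of_sample = np.repeat(np.arange(4), config.n_samples_per_group)

    baseline = rng.normal(6.0, 1.0, size=config.n_genes)
    matrix = np.tile(baseline[:, None], (1, n_samples))

    roles = np.array(["background"] * config.n_genes, dtype=object)
    roles[:n_up] = "signature_up"
    roles[n_up : n_up + n_down] = "signature_down"
    roles[n_up + n_down : n_up + n_down + n_int] = "interaction"

    # genotype of each of the 4 groups; first genotype listed = high activity
    high_genotype = config.groups[0][0]
    high_sample = np.array(
        [config.groups[g][0] == high_genotype for g in group_of_sample]
    )
    matrix[:n_up][:, high_sample] += config.signature_effect
    matrix[n_up : n_up + n_down][:, ~high_sample] += config.signature_effect

    n_pat = len(config.interaction_patterns)
    pattern_idx = np.arange(n_int) % n_pat if n_int else np.empty(0, dtype=int)
    for g, p in enumerate(pattern_idx):
        template = np.asarray(config.interaction_patterns[p], dtype=float)
        matrix[n_up + n_down + g] += template[group_of_sample]

    if config.noise_sd > 0:
        matrix = matrix + rng.normal(0, config.noise_sd, size=matrix.shape)

    mat = pd.DataFrame(matrix, index=genes, columns=samples["sample"].tolist())
    gene_roles = pd.Series(roles, index=genes, name="role")
    assignment = pd.Series(
        pattern_idx, index=genes[n_up + n_down : n_up + n_down + n_int], name="pattern"
    )
    return ExpressionSample(
        matrix=mat,
        samples=samples,
        gene_roles=gene_roles,
        pattern_assignment=assignment,
        config=config,
    )
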