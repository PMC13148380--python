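"""Reusable simulation studies built from the package's own pieces.

These functions generate synthetic study conditions, run the relevant
pipeline end to end, and return summary numbers; they are used by the
validation suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import embedding, ihc, pipeline, synthetic

__all__ = ["texture_pca_separation", "anova_type1_rate"]

#: The three simulated spatial-patterning conditions: uniformly scattered
#: macrophage-like cells at low and high density, and the same high density
#: aggregated around a few foci (Thomas process), emulating dispersed vs
#: damage-clustered staining.
PCA_CONDITIONS = {
    "dispersed_sparse": dict(cell_count=300),
    "dispersed_dense": dict(cell_count=1200),
    "clustered_dense": dict(
        cell_count=1200, clustering_mode="clustered", cluster_count=8,
        cluster_sd_px=110.0,
    ),
}


def texture_pca_separation(seed: int = 0, n_per_group: int = 20) -> dict:
    """Simulate three spatial-patterning groups of images, run the full
    texture pipeline and PCA, and measure group separation.

    Returns tile- and image-level silhouette of the ground-truth groups in
    (PC1, PC2), the |Pearson r| between PC1 and the texture-mean feature,
    and the per-group means of that feature (which must decrease with cell
    density: denser staining pulls more pixels toward the dark levels).
    """
    from sklearn.metrics import silhouette_score

    frames = []
    for gi, (name, kw) in enumerate(PCA_CONDITIONS.items()):
        for rep in range(n_per_group):
            cfg = synthetic.HistologySimConfig(
                seed=int(seed) * 10007 + 1000 * gi + rep, vein_count=0, **kw
            )
            sample = synthetic.simulate_histology(cfg)
            feats = pipeline.image_features(sample.image, image_id=f"{name}_{rep}")
            feats["group"] = name
            frames.append(feats)
    df = pd.concat(frames, ignore_index=True).set_index("tile_id")
    mat = df[pipeline.feature_columns()]
    res = embedding.fit_pca(mat, standardize=True)
    sc = res.scores[["PC1", "PC2"]]
    groups = df.loc[sc.index, "group"]
    tile_sil = float(silhouette_score(sc, groups))
    per_image = sc.join(df[["image_id", "group"]]).groupby("image_id").agg(
        {"PC1": "mean", "PC2": "mean", "group": "first"}
    )
    image_sil = float(silhouette_score(per_image[["PC1", "PC2"]], per_image["group"]))
    mean_feature = mat.loc[sc.index, "mean_mean"]
    pc1_corr = float(np.corrcoef(res.scores["PC1"], mean_feature)[0, 1])
    group_means = df.groupby("group")["mean_mean"].mean().to_dict()
    return {
        "tile_silhouette": tile_sil,
        "image_silhouette": image_sil,
        "pc1_mean_feature_corr": pc1_corr,
        "group_mean_feature": group_means,
        "n_tiles": int(len(df)),
        "explained_variance_ratio": res.explained_variance_ratio[:2].tolist(),
    }


def anova_type1_rate(
    seed: int = 0,
    n_reps: int = 1000,
    n_groups: int = 4,
    n_per_group: int = 6,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo type-I error of the one-way ANOVA under a shared null
    distribution of region scores."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([f"g{i}" for i in range(n_groups)], n_per_group)
    hits = 0
    for _ in range(n_reps):
        df = pd.DataFrame(
            {"h_score": rng.normal(size=n_groups * n_per_group), "condition": labels}
        )
        hits += ihc.compare_groups(df).p < alpha
    return hits / n_reps
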