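"""Interaction-gene pattern analysis: median centering, 1 - Pearson
correlation distance, average-linkage (UPGMA) hierarchical clustering with
a fixed k-cluster cut, and per-cluster expression summaries."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "CenteredMatrix",
    "ClusterAssignment",
    "median_center",
    "correlation_distance",
    "cluster_genes",
    "cluster_profiles",
    "to_newick",
]


@dataclasses.dataclass
class CenteredMatrix:
    """Median-centered genes x samples matrix plus the subtracted medians."""

    values: pd.DataFrame
    medians: pd.Series


@dataclasses.dataclass
class ClusterAssignment:
    """Gene -> cluster labels (1..k, ordered by decreasing cluster size,
    ties broken by lowest gene identifier) plus the dendrogram."""

    labels: pd.Series
    linkage: np.ndarray
    k: int
    removed_zero_variance: list


def median_center(expr: pd.DataFrame) -> CenteredMatrix:
    """Subtract each gene's across-sample median; idempotent."""
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    med = expr.median(axis=1)
    return CenteredMatrix(values=expr.sub(med, axis=0), medians=med)


def correlation_distance(values: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Pearson(row_i, row_j) distance matrix."""
    d = 1.0 - np.corrcoef(values.to_numpy())
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def cluster_genes(centered: CenteredMatrix | pd.DataFrame, k: int = 4) -> ClusterAssignment:
    """UPGMA clustering of genes on correlation distance, cut into k clusters.

    Zero-variance genes (Pearson undefined) are removed with a report.
    The tree is cut by the k-1 highest merges (a plain k-cluster cut).
    """
    values = centered.values if isinstance(centered, CenteredMatrix) else centered
    var = values.var(axis=1, ddof=0)
    removed = var.index[var == 0].tolist()
    if removed:
        logger.info("removing %d zero-variance genes before clustering", len(removed))
        values = values.drop(index=removed)
    if len(values) < k:
        raise ValueError(f"fewer genes ({len(values)}) than clusters ({k})")
    dist = correlation_distance(values)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=values.index, name="cluster")
    # relabel: 1..k by decreasing size, ties by lowest member gene id
    order = sorted(
        labels.groupby(labels).groups.items(),
        key=lambda kv: (-len(kv[1]), min(map(str, kv[1]))),
    )
    remap = {old: new + 1 for new, (old, _) in enumerate(order)}
    labels = labels.map(remap)
    return ClusterAssignment(labels=labels, linkage=Z, k=k, removed_zero_variance=removed)


def cluster_profiles(
    centered: CenteredMatrix | pd.DataFrame,
    assignment: ClusterAssignment,
    groups: pd.Series,
) -> pd.DataFrame:
    """Median and quartiles of centered expression per cluster x sample
    group, pooled over the cluster's genes and the group's samples.

    ``groups`` maps sample name -> experimental group.
    """
    values = centered.values if isinstance(centered, CenteredMatrix) else centered
    rows = []
    for cluster in sorted(assignment.labels.unique()):
        genes = assignment.labels.index[assignment.labels == cluster]
        sub = values.loc[genes]
        for grp in pd.unique(groups):
            samples = groups.index[groups == grp]
            pool = sub[samples].to_numpy().ravel()
            q1, med, q3 = np.quantile(pool, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "cluster": cluster,
                    "group": grp,
                    "n_genes": len(genes),
                    "n_values": pool.size,
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows)


def to_newick(assignment: ClusterAssignment) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    tree = hierarchy.to_tree(assignment.linkage)
    names = list(assignment.labels.index)

    def recurse(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"
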