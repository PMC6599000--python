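"""Hierarchical grouping of subpopulations by median isotope profile.

Subpopulations are summarised by the per-isotope median of z-scaled
individual values, clustered agglomeratively on Euclidean distance under
Ward's, average or complete linkage, with the linkage chosen by
cophenetic correlation and the number of groups by mean silhouette width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .metrics import mean_silhouette

LINKAGES = ("ward", "average", "complete")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over labelled rows."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    labels: list[str]
    linkage: str

    def __post_init__(self):
        if self.linkage not in LINKAGES:
            raise ValueError(f"unsupported linkage {self.linkage!r}; use one of {LINKAGES}")
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self):
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Cluster membership (0-based) at k groups."""
        return hierarchy.cut_tree(self.linkage_matrix, n_clusters=k).ravel()

    def cophenetic_distances(self) -> np.ndarray:
        """Condensed vector of first-merge heights per leaf pair."""
        return hierarchy.cophenet(self.linkage_matrix)

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


@dataclass
class GroupAssignment:
    groups: dict[str, int]  # subpopulation -> 1-based group id
    k: int
    mean_silhouette: float

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not -1.0 <= self.mean_silhouette <= 1.0:
            raise ValueError("mean silhouette outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subpopulation": list(self.groups), "group": list(self.groups.values())}
        )


def median_profiles(records: pd.DataFrame, isotopes) -> pd.DataFrame:
    """Subpopulation x isotope matrix of medians of z-scaled values.

    Each isotope is z-scaled across all individual records first (so the
    isotopes are commensurate), then the per-subpopulation median of the
    scaled values is taken (robust to within-subpopulation outliers).
    """
    isotopes = list(isotopes)
    if records["subpopulation"].nunique() < 2:
        raise ValueError("need at least two subpopulations")
    scaled = records[["subpopulation", *isotopes]].copy()
    for iso in isotopes:
        col = scaled[iso].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"isotope {iso} has zero variance; cannot scale")
        scaled[iso] = (col - col.mean()) / sd
    return scaled.groupby("subpopulation")[isotopes].median()


def hierarchical_cluster(matrix: pd.DataFrame, linkage: str = "ward") -> Dendrogram:
    """Agglomerative clustering of profile rows on Euclidean distance."""
    if linkage not in LINKAGES:
        raise ValueError(f"unsupported linkage {linkage!r}; use one of {LINKAGES}")
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    z = hierarchy.linkage(x, method=linkage, metric="euclidean")
    return Dendrogram(z, list(matrix.index), linkage)


def cophenetic_correlation(dendrogram: Dendrogram, distances=None,
                           matrix: pd.DataFrame | None = None) -> float:
    """Pearson correlation between original and cophenetic pairwise distances."""
    if distances is None:
        if matrix is None:
            raise ValueError("provide either condensed distances or the profile matrix")
        distances = pdist(np.asarray(matrix, dtype=float))
    distances = np.asarray(distances, dtype=float)
    if len(distances) < 2:
        raise ValueError("cophenetic correlation needs at least three leaves")
    coph = dendrogram.cophenetic_distances()
    if np.std(distances) == 0 or np.std(coph) == 0:
        raise ValueError("constant distance vector; correlation undefined")
    return float(np.corrcoef(distances, coph)[0, 1])


def select_linkage(matrix: pd.DataFrame) -> tuple[Dendrogram, dict[str, float]]:
    """Fit all supported linkages; keep the one with the highest cophenetic
    correlation (ties resolved in the order ward, average, complete)."""
    dists = pdist(np.asarray(matrix, dtype=float))
    scores: dict[str, float] = {}
    best = None
    for name in LINKAGES:
        dendro = hierarchical_cluster(matrix, name)
        scores[name] = cophenetic_correlation(dendro, dists)
        if best is None or scores[name] > scores[best.linkage]:
            best = dendro
    return best, scores


def select_groups(dendrogram: Dendrogram, matrix: pd.DataFrame,
                  k_range=None) -> GroupAssignment:
    """Cut the tree at each candidate k and keep the k with the highest
    mean silhouette width on the profile matrix (ties -> smallest k)."""
    n = len(dendrogram.labels)
    if n < 3:
        raise ValueError("group selection needs at least three leaves")
    if k_range is None:
        k_range = range(2, n)
    k_range = [k for k in k_range if 2 <= k <= n]
    if not k_range:
        raise ValueError("empty k range")
    dist = squareform(pdist(np.asarray(matrix, dtype=float)))
    best_k, best_sil, best_labels = None, -np.inf, None
    for k in k_range:
        labels = dendrogram.cut(k)
        sil = mean_silhouette(dist, labels)
        if sil > best_sil + 1e-12:
            best_k, best_sil, best_labels = k, sil, labels
    groups = {name: int(g) + 1 for name, g in zip(dendrogram.labels, best_labels)}
    return GroupAssignment(groups, best_k, best_sil)
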