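"""Spatially explicit isotopic clusters from aligned isoscape stacks.

Cells of a z-scaled multi-isotope raster stack are partitioned around
medoids: PAM (BUILD greedy seeding + steepest-descent SWAP) for exact
medoid clustering, and clara (PAM on random subsamples, all points
assigned to the best subsample's medoids) for large rasters. The number
of clusters is chosen by average silhouette width over a k range, with
the total-cost curve returned for elbow inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .isoscape import RasterStack
from .metrics import mean_silhouette, silhouette_samples
from .raster import Grid, Raster


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    """Greedy cost-minimising seeding: first the point with least total
    dissimilarity, then the point giving the largest cost reduction."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.sum(np.maximum(nearest[:, None] - d, 0.0), axis=0)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, d[:, best])
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int], tol: float = 1e-12):
    """Steepest-descent medoid/non-medoid exchanges until no swap lowers
    the total cost. Returns (medoids, labels, cost)."""
    n = d.shape[0]
    medoids = list(medoids)
    while True:
        dm = d[:, medoids]  # (n, k)
        order = np.argsort(dm, axis=1)
        d1 = dm[np.arange(n), order[:, 0]]  # nearest-medoid distance
        d2 = dm[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        assigned = order[:, 0]
        best_delta, best_swap = -tol, None
        nonmedoids = np.setdiff1d(np.arange(n), medoids)
        for mi in range(len(medoids)):
            mine = assigned == mi
            for h in nonmedoids:
                dh = d[:, h]
                # points losing medoid mi move to min(dh, second-nearest);
                # others may switch to h if closer
                delta = np.where(mine, np.minimum(dh, d2), np.minimum(dh, d1)) - d1
                delta = float(delta.sum())
                if delta < best_delta:
                    best_delta, best_swap = delta, (mi, int(h))
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    dm = d[:, medoids]
    labels = np.argmin(dm, axis=1)
    cost = float(dm[np.arange(n), labels].sum())
    return medoids, labels, cost


class KMedoids(BaseEstimator, ClusterMixin):
    """Exact PAM (partitioning around medoids) on Euclidean dissimilarity.

    Deterministic given the input row order. Attributes after ``fit``:
    ``medoid_indices_``, ``labels_``, ``inertia_`` (total dissimilarity to
    assigned medoids), ``cluster_centers_``.
    """

    def __init__(self, n_clusters=2, metric="euclidean"):
        self.n_clusters = n_clusters
        self.metric = metric

    def fit(self, X, y=None, dissimilarity=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = len(X)
        if not 2 <= self.n_clusters < n:
            raise ValueError(f"need 2 <= k < n, got k={self.n_clusters}, n={n}")
        d = cdist(X, X, metric=self.metric) if dissimilarity is None else dissimilarity
        medoids = _pam_build(d, self.n_clusters)
        medoids, labels, cost = _pam_swap(d, medoids)
        self.medoid_indices_ = np.asarray(medoids)
        self.labels_ = labels
        self.inertia_ = cost
        self.cluster_centers_ = X[self.medoid_indices_]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class CLARA(BaseEstimator, ClusterMixin):
    """Clustering large applications: PAM on independent random subsamples.

    Each of ``n_draws`` subsamples of size ``draw_size`` (default 40 + 2k)
    is clustered by PAM; all points are then assigned to that draw's
    medoids and the draw with the lowest total dissimilarity wins. When a
    draw covers the whole data set this reduces to exact PAM.
    """

    def __init__(self, n_clusters=2, n_draws=5, draw_size=None, metric="euclidean",
                 random_state=0):
        self.n_clusters = n_clusters
        self.n_draws = n_draws
        self.draw_size = draw_size
        self.metric = metric
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, k = len(X), self.n_clusters
        if not 2 <= k < n:
            raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
        size = self.draw_size if self.draw_size is not None else 40 + 2 * k
        if size < k + 1:
            raise ValueError("draw_size must be at least k + 1")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_draws):
            if size >= n:
                take = np.arange(n)
            else:
                take = np.sort(rng.choice(n, size, replace=False))
            pam = KMedoids(k, metric=self.metric).fit(X[take])
            medoids = take[pam.medoid_indices_]
            dm = cdist(X, X[medoids], metric=self.metric)
            labels = np.argmin(dm, axis=1)
            cost = float(dm[np.arange(n), labels].sum())
            if best is None or cost < best[2] - 1e-12:
                best = (medoids, labels, cost)
            if size >= n:
                break  # one draw already covered everything
        self.medoid_indices_ = np.asarray(best[0])
        self.labels_ = best[1]
        self.inertia_ = best[2]
        self.cluster_centers_ = X[self.medoid_indices_]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def pam(points, k, metric="euclidean"):
    """(medoid indices, labels, total cost) by exact PAM."""
    m = KMedoids(k, metric=metric).fit(points)
    return m.medoid_indices_, m.labels_, m.inertia_


def clara(points, k, n_draws=5, draw_size=None, seed=0, metric="euclidean"):
    """(medoid indices, labels, total cost) by clara."""
    m = CLARA(k, n_draws=n_draws, draw_size=draw_size, metric=metric,
              random_state=seed).fit(points)
    return m.medoid_indices_, m.labels_, m.inertia_


def choose_k(points, k_min=2, k_max=10, method="clara", seed=0, silhouette_warn=0.3):
    """Cluster for every k in [k_min, k_max]; pick the k with the highest
    average silhouette width (ties -> smaller k). Returns
    (k_star, silhouette curve, total-cost curve) with the cost curve kept
    for elbow inspection."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if n <= k_max:
        raise ValueError(f"need more points ({n}) than k_max ({k_max})")
    d = cdist(points, points)
    sil_curve, cost_curve = {}, {}
    for k in range(k_min, k_max + 1):
        if method == "pam":
            _, labels, cost = pam(points, k)
        else:
            _, labels, cost = clara(points, k, seed=seed)
        sil_curve[k] = mean_silhouette(d, labels)
        cost_curve[k] = cost
    k_star = max(sil_curve, key=lambda k: (round(sil_curve[k], 12), -k))
    if sil_curve[k_star] < silhouette_warn:
        warnings.warn(
            f"weak cluster structure: best average silhouette "
            f"{sil_curve[k_star]:.3f} < {silhouette_warn}"
        )
    return k_star, sil_curve, cost_curve


@dataclass
class ClusterRaster:
    """Per-cell spatial cluster labels (1..k; 0 = masked) with medoids in
    z-scaled isotope space and the clustering diagnostics."""

    grid: Grid
    labels: Raster  # integer labels stored as float; NaN where masked
    medoids: np.ndarray
    k: int
    avg_silhouette: float
    cost: float
    isotopes: list[str] = dc_field(default_factory=list)

    def label_at(self, lon, lat):
        """Cluster id at each point (0 where masked or outside)."""
        v = self.labels.sample(lon, lat)
        return np.nan_to_num(v, nan=0.0).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.medoids, columns=self.isotopes,
                            index=pd.RangeIndex(1, self.k + 1, name="cluster"))


def build_cluster_raster(stack: RasterStack, isotopes=None, k="auto", seed=0,
                         k_min=2, k_max=10, method="clara") -> ClusterRaster:
    """Cluster the unmasked cells of an aligned stack in z-scaled isotope
    space and write the labels back to the grid.

    Labels are renumbered by descending cluster size so repeated runs are
    comparable. ``k="auto"`` selects k by average silhouette width.
    """
    isotopes = list(isotopes or stack.isotopes)
    x, cell_idx = stack.to_matrix(isotopes)
    if len(x) == 0:
        raise ValueError("all cells are masked")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        flat = [isotopes[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant isoscape layer(s): {flat}")
    z = (x - mu) / sd
    if k == "auto":
        k, sil_curve, _ = choose_k(z, k_min=k_min, k_max=min(k_max, len(z) - 1),
                                   method=method, seed=seed)
    k = int(k)
    if method == "pam":
        model = KMedoids(k).fit(z)
    else:
        model = CLARA(k, random_state=seed).fit(z)
    labels = model.labels_
    sil = mean_silhouette(cdist(z, z), labels)
    # renumber by descending cluster size (ties by old label for determinism)
    sizes = np.bincount(labels, minlength=k)
    new_of_old = np.empty(k, dtype=int)
    new_of_old[np.argsort(-sizes, kind="stable")] = np.arange(1, k + 1)
    relabeled = new_of_old[labels]
    order = np.argsort(new_of_old)
    medoids = model.cluster_centers_[order]
    flat = np.full(stack.grid.size, np.nan)
    flat[cell_idx] = relabeled
    return ClusterRaster(stack.grid, Raster(stack.grid, flat.reshape(stack.grid.nrows,
                                                                     stack.grid.ncols)),
                         medoids, k, sil, model.inertia_, isotopes)
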