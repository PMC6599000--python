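"""Multivariate-normal assignment of individuals to spatial isotope clusters.

Each spatial cluster is summarised by the mean vector and covariance of
the raw (unscaled) isotope profiles of the training individuals captured
inside it — individuals, not raster cells, carry the within-region
biological variance the assignment must model. A new individual is
assigned to the cluster maximising the Gaussian log-likelihood of its
isotope vector, with equal priors across clusters (forensic neutrality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, ClassifierMixin

from .clusters import ClusterRaster
from .metrics import AccuracyTable


@dataclass
class ClusterStats:
    """Gaussian summary of one spatial cluster in raw isotope space."""

    cluster: int
    mean: np.ndarray
    covariance: np.ndarray
    n_train: int

    def __post_init__(self):
        p = len(self.mean)
        if self.covariance.shape != (p, p):
            raise ValueError("covariance shape does not match mean")
        if self.n_train < p + 2:
            raise ValueError(f"cluster {self.cluster} has n_train < p + 2")


@dataclass
class AssignmentResult:
    id: str
    assigned: int
    log_likelihood: dict[int, float]
    posterior: dict[int, float]
    odds_ratio: float  # best : second-best posterior
    true_cluster: int | None = None

    def __post_init__(self):
        if abs(sum(self.posterior.values()) - 1.0) > 1e-9:
            raise ValueError("posteriors must sum to 1")
        if self.odds_ratio < 1.0 - 1e-12:
            raise ValueError("odds ratio must be >= 1")


class GaussianClusterAssigner(BaseEstimator, ClassifierMixin):
    """Equal-prior Gaussian likelihood classifier over cluster labels.

    ``fit(X, y)`` estimates per-cluster means and unbiased covariances;
    ``predict`` assigns by maximum log-density (ties -> lowest cluster id).
    """

    def __init__(self, min_n_margin: int = 2):
        self.min_n_margin = min_n_margin

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        p = X.shape[1]
        self.classes_ = np.unique(y)
        stats, chols = [], []
        starved = [int(c) for c in self.classes_ if (y == c).sum() < p + self.min_n_margin]
        if starved:
            raise ValueError(f"under-populated cluster(s): {starved}")
        for c in self.classes_:
            xc = X[y == c]
            mu = xc.mean(axis=0)
            cov = np.cov(xc, rowvar=False, ddof=1).reshape(p, p)
            try:
                cf = cho_factor(cov, lower=True)
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"cluster {c} covariance not positive-definite") from exc
            stats.append(ClusterStats(int(c), mu, cov, int(len(xc))))
            chols.append(cf)
        self.cluster_stats_ = stats
        self._chols = chols
        self._logdets = [2.0 * np.sum(np.log(np.diag(cf[0]))) for cf in chols]
        return self

    def log_likelihood(self, X):
        """Gaussian log-densities, shape (n, n_clusters)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not np.all(np.isfinite(X)):
            raise ValueError("isotope vectors must be finite")
        p = X.shape[1]
        out = np.empty((len(X), len(self.cluster_stats_)))
        for j, (st, cf) in enumerate(zip(self.cluster_stats_, self._chols)):
            d = X - st.mean
            maha = np.einsum("ij,ij->i", d, cho_solve(cf, d.T).T)
            out[:, j] = -0.5 * (p * np.log(2.0 * np.pi) + self._logdets[j] + maha)
        return out

    def predict_proba(self, X):
        ll = self.log_likelihood(X)
        ll = ll - ll.max(axis=1, keepdims=True)
        e = np.exp(ll)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.log_likelihood(X), axis=1)]


def records_cluster_labels(records: pd.DataFrame, cluster_raster: ClusterRaster):
    """Cluster id at each record's capture location (0 = masked/outside)."""
    return cluster_raster.label_at(records["lon"].to_numpy(dtype=float),
                                   records["lat"].to_numpy(dtype=float))


def cluster_stats(train_records: pd.DataFrame, cluster_raster: ClusterRaster,
                  isotopes, merge_small: bool = False) -> list[ClusterStats]:
    """Per-cluster Gaussian statistics from the training individuals.

    A record's cluster is the raster label at its capture location;
    records on masked cells are excluded (logged via warning). Clusters
    with fewer than p + 2 members raise, or with ``merge_small`` their
    members are reassigned to the cluster with the nearest medoid.
    """
    isotopes = list(isotopes)
    df = train_records.dropna(subset=isotopes).reset_index(drop=True)
    labels = records_cluster_labels(df, cluster_raster)
    if (labels == 0).any():
        warnings.warn(f"{int((labels == 0).sum())} training record(s) on masked cells excluded")
        df, labels = df[labels > 0].reset_index(drop=True), labels[labels > 0]
    if len(df) == 0:
        raise ValueError("no training records fall on unmasked cells")
    x = df[isotopes].to_numpy(dtype=float)
    p = x.shape[1]
    if merge_small:
        counts = np.bincount(labels, minlength=cluster_raster.k + 1)
        ok = [c for c in range(1, cluster_raster.k + 1) if counts[c] >= p + 2]
        if not ok:
            raise ValueError("no cluster has enough training records")
        for c in range(1, cluster_raster.k + 1):
            if counts[c] >= p + 2 or counts[c] == 0:
                continue
            med = cluster_raster.medoids
            dists = {o: float(np.linalg.norm(med[c - 1] - med[o - 1])) for o in ok}
            target = min(dists, key=dists.get)
            warnings.warn(f"cluster {c} merged into {target} (n = {counts[c]} < p + 2)")
            labels[labels == c] = target
    model = GaussianClusterAssigner().fit(x, labels)
    return model.cluster_stats_


def _assigner_from_stats(stats: list[ClusterStats]) -> GaussianClusterAssigner:
    model = GaussianClusterAssigner()
    model.classes_ = np.asarray([s.cluster for s in stats])
    model.cluster_stats_ = stats
    model._chols = [cho_factor(s.covariance, lower=True) for s in stats]
    model._logdets = [2.0 * np.sum(np.log(np.diag(cf[0]))) for cf in model._chols]
    return model


def assign_bear(stats: list[ClusterStats], y, bear_id: str = "",
                true_cluster: int | None = None) -> AssignmentResult:
    """Assign one isotope vector to the most likely cluster.

    Ties in log-likelihood go to the lowest cluster id; the odds ratio is
    the posterior ratio of the best to the second-best cluster.
    """
    model = _assigner_from_stats(stats)
    ll = model.log_likelihood(np.asarray(y, dtype=float))[0]
    post = model.predict_proba(np.asarray(y, dtype=float))[0]
    best = int(np.argmax(ll))
    order = np.argsort(-ll, kind="stable")
    second = int(order[1]) if len(order) > 1 else best
    odds = float(post[best] / post[second]) if len(order) > 1 else np.inf
    return AssignmentResult(
        id=bear_id,
        assigned=int(model.classes_[best]),
        log_likelihood={int(c): float(v) for c, v in zip(model.classes_, ll)},
        posterior={int(c): float(v) for c, v in zip(model.classes_, post)},
        odds_ratio=max(odds, 1.0),
        true_cluster=true_cluster,
    )


def assign_records(stats: list[ClusterStats], records: pd.DataFrame, isotopes,
                   cluster_raster: ClusterRaster | None = None,
                   odds_threshold: float | None = None) -> pd.DataFrame:
    """Assignment table (id, assigned, true, posteriors, odds) for many records.

    With ``odds_threshold`` set, records whose best:second posterior ratio
    falls below the threshold are left unassigned (assigned = 0).
    """
    isotopes = list(isotopes)
    df = records.dropna(subset=isotopes).reset_index(drop=True)
    model = _assigner_from_stats(stats)
    x = df[isotopes].to_numpy(dtype=float)
    ll = model.log_likelihood(x)
    post = model.predict_proba(x)
    assigned = model.classes_[np.argmax(ll, axis=1)]
    rows = pd.DataFrame({"id": df["id"], "assigned": assigned})
    if cluster_raster is not None:
        rows["true"] = records_cluster_labels(df, cluster_raster)
    for j, c in enumerate(model.classes_):
        rows[f"posterior_{c}"] = post[:, j]
    top2 = -np.sort(-post, axis=1)[:, :2]
    with np.errstate(divide="ignore"):
        rows["odds_ratio"] = np.where(top2[:, 1] > 0, top2[:, 0] / top2[:, 1], np.inf)
    if odds_threshold is not None:
        rows.loc[rows["odds_ratio"] < odds_threshold, "assigned"] = 0
    return rows


def evaluate_accuracy(test_records: pd.DataFrame, stats: list[ClusterStats],
                      cluster_raster: ClusterRaster, isotopes) -> AccuracyTable:
    """Accuracy of assigning held-out individuals to their true spatial
    cluster (the raster label at the capture location)."""
    isotopes = list(isotopes)
    df = test_records.dropna(subset=isotopes).reset_index(drop=True)
    truth = records_cluster_labels(df, cluster_raster)
    if (truth == 0).any():
        warnings.warn(f"{int((truth == 0).sum())} test record(s) on masked cells excluded")
        df, truth = df[truth > 0].reset_index(drop=True), truth[truth > 0]
    if len(df) == 0:
        raise ValueError("empty test set after masking")
    if len(np.unique(truth)) < 2:
        warnings.warn("all test records fall in a single cluster; accuracy is uninformative")
    model = _assigner_from_stats(stats)
    preds = model.predict(df[isotopes].to_numpy(dtype=float))
    classes = sorted({int(s.cluster) for s in stats} | set(np.unique(truth).tolist()))
    return AccuracyTable.from_labels(truth, preds, classes=classes)
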