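"""Clustering and classification quality measures shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def silhouette_samples(dist: np.ndarray, labels) -> np.ndarray:
    """Per-point silhouette width from a precomputed distance matrix.

    s(i) = (b - a) / max(a, b) with a the mean distance to the point's own
    cluster (excluding itself) and b the smallest mean distance to another
    cluster. Points in singleton clusters get s = 0 (convention).
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two clusters")
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    sizes = {c: len(ix) for c, ix in members.items()}
    # mean distance from every point to every cluster, in one pass
    mean_to = np.column_stack([dist[:, members[c]].mean(axis=1) for c in uniq])
    s = np.zeros(n)
    for j, c in enumerate(uniq):
        ix = members[c]
        if sizes[c] == 1:
            continue  # singleton: s = 0
        a = mean_to[ix, j] * sizes[c] / (sizes[c] - 1)  # exclude self
        b = np.min(np.delete(mean_to[ix], j, axis=1), axis=1)
        with np.errstate(invalid="ignore"):
            s[ix] = np.where(np.maximum(a, b) > 0, (b - a) / np.maximum(a, b), 0.0)
    return s


def mean_silhouette(dist: np.ndarray, labels) -> float:
    return float(np.mean(silhouette_samples(dist, labels)))


@dataclass
class AccuracyTable:
    """Confusion counts plus per-class and overall accuracy in percent."""

    confusion: pd.DataFrame  # rows = true class, columns = predicted class
    per_class: pd.Series  # percent
    overall: float  # percent
    n_per_class: pd.Series

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "AccuracyTable":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if classes is None:
            classes = np.unique(np.concatenate([y_true, y_pred]))
        classes = list(classes)
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        conf = pd.DataFrame(counts, index=classes, columns=classes)
        n = conf.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_class = 100.0 * pd.Series(np.diag(counts), index=classes) / n
        overall = 100.0 * np.trace(counts) / counts.sum()
        return cls(conf, per_class, float(overall), n)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"n": self.n_per_class, "accuracy_pct": self.per_class})
        out.loc["overall"] = [int(self.n_per_class.sum()), self.overall]
        return out
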