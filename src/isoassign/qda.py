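"""Quadratic discriminant analysis with leave-one-out cross-validation.

Each class is modelled as a multivariate Gaussian with its own mean and
covariance; a record is assigned to the class maximising

    log pi_c - 1/2 log|Sigma_c| - 1/2 (x - mu_c)' Sigma_c^-1 (x - mu_c).

Priors default to class frequencies. LOOCV refits the model on the n-1
remaining records for every held-out record and tabulates per-class and
overall accuracy in percent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, ClassifierMixin

from .metrics import AccuracyTable


class QuadraticDiscriminant(BaseEstimator, ClassifierMixin):
    """Gaussian QDA classifier.

    Parameters
    ----------
    priors : {"proportional", "uniform"} or array of shape (n_classes,)
        Class prior probabilities. "proportional" (default) uses observed
        class frequencies.
    shrinkage : float in [0, 1]
        Optional shrinkage of each class covariance toward its diagonal,
        (1 - shrinkage) * S + shrinkage * diag(S). Off (0.0) by default.

    Attributes
    ----------
    classes_ : ndarray of class labels
    means_ : (n_classes, p) class means
    covariances_ : (n_classes, p, p) unbiased class covariances
    priors_ : (n_classes,) prior probabilities
    log_dets_ : cached log-determinants of the class covariances
    """

    def __init__(self, priors="proportional", shrinkage=0.0):
        self.priors = priors
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        p = X.shape[1]
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        small = self.classes_[counts < p + 2]
        if len(small):
            raise ValueError(
                f"class(es) {list(small)} below the minimum size p + 2 = {p + 2}"
            )
        means, covs, logdets, chols = [], [], [], []
        for c in self.classes_:
            xc = X[y == c]
            mu = xc.mean(axis=0)
            s = np.cov(xc, rowvar=False, ddof=1).reshape(p, p)
            if self.shrinkage:
                s = (1.0 - self.shrinkage) * s + self.shrinkage * np.diag(np.diag(s))
            try:
                cf = cho_factor(s, lower=True)
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"singular covariance for class {c!r}") from exc
            means.append(mu)
            covs.append(s)
            chols.append(cf)
            logdets.append(2.0 * np.sum(np.log(np.diag(cf[0]))))
        self.means_ = np.asarray(means)
        self.covariances_ = np.asarray(covs)
        self.log_dets_ = np.asarray(logdets)
        self._chol_factors = chols
        if isinstance(self.priors, str):
            if self.priors == "proportional":
                self.priors_ = counts / counts.sum()
            elif self.priors == "uniform":
                self.priors_ = np.full(len(self.classes_), 1.0 / len(self.classes_))
            else:
                raise ValueError("priors must be 'proportional', 'uniform' or an array")
        else:
            self.priors_ = np.asarray(self.priors, dtype=float)
            if len(self.priors_) != len(self.classes_) or not np.isclose(self.priors_.sum(), 1.0):
                raise ValueError("priors must sum to 1 with one entry per class")
        return self

    def decision_scores(self, X):
        """log pi_c - 1/2 log|Sigma_c| - 1/2 Mahalanobis^2, shape (n, n_classes)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        scores = np.empty((len(X), len(self.classes_)))
        for j in range(len(self.classes_)):
            d = X - self.means_[j]
            maha = np.einsum("ij,ij->i", d, cho_solve(self._chol_factors[j], d.T).T)
            scores[:, j] = np.log(self.priors_[j]) - 0.5 * self.log_dets_[j] - 0.5 * maha
        return scores

    def predict(self, X):
        # argmax breaks exact ties by class order
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]

    def predict_proba(self, X):
        s = self.decision_scores(X)
        s -= s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)


def qda_fit(records: pd.DataFrame, isotopes, labels: str | np.ndarray,
            **params) -> QuadraticDiscriminant:
    """Fit QDA on complete cases of the requested isotope columns."""
    isotopes = list(isotopes)
    df = records.dropna(subset=isotopes)
    y = df[labels].to_numpy() if isinstance(labels, str) else np.asarray(labels)
    return QuadraticDiscriminant(**params).fit(df[isotopes].to_numpy(dtype=float), y)


def qda_predict(model: QuadraticDiscriminant, x):
    """(label, posterior per class) for a single complete isotope vector."""
    x = np.asarray(x, dtype=float)
    post = model.predict_proba(x[None, :])[0]
    label = model.classes_[int(np.argmax(model.decision_scores(x[None, :])[0]))]
    return label, dict(zip(model.classes_, post))


def qda_loocv(records: pd.DataFrame, isotopes, labels: str = "subpopulation",
              **params) -> AccuracyTable:
    """Leave-one-out cross-validated accuracy table.

    For every complete record the model is refit on the remaining n - 1
    records and the held-out record predicted.
    """
    isotopes = list(isotopes)
    df = records.dropna(subset=isotopes)
    X = df[isotopes].to_numpy(dtype=float)
    y = df[labels].to_numpy() if isinstance(labels, str) else np.asarray(labels)
    p = X.shape[1]
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < p + 3:
        raise ValueError(f"every class needs n >= p + 3 = {p + 3} so folds stay fittable")
    preds = np.empty(len(X), dtype=y.dtype)
    keep = np.ones(len(X), dtype=bool)
    for i in range(len(X)):
        keep[i] = False
        model = QuadraticDiscriminant(**params).fit(X[keep], y[keep])
        preds[i] = model.predict(X[i][None, :])[0]
        keep[i] = True
    return AccuracyTable.from_labels(y, preds, classes=np.unique(y))


def accuracy_by_isotope_set(records: pd.DataFrame, isotope_sets, labels="subpopulation",
                            **params) -> pd.DataFrame:
    """LOOCV accuracy table with one row per isotope combination (the
    shape of a multi-combination prediction-accuracy summary)."""
    rows = []
    for isotopes in isotope_sets:
        table = qda_loocv(records, isotopes, labels, **params)
        row = {"isotopes": "+".join(isotopes), "overall_pct": table.overall,
               "n": int(table.n_per_class.sum())}
        for cls, acc in table.per_class.items():
            row[f"{cls}_pct"] = acc
        rows.append(row)
    return pd.DataFrame(rows)
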