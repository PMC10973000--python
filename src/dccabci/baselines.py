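"""Covariance-based CSP + LDA benchmark decoder.

Common spatial patterns (CSP) computed directly from class-mean covariance
matrices: solve the generalized eigenproblem ``C1 w = lambda (C1 + C2) w``,
rank components by how far ``lambda`` sits from 0.5 (0.5 = no variance-ratio
discrimination), and keep the most discriminative filters.  Epochs are then
summarised by log-variance features ``log(w^T C w)`` and classified with
linear discriminant analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.pipeline import Pipeline

from .riemann import check_spd, karcher_mean

__all__ = [
    "CspFilters",
    "csp_fit",
    "csp_features",
    "CSP",
    "lda_fit",
    "lda_predict",
    "make_csp_lda",
]


@dataclass
class CspFilters:
    """Selected spatial filters (rows) and their generalized eigenvalues."""

    filters: np.ndarray      # (n_selected, n_channels)
    eigenvalues: np.ndarray  # in [0, 1], ordered as filters


def csp_fit(class_means: dict, n_filters: int = 3) -> CspFilters:
    """Spatial filters from two class-mean covariance matrices.

    Eigenvectors of ``C1 w = lambda (C1 + C2) w`` are normalised so that
    ``w^T (C1 + C2) w = 1``; filters are ranked by ``|lambda - 0.5|``
    descending (ties broken by eigenvalue index) and the top ``n_filters``
    kept.
    """
    if len(class_means) != 2:
        raise ValueError("CSP is defined for exactly 2 classes")
    keys = sorted(class_means)
    c1 = check_spd(class_means[keys[0]], name="class mean 1")
    c2 = check_spd(class_means[keys[1]], name="class mean 2")
    if c1.shape != c2.shape:
        raise ValueError("class means must share dimension")
    n = c1.shape[0]
    if not 1 <= n_filters <= n:
        raise ValueError(f"n_filters must be in [1, {n}]")
    comp = c1 + c2
    if np.linalg.cond(comp) > 1e12:
        raise ValueError("composite covariance is numerically singular")
    w, v = eigh(c1, comp)  # ascending lambda; v columns are comp-orthonormal
    order = np.lexsort((np.arange(n), -np.abs(w - 0.5)))[:n_filters]
    return CspFilters(filters=v[:, order].T.copy(), eigenvalues=w[order].copy())


def csp_features(C_epoch: np.ndarray, filters: CspFilters) -> np.ndarray:
    """Log-variance of an epoch covariance projected through each filter."""
    C_epoch = np.asarray(C_epoch, dtype=float)
    W = filters.filters
    if C_epoch.shape[0] != W.shape[1]:
        raise ValueError("dimension mismatch between epoch matrix and filters")
    var = np.einsum("fa,ab,fb->f", W, C_epoch, W)
    if np.any(var <= 0.0):
        raise ValueError("non-positive projected variance; input not SPD?")
    return np.log(var)


class CSP(BaseEstimator, TransformerMixin):
    """Sklearn transformer: SPD epoch matrices -> CSP log-variance features.

    Class means default to arithmetic averages of the per-epoch matrices;
    ``mean="geometric"`` switches to Karcher means.
    """

    def __init__(self, n_filters: int = 3, mean: str = "arithmetic"):
        self.n_filters = n_filters
        self.mean = mean

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("X must be a stack of square matrices")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("CSP is defined for exactly 2 classes")
        means = {}
        for cls in self.classes_:
            members = X[y == cls]
            if self.mean == "geometric":
                means[cls] = karcher_mean(list(members))
            else:
                means[cls] = members.mean(axis=0)
        self.filters_ = csp_fit(means, n_filters=self.n_filters)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.stack([csp_features(c, self.filters_) for c in X])


def lda_fit(features: np.ndarray, labels) -> LinearDiscriminantAnalysis:
    """Two-class LDA with pooled covariance (singular inputs are ridge-repaired)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need 2 classes with at least 2 examples each")
    model = LinearDiscriminantAnalysis(solver="lsqr")
    try:
        model.fit(features, labels)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; refitting with shrinkage ridge",
                      RuntimeWarning, stacklevel=2)
        model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)
        model.fit(features, labels)
    return model


def lda_predict(features: np.ndarray, model: LinearDiscriminantAnalysis):
    return model.predict(np.atleast_2d(np.asarray(features, dtype=float)))


def make_csp_lda(n_filters: int = 3, mean: str = "arithmetic") -> Pipeline:
    """The Cov-CSP-LDA benchmark as an sklearn pipeline over SPD epochs."""
    return Pipeline([
        ("csp", CSP(n_filters=n_filters, mean=mean)),
        ("lda", LinearDiscriminantAnalysis(solver="lsqr")),
    ])
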