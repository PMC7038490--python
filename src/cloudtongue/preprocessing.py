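"""Dimensionality reduction of the 10-channel e-tongue features.

The sensor array reports five taste and five aftertaste steady-state
potentials (mV).  The pipeline centres them and keeps the first two
principal components, which carry essentially all between-flavor
variance; the variance contribution rate of every component is reported
so the >= 0.85 cumulative-contribution check can be made explicit.
"""

from __future__ import annotations

import json
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import DegenerateDataError, InsufficientDataError

__all__ = ["PCPoint", "TastePCA", "fit_pca", "project"]


class PCPoint(NamedTuple):
    """A sample's coordinates in the PC plane."""

    pc1: float
    pc2: float


class TastePCA(TransformerMixin, BaseEstimator):
    """Centre-only PCA keeping ``n_components`` axes (default 2).

    Channels are centred but not scaled: the steady-state potentials share
    units (mV), so the raw covariance structure is the signal.  Loadings
    column signs are fixed so that each column's largest-magnitude entry
    is positive (eigenvectors are sign-ambiguous).

    Attributes
    ----------
    mean_ : ndarray of shape (n_channels,)
        Per-channel training mean (mV).
    loadings_ : ndarray of shape (n_channels, n_components)
        Column-orthonormal projection matrix.
    contribution_rates_ : ndarray of shape (n_channels,)
        All per-component variance fractions, descending; sums to 1.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None) -> "TastePCA":
        X = check_array(X, dtype=float, ensure_min_samples=1)
        if X.shape[0] < 3:
            raise InsufficientDataError(
                f"PCA needs >= 3 samples, got {X.shape[0]}"
            )
        if X.shape[1] < self.n_components:
            raise InsufficientDataError(
                f"need >= {self.n_components} feature columns, got {X.shape[1]}"
            )
        if not np.any(np.ptp(X, axis=0) > 0.0):
            raise DegenerateDataError("input has zero covariance")
        pca = PCA(n_components=None, svd_solver="full")
        pca.fit(X)
        comps = pca.components_[: self.n_components].copy()  # (k, p)
        # sign convention: largest-|entry| of each loading column positive
        for row in comps:
            if row[np.argmax(np.abs(row))] < 0:
                row *= -1.0
        self.mean_ = pca.mean_
        self.loadings_ = comps.T
        self.contribution_rates_ = pca.explained_variance_ratio_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return (X - self.mean_) @ self.loadings_

    # -- persistence -----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "loadings_")
        return {
            "mean": self.mean_.tolist(),
            "loadings": self.loadings_.tolist(),
            "contribution_rates": self.contribution_rates_.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "TastePCA":
        loadings = np.asarray(d["loadings"], dtype=float)
        model = cls(n_components=loadings.shape[1])
        model.mean_ = np.asarray(d["mean"], dtype=float)
        model.loadings_ = loadings
        model.contribution_rates_ = np.asarray(d["contribution_rates"], dtype=float)
        model.n_features_in_ = loadings.shape[0]
        return model

    @classmethod
    def from_json(cls, path) -> "TastePCA":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_pca(data, n_components: int = 2) -> TastePCA:
    """Fit a :class:`TastePCA` on a feature table (array or DataFrame)."""
    return TastePCA(n_components=n_components).fit(np.asarray(data, dtype=float))


def project(model: TastePCA, sample) -> PCPoint:
    """Project one feature vector into the PC plane."""
    scores = model.transform(np.asarray(sample, dtype=float).reshape(1, -1))
    return PCPoint(float(scores[0, 0]), float(scores[0, 1]))
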