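"""Standardized principal component analysis for sub-population screening.

RT-DC feature tables mix incommensurate units (μm², grayscale counts,
dimensionless ratios), so every column is z-scored before the
eigendecomposition of the covariance matrix.  Projecting onto the
leading components is a cheap screen for rare sub-populations — a small
cluster that is invisible in any single (area, deformation)-style plane
can separate cleanly in the (PC1, PC2) plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PcaModel", "StandardizedPCA", "pca_fit", "pca_project"]


@dataclass
class PcaModel:
    """Frozen result of a standardized PCA fit."""

    loadings: np.ndarray          # (k, k), columns = components
    explained_variance: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    feature_names: tuple[str, ...]


class StandardizedPCA:
    """z-score standardization followed by covariance eigendecomposition.

    scikit-learn-style transformer: ``fit(X)`` stores per-feature means
    and SDs, the orthonormal loading matrix (columns sorted by
    decreasing eigenvalue) and the explained variances; ``transform(X)``
    returns the component scores.  Component signs are fixed
    deterministically: the largest-magnitude entry of each loading
    column is made positive.
    """

    def __init__(self, feature_names: tuple[str, ...] | None = None):
        self.feature_names = feature_names

    def get_params(self, deep: bool = True) -> dict:
        return {"feature_names": self.feature_names}

    def set_params(self, **params) -> "StandardizedPCA":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "StandardizedPCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be an (n, k) matrix")
        n, k = X.shape
        if n <= k:
            raise ValueError("need more events than features")
        names = tuple(self.feature_names) if self.feature_names is not None \
            else tuple(f"f{i}" for i in range(k))
        if len(names) != k:
            raise ValueError("feature_names length does not match X")
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        const = np.flatnonzero(sd == 0)
        if const.size:
            raise ValueError(f"constant feature column: {names[const[0]]!r}")
        Z = (X - mu) / sd
        cov = np.cov(Z, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # deterministic sign: largest-|entry| of each column positive
        flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0),
                             np.arange(k)])
        evecs = evecs * np.where(flip == 0, 1.0, flip)
        self.feature_means_ = mu
        self.feature_sds_ = sd
        self.loadings_ = evecs
        self.explained_variance_ = evals
        self.feature_names_ = names
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "loadings_"):
            raise RuntimeError("fit before transform")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.loadings_.shape[0]:
            raise ValueError("dimension mismatch with the fitted model")
        Z = (X - self.feature_means_) / self.feature_sds_
        return Z @ self.loadings_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def model(self) -> PcaModel:
        return PcaModel(
            loadings=self.loadings_.copy(),
            explained_variance=self.explained_variance_.copy(),
            feature_means=self.feature_means_.copy(),
            feature_sds=self.feature_sds_.copy(),
            feature_names=self.feature_names_,
        )


def pca_fit(X, feature_names=None) -> PcaModel:
    """Functional wrapper over :class:`StandardizedPCA`."""
    return StandardizedPCA(feature_names=feature_names).fit(X).model()


def pca_project(model: PcaModel, X) -> np.ndarray:
    """Scores of ``X`` under a fitted :class:`PcaModel`."""
    est = StandardizedPCA(feature_names=model.feature_names)
    est.feature_means_ = model.feature_means
    est.feature_sds_ = model.feature_sds
    est.loadings_ = model.loadings
    est.explained_variance_ = model.explained_variance
    est.feature_names_ = model.feature_names
    return est.transform(X)
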