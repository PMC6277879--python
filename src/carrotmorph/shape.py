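"""Population-level PCA of biomass profiles with eigen-sweep reconstructions.

Shoot profiles enter raw (so PC1 captures biomass magnitude); root profiles
enter length- and width-normalized (so components capture pure contour:
taper, tip fill, mid-section thickening).  Profiles are centered but not
scaled before decomposition.  Component signs are fixed so the entry of
largest magnitude in each component is positive.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = ["ProfilePCA", "fit_population_pca", "eigen_sweep"]


class ProfilePCA(BaseEstimator, TransformerMixin):
    """Centered (unscaled) PCA over a matrix of equal-length profiles.

    Fitted attributes: ``mean_profile_`` (p,), ``components_`` (k, p)
    orthonormal rows, ``pve_`` percent variance explained per component
    (non-increasing), ``scores_`` (n, k) projections of the training set.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, profiles, y=None):
        X = np.asarray(profiles, dtype=float)
        if X.ndim != 2:
            raise ValueError("profiles must be a 2-D matrix")
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least 3 individuals")
        if np.allclose(X.var(axis=0), 0):
            raise ValueError("zero variance: all profiles identical")
        k = self.n_components or min(n - 1, p)
        k = min(k, n - 1, p)
        pca = PCA(n_components=k, svd_solver="full").fit(X)
        components = pca.components_.copy()
        scores = pca.transform(X)
        # sign convention: largest-magnitude loading positive
        for i in range(components.shape[0]):
            j = int(np.argmax(np.abs(components[i])))
            if components[i, j] < 0:
                components[i] *= -1
                scores[:, i] *= -1
        self.mean_profile_ = pca.mean_
        self.components_ = components
        self.pve_ = 100.0 * pca.explained_variance_ratio_
        self.scores_ = scores
        self.n_components_ = components.shape[0]
        return self

    def transform(self, profiles):
        check_is_fitted(self, "components_")
        X = np.asarray(profiles, dtype=float)
        return (X - self.mean_profile_) @ self.components_.T

    def inverse_transform(self, scores):
        check_is_fitted(self, "components_")
        return np.asarray(scores, dtype=float) @ self.components_ + self.mean_profile_


def fit_population_pca(profiles, n_components: int | None = None) -> ProfilePCA:
    """Fit a centered PCA over a population of biomass profiles."""
    return ProfilePCA(n_components=n_components).fit(profiles)


def eigen_sweep(pca: ProfilePCA, component: int, k_values) -> list[np.ndarray]:
    """Reconstruct profiles at mean + k * sd(scores) * component vector.

    Sweeping k in standard-deviation units visualizes what shape variation
    a component encodes; k = 0 returns the mean profile exactly.
    """
    check_is_fitted(pca, "components_")
    if not 0 <= component < pca.n_components_:
        raise IndexError(f"component {component} out of range")
    sd = float(pca.scores_[:, component].std())
    vec = pca.components_[component]
    return [pca.mean_profile_ + float(k) * sd * vec for k in k_values]
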