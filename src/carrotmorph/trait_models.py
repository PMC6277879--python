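"""Regression models predicting petiole traits from image features.

Three predictors, mirroring the two-stage phenotyping design:

* **Petiole width** — the Euclidean distance transform (EDT) of the binary
  shoot is sampled at morphological-skeleton pixels (twice the EDT value is
  the local full width); the sample distribution, summarized as a fixed-
  length normalized histogram, feeds a PLS regression against ground-truth
  widths.
* **Petiole number** — digital shoot biomass (shoot pixel count) divided by
  the predicted petiole width approximates total petiole length, which
  scales with the leaf count; the ratio feeds a PLS regression against
  hand counts.
* **Petiole length** — shoot biomass profiles are reduced by PCA and the
  scores feed a small feed-forward network (one tanh hidden layer, linear
  output) trained against ground-truth lengths.

PLS component counts are selected by leave-one-out cross-validated RMSE
(a single random holdout is available as an alternative).  All estimators
follow the sklearn fit/predict protocol and persist to versioned JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.morphology import skeletonize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted

from .imaging import PlantMask
from .morphometrics import Calibration

__all__ = [
    "WidthFeature",
    "skeleton_edt_samples",
    "width_feature",
    "petiole_count_feature",
    "PlsTraitRegressor",
    "PetioleWidthRegressor",
    "PetioleLengthRegressor",
    "fit_pls",
    "fit_length_model",
    "predict_petiole_width",
    "predict_petiole_number",
]

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------- features

@dataclass(frozen=True)
class WidthFeature:
    """Histogram descriptor of EDT values at skeleton pixels.

    descriptor sums to 1 whenever the mask had any skeleton pixels;
    edt_max_px is the largest sampled EDT value (half the widest local
    structure), n_skeleton_px the sample size.
    """

    descriptor: np.ndarray
    n_skeleton_px: int
    edt_max_px: float
    samples: np.ndarray


def skeleton_edt_samples(mask: PlantMask) -> np.ndarray:
    """EDT values at the morphological-skeleton pixels of a mask."""
    grid = mask.grid.astype(bool)
    if not grid.any():
        raise ValueError("empty mask")
    edt = distance_transform_edt(grid)
    skel = skeletonize(grid)
    return np.asarray(edt[skel], dtype=float)


def _edt_histogram(samples: np.ndarray, edt_cap: float, n_bins: int) -> np.ndarray:
    hist, _ = np.histogram(
        np.clip(samples, 0, edt_cap), bins=n_bins, range=(0.0, edt_cap))
    total = hist.sum()
    return (hist / total) if total > 0 else hist.astype(float)


def width_feature(
    shoot: PlantMask, edt_cap: float | None = None, n_bins: int = 100
) -> WidthFeature:
    """Build the petiole-width descriptor for one shoot mask.

    If ``edt_cap`` is None the histogram range is capped at this mask's own
    maximum; for model training the cap must be shared across the training
    set (the width regressor computes and stores it).
    """
    samples = skeleton_edt_samples(shoot)
    if samples.size == 0:  # single-pixel degenerate mask
        n = int(n_bins)
        return WidthFeature(np.zeros(n), 0, 0.0, samples)
    cap = float(edt_cap) if edt_cap is not None else float(samples.max())
    cap = max(cap, 1e-9)
    return WidthFeature(
        _edt_histogram(samples, cap, n_bins),
        int(samples.size), float(samples.max()), samples,
    )


def petiole_count_feature(shoot: PlantMask, predicted_width_px: float) -> float:
    """Digital shoot biomass divided by petiole width (px): the count feature.

    The ratio approximates the summed petiole length, so at a given petiole
    length it grows with the number of petioles.  An empty shoot gives 0.
    """
    if not shoot.grid.any():
        return 0.0
    if predicted_width_px <= 0:
        raise ValueError("predicted width must be positive")
    return float(shoot.foreground_count) / float(predicted_width_px)


# -------------------------------------------------------------- PLS models

class PlsTraitRegressor(BaseEstimator, RegressorMixin):
    """PLS regression with CV-selected component count.

    The number of latent components minimizing cross-validated RMSE is
    retained; ``cv="loo"`` (default) uses leave-one-out, ``cv="holdout"``
    a single random 80/20 split.  Predictions can be clamped at zero for
    physically nonnegative traits.

    Fitted attributes: ``coef_``, ``intercept_``, ``n_components_``,
    ``cv_rmse_by_k_``.
    """

    def __init__(self, max_components: int = 10, cv: str = "loo",
                 clamp_nonnegative: bool = True, target_name: str = "trait",
                 random_state: int = 0):
        self.max_components = max_components
        self.cv = cv
        self.clamp_nonnegative = clamp_nonnegative
        self.target_name = target_name
        self.random_state = random_state

    def _cv_splits(self, n):
        if self.cv == "loo":
            for i in range(n):
                test = np.zeros(n, bool)
                test[i] = True
                yield ~test, test
        elif self.cv == "holdout":
            rng = np.random.default_rng(self.random_state)
            perm = rng.permutation(n)
            n_test = max(1, n // 5)
            test = np.zeros(n, bool)
            test[perm[:n_test]] = True
            yield ~test, test
        else:
            raise ValueError("cv must be 'loo' or 'holdout'")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and targets must be row-matched")
        if X.shape[0] < 5:
            raise ValueError("need at least 5 training samples")
        n, p = X.shape
        rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
        k_max = max(1, min(self.max_components, p, n - 2, max(rank, 1)))

        cv_mse = np.full(k_max, np.nan)
        cv_se = np.full(k_max, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # PLS warns on tiny residual y
            for k in range(1, k_max + 1):
                errs = []
                for tr, te in self._cv_splits(n):
                    try:
                        m = PLSRegression(n_components=k).fit(X[tr], y[tr])
                        errs.append((m.predict(X[te]).ravel() - y[te]) ** 2)
                    except Exception:
                        errs = None
                        break
                if errs:
                    errs = np.concatenate(errs)
                    cv_mse[k - 1] = float(errs.mean())
                    cv_se[k - 1] = float(errs.std() / np.sqrt(errs.size))
            if np.all(np.isnan(cv_mse)):
                warnings.warn("degenerate features; falling back to 1 component")
                best_k = 1
            else:
                # one-SE rule: smallest k within one standard error of the
                # CV minimum (parsimony against near-flat CV curves); the
                # epsilon keeps the cutoff meaningful on noiseless targets
                i_min = int(np.nanargmin(cv_mse))
                cutoff = cv_mse[i_min] + cv_se[i_min] + 1e-10 * float(np.var(y))
                best_k = int(np.flatnonzero(cv_mse <= cutoff)[0]) + 1
            pls = PLSRegression(n_components=best_k).fit(X, y)
        self.n_components_ = best_k
        self.cv_rmse_by_k_ = np.sqrt(cv_mse)
        self.coef_ = np.ascontiguousarray(pls.coef_, dtype=float).reshape(1, -1)
        self.x_mean_ = np.ascontiguousarray(pls._x_mean, dtype=float)
        self.intercept_ = float(np.ravel(pls.intercept_)[0])
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} != trained {self.n_features_in_}")
        pred = (X - self.x_mean_) @ self.coef_.ravel() + self.intercept_
        if self.clamp_nonnegative:
            pred = np.maximum(pred, 0.0)
        return pred

    # -- persistence ------------------------------------------------------
    def to_json(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "model": "pls",
            "target_name": self.target_name,
            "params": self.get_params(),
            "n_components": self.n_components_,
            "cv_rmse_by_k": np.where(
                np.isnan(self.cv_rmse_by_k_), None, self.cv_rmse_by_k_).tolist(),
            "coef": self.coef_.ravel().tolist(),
            "x_mean": self.x_mean_.tolist(),
            "intercept": self.intercept_,
        }

    @classmethod
    def from_json(cls, blob: dict) -> "PlsTraitRegressor":
        obj = cls(**blob["params"])
        obj.coef_ = np.ascontiguousarray(blob["coef"], dtype=float).reshape(1, -1)
        obj.x_mean_ = np.ascontiguousarray(blob["x_mean"], dtype=float)
        obj.intercept_ = float(blob["intercept"])
        obj.n_components_ = int(blob["n_components"])
        obj.cv_rmse_by_k_ = np.asarray(
            [np.nan if v is None else v for v in blob["cv_rmse_by_k"]], dtype=float)
        obj.n_features_in_ = obj.coef_.size
        return obj


class PetioleWidthRegressor(PlsTraitRegressor):
    """Petiole-width PLS model over skeleton-EDT histogram descriptors.

    fit accepts a list of shoot masks (or precomputed 1-D EDT sample
    arrays) and ground-truth widths in cm.  The histogram cap is set to
    the ``cap_percentile`` of the pooled training EDT values and stored,
    so train- and predict-time descriptors share a binning.
    """

    def __init__(self, n_bins: int = 100, cap_percentile: float = 99.5,
                 max_components: int = 10, cv: str = "loo",
                 clamp_nonnegative: bool = True,
                 target_name: str = "petiole_width_cm", random_state: int = 0):
        super().__init__(max_components=max_components, cv=cv,
                         clamp_nonnegative=clamp_nonnegative,
                         target_name=target_name, random_state=random_state)
        self.n_bins = n_bins
        self.cap_percentile = cap_percentile

    @staticmethod
    def _as_samples(items) -> list[np.ndarray]:
        out = []
        for it in items:
            if isinstance(it, PlantMask):
                out.append(skeleton_edt_samples(it))
            else:
                out.append(np.asarray(it, dtype=float).ravel())
        return out

    def _descriptors(self, samples_list) -> np.ndarray:
        return np.vstack([
            _edt_histogram(s, self.edt_cap_, self.n_bins) for s in samples_list])

    def fit(self, masks_or_samples, y):
        samples = self._as_samples(masks_or_samples)
        pooled = np.concatenate([s for s in samples if s.size]) \
            if any(s.size for s in samples) else np.array([1.0])
        self.edt_cap_ = float(max(np.percentile(pooled, self.cap_percentile), 1e-9))
        X = self._descriptors(samples)
        return super().fit(X, y)

    def predict(self, masks_or_samples):
        check_is_fitted(self, "edt_cap_")
        X = self._descriptors(self._as_samples(masks_or_samples))
        return super().predict(X)

    def to_json(self) -> dict:
        blob = super().to_json()
        blob["model"] = "pls_width"
        blob["edt_cap"] = self.edt_cap_
        return blob

    @classmethod
    def from_json(cls, blob: dict) -> "PetioleWidthRegressor":
        obj = super().from_json(blob)
        obj.edt_cap_ = float(blob["edt_cap"])
        return obj


# ----------------------------------------------------------- length model

class PetioleLengthRegressor(BaseEstimator, RegressorMixin):
    """Petiole-length model: SBP -> PCA scores -> small feed-forward network.

    Shoot biomass profiles are centered and projected onto enough principal
    components to cover ``var_threshold`` of training variance (capped at
    ``max_pcs``); standardized scores feed a one-hidden-layer tanh network
    with linear output, trained by L-BFGS with a fixed seed.  Prediction
    uses the stored weights directly, so a persisted model reproduces its
    outputs bit-exactly.
    """

    def __init__(self, hidden_units: int = 10, var_threshold: float = 0.95,
                 max_pcs: int = 10, seed: int = 0, max_iter: int = 4000,
                 tol: float = 1e-7, target_name: str = "petiole_length_cm"):
        self.hidden_units = hidden_units
        self.var_threshold = var_threshold
        self.max_pcs = max_pcs
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.target_name = target_name

    def fit(self, sbps, y):
        X = np.asarray(sbps, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("profiles and targets must be row-matched")
        if X.shape[0] < 20:
            raise ValueError("need at least 20 training samples")
        cap = min(self.max_pcs, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=cap, svd_solver="full").fit(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, self.var_threshold) + 1)
        n_pcs = min(max(n_pcs, 1), cap)
        if n_pcs > X.shape[0]:
            warnings.warn("fewer samples than requested PCs; reducing")
            n_pcs = X.shape[0]
        self.pca_mean_ = np.ascontiguousarray(pca.mean_)
        self.pca_components_ = np.ascontiguousarray(pca.components_[:n_pcs])
        self.n_pcs_ = n_pcs

        scores = (X - self.pca_mean_) @ self.pca_components_.T
        self.x_mean_ = scores.mean(axis=0)
        self.x_std_ = scores.std(axis=0)
        self.x_std_[self.x_std_ == 0] = 1.0
        self.y_mean_ = float(y.mean())
        self.y_std_ = float(y.std()) or 1.0
        Z = (scores - self.x_mean_) / self.x_std_
        t = (y - self.y_mean_) / self.y_std_

        net = MLPRegressor(
            hidden_layer_sizes=(self.hidden_units,), activation="tanh",
            solver="lbfgs", max_iter=self.max_iter, tol=self.tol,
            random_state=self.seed, alpha=1e-4,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net.fit(Z, t)
        self.w1_, self.w2_ = net.coefs_
        self.b1_, self.b2_ = net.intercepts_
        return self

    def _forward(self, Z):
        h = np.tanh(Z @ self.w1_ + self.b1_)
        return (h @ self.w2_ + self.b2_).ravel()

    def predict(self, sbps):
        check_is_fitted(self, "w1_")
        X = np.asarray(sbps, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.pca_mean_.size:
            raise ValueError("profile length differs from training")
        scores = (X - self.pca_mean_) @ self.pca_components_.T
        Z = (scores - self.x_mean_) / self.x_std_
        pred = self._forward(Z) * self.y_std_ + self.y_mean_
        return np.maximum(pred, 0.0)

    def to_json(self) -> dict:
        check_is_fitted(self, "w1_")
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "model": "pca_network_length",
            "target_name": self.target_name,
            "params": self.get_params(),
            "n_pcs": self.n_pcs_,
            "pca_mean": self.pca_mean_.tolist(),
            "pca_components": self.pca_components_.tolist(),
            "x_mean": self.x_mean_.tolist(),
            "x_std": self.x_std_.tolist(),
            "y_mean": self.y_mean_,
            "y_std": self.y_std_,
            "w1": self.w1_.tolist(),
            "b1": self.b1_.tolist(),
            "w2": self.w2_.tolist(),
            "b2": self.b2_.tolist(),
        }

    @classmethod
    def from_json(cls, blob: dict) -> "PetioleLengthRegressor":
        obj = cls(**blob["params"])
        obj.n_pcs_ = int(blob["n_pcs"])
        obj.pca_mean_ = np.ascontiguousarray(blob["pca_mean"], dtype=float)
        obj.pca_components_ = np.ascontiguousarray(blob["pca_components"],
                                                   dtype=float)
        obj.x_mean_ = np.ascontiguousarray(blob["x_mean"], dtype=float)
        obj.x_std_ = np.ascontiguousarray(blob["x_std"], dtype=float)
        obj.y_mean_ = float(blob["y_mean"])
        obj.y_std_ = float(blob["y_std"])
        obj.w1_ = np.ascontiguousarray(blob["w1"], dtype=float)
        obj.b1_ = np.ascontiguousarray(blob["b1"], dtype=float)
        obj.w2_ = np.ascontiguousarray(blob["w2"], dtype=float)
        obj.b2_ = np.ascontiguousarray(blob["b2"], dtype=float)
        return obj


# ----------------------------------------------------------- thin wrappers

def fit_pls(features, targets, max_components: int = 10,
            **kwargs) -> PlsTraitRegressor:
    """Fit a PLS trait model with LOO-CV component selection."""
    return PlsTraitRegressor(max_components=max_components, **kwargs).fit(
        features, targets)


def fit_length_model(sbps, lengths, hidden_units: int = 10,
                     seed: int = 0, **kwargs) -> PetioleLengthRegressor:
    """Fit the PCA + feed-forward-network petiole length model."""
    return PetioleLengthRegressor(
        hidden_units=hidden_units, seed=seed, **kwargs).fit(sbps, lengths)


def predict_petiole_width(model: PetioleWidthRegressor, shoot,
                          cal: Calibration | None = None) -> float:
    """Predict petiole width (cm) for one shoot mask; never negative."""
    return float(model.predict([shoot])[0])


def predict_petiole_number(model: PlsTraitRegressor, ratio_feature) -> float:
    """Predict the (continuous, unrounded) petiole count from the ratio feature."""
    X = np.atleast_2d(np.asarray(ratio_feature, dtype=float))
    return float(model.predict(X)[0])


def save_model_json(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_json(), fh)


def load_model_json(path):
    with open(path) as fh:
        blob = json.load(fh)
    kinds = {
        "pls": PlsTraitRegressor,
        "pls_width": PetioleWidthRegressor,
        "pca_network_length": PetioleLengthRegressor,
    }
    return kinds[blob["model"]].from_json(blob)
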