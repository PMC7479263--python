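"""One-latent-variable partial least squares mapping of MRI features to
epithelium density, and voxel-wise prediction maps.

With a single component, PLS has a closed form: after centering and scaling
the features and centering the target, the weight vector is the normalized
feature–target covariance, w = X'y / ||X'y||; the scores are t = Xw, the
loadings p = X't/(t't) and q = y't/(t't), and the fitted map is
yhat = y_mean + q * (X - x_mean)/x_scale @ w, folded into per-feature
regression coefficients in original units. Predicted density is clipped to
[0, 1] (it is an area fraction). The consensus map is the voxel-wise mean
of the per-pathologist predicted maps.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Lesion
from .phantom import FEATURE_NAMES, DensityMap, FeatureVolume

logger = logging.getLogger(__name__)


class DegenerateModelError(ValueError):
    """The target carries no covariance with any feature."""


@dataclass
class Pls1Model:
    """Fitted one-component PLS regression in original feature units."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    w: np.ndarray
    p: np.ndarray
    q: float
    beta: np.ndarray
    intercept: float
    n_train: int
    feature_names: tuple[str, ...] = FEATURE_NAMES
    observer: str | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.beta + self.intercept

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("x_mean", "x_scale", "w", "p", "beta"):
            d[key] = [float(v) for v in d[key]]
        d["feature_names"] = list(self.feature_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Pls1Model":
        d = dict(d)
        for key in ("x_mean", "x_scale", "w", "p", "beta"):
            d[key] = np.asarray(d[key], dtype=float)
        d["feature_names"] = tuple(d["feature_names"])
        return cls(**d)


def fit_pls1(X: np.ndarray, y: np.ndarray,
             feature_names: Sequence[str] = FEATURE_NAMES,
             observer: str | None = None) -> Pls1Model:
    """Fit the single-component PLS regression.

    Features are standardized to zero mean and unit variance before the
    fit (they carry heterogeneous physical units); the returned ``beta``
    and ``intercept`` are back-transformed so that prediction is a plain
    affine map on raw features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.size != n:
        raise ValueError("X and y row counts differ")
    if n < k + 1:
        raise ValueError(f"need more training rows ({n}) than features ({k})")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training values")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    dead = np.nonzero(x_scale <= 0)[0]
    if dead.size:
        names = ", ".join(feature_names[i] for i in dead)
        raise ValueError(f"zero-variance feature(s): {names}")
    Xc = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean
    cov = Xc.T @ yc
    norm = float(np.linalg.norm(cov))
    if norm == 0.0:
        raise DegenerateModelError(
            "target has zero covariance with every feature; "
            "no one-component PLS direction exists"
        )
    w = cov / norm
    t = Xc @ w
    tt = float(t @ t)
    p = Xc.T @ t / tt
    q = float(yc @ t / tt)
    beta_std = q * w                 # yhat_c = (Xc w) q
    beta = beta_std / x_scale
    intercept = y_mean - float(x_mean @ beta)
    return Pls1Model(x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, w=w, p=p,
                     q=q, beta=beta, intercept=float(intercept), n_train=n,
                     feature_names=tuple(feature_names), observer=observer)


def fit_observer_models(table: pd.DataFrame,
                        feature_names: Sequence[str] = FEATURE_NAMES,
                        shared_rows: pd.DataFrame | None = None) -> dict[str, Pls1Model]:
    """One PLS model per observer from a pooled training table.

    ``shared_rows`` (e.g. unlabeled-consensus controls) are appended to
    every observer's training set.
    """
    cols = [f"x_{n}" for n in feature_names]
    models = {}
    for obs, sub in table.groupby("observer", sort=True):
        if shared_rows is not None:
            sub = pd.concat([sub, shared_rows], ignore_index=True)
        models[obs] = fit_pls1(sub[cols].to_numpy(), sub["y"].to_numpy(),
                               feature_names=feature_names, observer=obs)
    return models


def predict_map(model: Pls1Model, features: FeatureVolume) -> DensityMap:
    """Voxel-wise predicted density inside the prostate mask, clipped to
    [0, 1]; NaN outside the mask."""
    if tuple(features.feature_names) != tuple(model.feature_names):
        raise ValueError(
            f"feature order mismatch: model {model.feature_names} vs "
            f"volume {tuple(features.feature_names)}"
        )
    mask = features.prostate_mask
    X = features.data[mask]
    pred = model.predict(X)
    n_clip = int(np.sum((pred < 0) | (pred > 1)))
    if n_clip:
        logger.debug("clipped %d/%d predicted voxels to [0, 1]", n_clip, pred.size)
    out = np.full(mask.shape, np.nan)
    out[mask] = np.clip(pred, 0.0, 1.0)
    return DensityMap(out, role="predicted")


def consensus_map(maps: Sequence[DensityMap]) -> DensityMap:
    """Voxel-wise mean of predicted maps; mask = intersection of inputs."""
    if len(maps) == 0:
        raise ValueError("need at least one map")
    arrays = [np.asarray(m.data, float) for m in maps]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("maps have mismatched grid shapes")
    stack = np.stack(arrays)
    valid = np.all(np.isfinite(stack), axis=0)
    out = np.full(shape, np.nan)
    out[valid] = stack[:, valid].mean(axis=0)
    return DensityMap(out, role="predicted")


def roi_prediction(density_map: DensityMap, lesion: Lesion) -> float:
    """Median predicted density over a lesion's voxels."""
    if lesion.area_vox == 0:
        raise ValueError(f"lesion {lesion.lesion_id} has no voxels")
    vals = density_map.data[lesion.rows, lesion.cols]
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"lesion {lesion.lesion_id} extends outside the map mask")
    return float(np.median(vals))
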