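"""Random-forest prediction of the gaze fixation point from eye/tumor geometry.

One forest of 50 trees per output coordinate (fixation x and y on the plane
132.5 mm upstream of the isocentre); the prediction is the bagged mean of the
trees and is clamped to the feasible disk (polar angle <= 25 deg).  Features
are purely geometric and computed in the gaze-centered reference frame before
orientation: target centre of mass relative to the model centre and to the
rotation point, target bounding extremes, proximity of the target to the
critical OARs, and the tumor's height / base area / volume.  Laterality,
diagnosis and age are deliberately not features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestRegressor

from .errors import ConfigurationError, ModelError, StateError
from .eye_model import EyeModel
from .fixation import FixationPoint, clamp_to_disk
from .geometry import PLANE_DISTANCE, POLAR_MAX

FEATURE_NAMES = (
    "com_x", "com_y", "com_z",
    "com_rp_x", "com_rp_y", "com_rp_z",
    "tmin_x", "tmax_x", "tmin_y", "tmax_y", "tmin_z", "tmax_z",
    "dist_optic_disc", "dist_macula", "dist_ciliary_body",
    "height", "base_area", "volume",
)

N_TREES = 50


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple = FEATURE_NAMES


def extract_features(model: EyeModel) -> FeatureVector:
    """Geometric feature vector of one patient (gaze-centered frame).

    Order-invariant in the point clouds; for a laterality-mirrored model the
    x-coordinate features flip sign while distances are unchanged.
    """
    if not model.has_structure("target"):
        raise ModelError("cannot extract features: model has no target")
    base = model.to_base()
    target = base.points("target")
    com = target.mean(axis=0)
    rel_centre = com - base.globe_centre
    rel_rp = com - base.rotation_point
    tmin = target.min(axis=0) - base.globe_centre
    tmax = target.max(axis=0) - base.globe_centre
    dists = []
    for oar in ("optic_disc", "macula", "ciliary_body"):
        tree = cKDTree(base.points(oar))
        d, _ = tree.query(target, k=1)
        dists.append(float(d.min()))
    spec = base.tumor_spec or model.tumor_spec
    if spec is not None:
        from .eye_model import dome_volume
        shape = [spec.height, spec.base_area,
                 spec.volume if spec.volume is not None
                 else float(dome_volume(spec, base.globe_radius))]
    else:
        # empirical fallbacks from the cloud
        rho = np.linalg.norm(target - base.globe_centre, axis=1)
        height = float(base.globe_radius - rho.min())
        u = (com - base.globe_centre)
        u = u / np.linalg.norm(u)
        ang = np.arccos(np.clip((target - base.globe_centre) @ u / rho, -1, 1))
        theta_b = float(np.quantile(ang, 0.98))
        area = 2 * np.pi * base.globe_radius ** 2 * (1 - np.cos(theta_b))
        shape = [height, area, area * height / 2.0]
    vals = np.concatenate([
        rel_centre, rel_rp,
        [tmin[0], tmax[0], tmin[1], tmax[1], tmin[2], tmax[2]],
        dists, shape,
    ])
    return FeatureVector(values=vals.astype(float))


@dataclass
class ForestEnsemble:
    """One 50-tree random forest per fixation-plane coordinate."""

    forest_x: RandomForestRegressor | None = None
    forest_y: RandomForestRegressor | None = None
    seed: int = 0
    feature_names: tuple = FEATURE_NAMES
    feature_importances: dict = field(default_factory=dict)

    @property
    def trained(self) -> bool:
        return self.forest_x is not None and self.forest_y is not None


def train(features: np.ndarray, labels_xy: np.ndarray, seed: int = 0,
          n_trees: int = N_TREES, **forest_kwargs) -> ForestEnsemble:
    """Train the per-coordinate forests on (feature, fixation-label) pairs.

    ``labels_xy`` are fixation-plane coordinates in mm, shape (n, 2).
    """
    X = np.asarray(features, dtype=float)
    Y = np.asarray(labels_xy, dtype=float)
    if X.ndim != 2 or Y.shape != (X.shape[0], 2):
        raise ConfigurationError("features must be (n, f) and labels (n, 2)")
    if X.shape[0] < 10:
        raise ConfigurationError("need at least 10 training samples")
    if np.allclose(X.std(axis=0), 0.0):
        warnings.warn("all training features are constant; predictions will "
                      "collapse to the mean label", stacklevel=2)
    ens = ForestEnsemble(seed=seed)
    ens.forest_x = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                         **forest_kwargs).fit(X, Y[:, 0])
    ens.forest_y = RandomForestRegressor(n_estimators=n_trees, random_state=seed + 1,
                                         **forest_kwargs).fit(X, Y[:, 1])
    ens.feature_importances = {
        "x": dict(zip(FEATURE_NAMES, ens.forest_x.feature_importances_)),
        "y": dict(zip(FEATURE_NAMES, ens.forest_y.feature_importances_)),
    }
    return ens


def predict(ensemble: ForestEnsemble, features: FeatureVector | np.ndarray,
            plane_distance: float = PLANE_DISTANCE,
            polar_max: float = POLAR_MAX) -> FixationPoint:
    """Bagged-mean fixation prediction, clamped to the feasible disk."""
    if not ensemble.trained:
        raise StateError("ensemble has not been trained")
    vals = features.values if isinstance(features, FeatureVector) else np.asarray(features)
    X = np.atleast_2d(vals)
    x = float(ensemble.forest_x.predict(X)[0])
    y = float(ensemble.forest_y.predict(X)[0])
    return clamp_to_disk(x, y, plane_distance, polar_max)


def loo_evaluate(features: np.ndarray, labels_xy: np.ndarray, seed: int = 0,
                 **train_kwargs) -> pd.DataFrame:
    """Leave-one-out evaluation: each sample predicted by a model trained
    strictly on the remaining samples.

    Returns per-sample planar error (mm) and polar/azimuth deviations (deg).
    """
    X = np.asarray(features, dtype=float)
    Y = np.asarray(labels_xy, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ConfigurationError("leave-one-out needs at least 3 samples")
    rows = []
    for i in range(n):
        keep = np.arange(n) != i
        ens = train(X[keep], Y[keep], seed=seed, **train_kwargs)
        pred = predict(ens, X[i])
        lx, ly = Y[i]
        label = clamp_to_disk(lx, ly)
        d_az = (pred.azimuth - label.azimuth + 180.0) % 360.0 - 180.0
        rows.append({
            "sample": i,
            "pred_x_mm": pred.x,
            "pred_y_mm": pred.y,
            "planar_error_mm": float(np.hypot(pred.x - lx, pred.y - ly)),
            "polar_error_deg": pred.polar - label.polar,
            "azimuth_error_deg": d_az,
        })
    return pd.DataFrame(rows)
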