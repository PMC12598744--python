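"""Simplified passive-scattering broad-beam dose model on a voxel grid.

The beam travels along -z.  Dose at a point factorizes into

    dose = prescription * depth_factor(WED) * lateral_factor(signed distance)

where WED is the water-equivalent depth below the anterior eye surface along
the beam axis (the eye is treated as homogeneous water, its surface the globe
sphere), ``depth_factor`` is a spread-out Bragg peak plateau with logistic
fall-offs at the proximal and distal plateau edges, and ``lateral_factor`` is
a logistic profile of the signed distance to the aperture contour in the
beam-eye view (value 0.5 exactly on the contour).  Proton range and modulation
are derived per orientation from the target depth extent; the aperture is the
projected target outline expanded outward by the lateral margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon

from .errors import (AttributionError_, ConfigurationError, OcugazeError,
                     TreatabilityError)
from .eye_model import EyeModel
from .geometry import signed_distance_to_polygon

#: maximum range of 70 MeV protons in water, mm
MAX_RANGE = 35.0
#: aperture blank diameter, mm
MAX_APERTURE_DIAMETER = 35.0

# logistic scale s such that the 80-20 fall-off width w satisfies w = 2 s ln 4
_W_TO_S = 1.0 / (2.0 * np.log(4.0))


@dataclass
class BeamSpec:
    """Passive-scattering beam parameters for one candidate orientation."""

    range_mm: float                 # proton range in water
    modulation: float               # SOBP modulation length
    aperture_contour: np.ndarray    # (E, 2) closed polygon, beam-eye view, mm
    prescription: float = 60.0      # GyRBE
    n_fractions: int = 4
    distal_margin: float = 2.5
    proximal_margin: float = 2.5
    lateral_margin: float = 2.5
    distal_falloff_80_20: float = 1.0    # mm
    proximal_falloff_80_20: float = 1.0  # mm
    lateral_penumbra_80_20: float = 2.0  # mm

    def __post_init__(self):
        self.aperture_contour = np.asarray(self.aperture_contour, dtype=float)
        if self.range_mm > MAX_RANGE:
            raise TreatabilityError(
                f"required range {self.range_mm:.2f} mm exceeds the "
                f"{MAX_RANGE} mm limit of 70 MeV protons")
        if self.modulation > self.range_mm + 1e-9:
            raise TreatabilityError("modulation exceeds range")
        if _min_enclosing_radius(self.aperture_contour) > MAX_APERTURE_DIAMETER / 2 + 1e-9:
            raise TreatabilityError(
                f"aperture does not fit the {MAX_APERTURE_DIAMETER} mm diameter blank")


def _min_enclosing_radius(poly: np.ndarray) -> float:
    """Radius of the minimum enclosing circle of a polygon (Welzl via shapely)."""
    import shapely
    return float(shapely.minimum_bounding_radius(Polygon(poly)))


def derive_beam(model: EyeModel, distal_margin: float = 2.5,
                proximal_margin: float = 2.5, lateral_margin: float = 2.5,
                prescription: float = 60.0, n_fractions: int = 4,
                **falloffs) -> BeamSpec:
    """Derive range, modulation and aperture from an oriented model.

    range = deepest water-equivalent target depth + distal margin; modulation
    covers the proximal-to-distal target extent plus both margins; the aperture
    is the convex hull of the target's beam-axis projection offset outward by
    the lateral margin (rounded corners).
    """
    target = model.points("target")
    depths = water_equivalent_depth(target, model.globe_centre, model.globe_radius)
    if not np.all(np.isfinite(depths)):
        raise TreatabilityError("target extends outside the eye surface footprint")
    d_max, d_min = float(depths.max()), float(depths.min())
    rng_mm = d_max + distal_margin
    modulation = min((d_max - d_min) + distal_margin + proximal_margin, rng_mm)

    proj = target[:, :2]
    hull = ConvexHull(proj)
    hull_poly = Polygon(proj[hull.vertices])
    aperture = hull_poly.buffer(lateral_margin, quad_segs=4)
    contour = np.asarray(aperture.exterior.coords)[:-1]

    return BeamSpec(range_mm=rng_mm, modulation=modulation, aperture_contour=contour,
                    prescription=prescription, n_fractions=n_fractions,
                    distal_margin=distal_margin, proximal_margin=proximal_margin,
                    lateral_margin=lateral_margin, **falloffs)


def water_equivalent_depth(points: np.ndarray, globe_centre: np.ndarray,
                           globe_radius: float) -> np.ndarray:
    """Depth below the anterior surface along -z; NaN where the beam column
    misses the eye entirely."""
    points = np.atleast_2d(points)
    dx = points[:, 0] - globe_centre[0]
    dy = points[:, 1] - globe_centre[1]
    rho2 = dx * dx + dy * dy
    inside = rho2 <= globe_radius ** 2
    z_entry = np.full(points.shape[0], np.nan)
    z_entry[inside] = globe_centre[2] + np.sqrt(globe_radius ** 2 - rho2[inside])
    return z_entry - points[:, 2]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def dose_at_points(points: np.ndarray, beam: BeamSpec, globe_centre: np.ndarray,
                   globe_radius: float) -> np.ndarray:
    """Broad-beam dose (GyRBE) at arbitrary 3D points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    depth = water_equivalent_depth(points, globe_centre, globe_radius)
    s_d = beam.distal_falloff_80_20 * _W_TO_S
    s_p = beam.proximal_falloff_80_20 * _W_TO_S
    p0 = beam.range_mm - beam.modulation
    valid = np.isfinite(depth)
    f_depth = np.zeros(points.shape[0])
    f_depth[valid] = (_sigmoid((depth[valid] - p0) / s_p)
                      * _sigmoid((beam.range_mm - depth[valid]) / s_d))
    s_l = beam.lateral_penumbra_80_20 * _W_TO_S
    sd = signed_distance_to_polygon(points[:, :2], beam.aperture_contour)
    f_lat = _sigmoid(-sd / s_l)
    return beam.prescription * f_depth * f_lat


@dataclass
class DoseGrid:
    """Voxel dose distribution plus per-structure binary masks."""

    shape: tuple
    spacing: float              # mm / voxel (isotropic)
    origin: np.ndarray          # corner of voxel (0,0,0), mm
    dose: np.ndarray            # (nx, ny, nz) GyRBE
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    prescription: float = 60.0

    def voxel_centres(self) -> np.ndarray:
        ax = [self.origin[i] + (np.arange(self.shape[i]) + 0.5) * self.spacing
              for i in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def voxel_index(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel indices of points; raises if any fall outside the grid."""
        idx = np.floor((points - self.origin) / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise AttributionError_("points fall outside the dose grid")
        return idx

    def structure_dose(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise AttributionError_(f"no mask for structure '{name}'")
        return self.dose[self.masks[name]]


DEFAULT_GRID_SHAPE = (60, 60, 60)
DEFAULT_GRID_SPACING = 0.59


def grid_origin_for(model: EyeModel, shape=DEFAULT_GRID_SHAPE,
                    spacing: float = DEFAULT_GRID_SPACING) -> np.ndarray:
    """Grid corner placing the globe centre at the grid centre."""
    extent = np.array(shape) * spacing
    return model.globe_centre - extent / 2.0


def compute_dose_grid(model: EyeModel, beam: BeamSpec, shape=DEFAULT_GRID_SHAPE,
                      spacing: float = DEFAULT_GRID_SPACING,
                      origin: np.ndarray | None = None) -> DoseGrid:
    """Full-grid dose computation with structure masks for an oriented model."""
    if origin is None:
        origin = grid_origin_for(model, shape, spacing)
    origin = np.asarray(origin, dtype=float)
    lo = model.globe_centre - model.globe_radius
    hi = model.globe_centre + model.globe_radius
    if np.any(lo < origin) or np.any(hi > origin + np.array(shape) * spacing):
        raise ConfigurationError("dose grid does not cover the globe")
    grid = DoseGrid(shape=tuple(shape), spacing=spacing, origin=origin,
                    dose=np.zeros(shape), prescription=beam.prescription)
    # the lateral factor and surface entry depend only on the (x, y) column,
    # so evaluate them once per column and broadcast along z
    ax = [origin[i] + (np.arange(shape[i]) + 0.5) * spacing for i in range(3)]
    X, Y = np.meshgrid(ax[0], ax[1], indexing="ij")
    cols = np.column_stack([X.ravel(), Y.ravel()])
    s_l = beam.lateral_penumbra_80_20 * _W_TO_S
    sd = signed_distance_to_polygon(cols, beam.aperture_contour)
    f_lat = _sigmoid(-sd / s_l).reshape(shape[0], shape[1])
    dx = X - model.globe_centre[0]
    dy = Y - model.globe_centre[1]
    rho2 = dx * dx + dy * dy
    inside = rho2 <= model.globe_radius ** 2
    z_entry = np.full(X.shape, np.nan)
    z_entry[inside] = model.globe_centre[2] + np.sqrt(
        model.globe_radius ** 2 - rho2[inside])
    depth = z_entry[:, :, None] - ax[2][None, None, :]
    s_d = beam.distal_falloff_80_20 * _W_TO_S
    s_p = beam.proximal_falloff_80_20 * _W_TO_S
    p0 = beam.range_mm - beam.modulation
    f_depth = np.where(np.isfinite(depth),
                       _sigmoid(np.nan_to_num(depth - p0) / s_p)
                       * _sigmoid(np.nan_to_num(beam.range_mm - depth) / s_d),
                       0.0)
    grid.dose = beam.prescription * f_lat[:, :, None] * f_depth
    grid.masks = attribute_masks(model, grid)
    return grid


def attribute_masks(model: EyeModel, grid: DoseGrid) -> dict[str, np.ndarray]:
    """Rasterize each structure's points into a binary voxel occupancy mask."""
    masks = {}
    shape = np.array(grid.shape)
    for name, cloud in model.structures.items():
        idx = np.floor((cloud.points - grid.origin) / grid.spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        if not np.any(ok):
            raise AttributionError_(f"structure '{name}' lies entirely outside the grid")
        mask = np.zeros(grid.shape, dtype=bool)
        mask[idx[ok, 0], idx[ok, 1], idx[ok, 2]] = True
        masks[name] = mask
    return masks


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure.

    Carries the raw per-voxel doses (sorted descending) so that Dx%/V_D are
    exact order statistics, plus a sampled curve for plotting/export.
    """

    structure: str
    doses_desc: np.ndarray      # per-voxel doses sorted descending, GyRBE
    dose_axis: np.ndarray       # GyRBE
    volume_pct: np.ndarray      # % of structure volume receiving >= dose

    @classmethod
    def from_doses(cls, structure: str, doses: np.ndarray, n_axis: int = 201) -> "DVHCurve":
        doses = np.asarray(doses, dtype=float)
        if doses.size == 0:
            raise AttributionError_(f"empty dose sample for '{structure}'")
        asc = np.sort(doses)
        desc = asc[::-1]
        top = max(desc[0] * 1.01, 1e-6)
        axis = np.linspace(0.0, top, n_axis)
        n = asc.size
        vol = 100.0 * ((n - np.searchsorted(asc, axis, side="left")) / n)
        return cls(structure=structure, doses_desc=desc, dose_axis=axis, volume_pct=vol)

    def volumes_at(self, dose_levels: np.ndarray) -> np.ndarray:
        """V_D (%) for an array of dose levels, by binary search; the arithmetic
        (100 times the count fraction) matches the definition digit-for-digit."""
        asc = self.doses_desc[::-1]
        n = asc.size
        return 100.0 * ((n - np.searchsorted(asc, dose_levels, side="left")) / n)


def dvh(grid: DoseGrid, structure: str) -> DVHCurve:
    """Cumulative DVH of a structure from its mask voxels."""
    return DVHCurve.from_doses(structure, grid.structure_dose(structure))


def dose_at_volume(curve: DVHCurve, x_pct: float) -> float:
    """D_x%: minimum dose received by the hottest x% of the structure volume."""
    if not 0.0 < x_pct <= 100.0:
        raise OcugazeError(f"volume percentage {x_pct} outside (0, 100]")
    n = curve.doses_desc.size
    k = int(np.ceil(x_pct / 100.0 * n))
    return float(curve.doses_desc[max(k, 1) - 1])


def volume_at_dose(curve: DVHCurve, dose_gy: float) -> float:
    """V_D: percentage of the structure volume receiving at least ``dose_gy``."""
    if dose_gy < 0:
        raise OcugazeError(f"dose level {dose_gy} GyRBE is negative")
    return float(curve.volumes_at(np.array([dose_gy]))[0])


def export_dvh_csv(curve: DVHCurve, path) -> None:
    """Two-column CSV export (dose GyRBE, volume %)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["dose_gyrbe", "volume_pct"])
        for d, v in zip(curve.dose_axis, curve.volume_pct):
            w.writerow([f"{d:.6g}", f"{v:.6g}"])
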