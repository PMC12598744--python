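"""Parametric eye/tumor geometry, gaze-dependent orientation and the synthetic cohort.

The patient model is a set of per-structure 3D point clouds in a gaze-centered
frame: primary gaze along +z (cornea anterior at +z), globe centre at the
origin before orientation, nasal direction +x for a right eye (mirrored in x
for a left eye).  Orienting the model rotates it about its rotation point so
that the gaze vector points at a fixation point on the plane z = +132.5 mm,
then translates it rigidly so the target centre of mass sits at the isocentre
(the origin).

The tumor is modelled as a dome following the inner eye wall: the intersection
of the eye ball with a second sphere chosen so that the dome's base is a
spherical patch of the requested area on the wall and its apex reaches the
requested radial height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, FeasibilityError, GeometryError, ModelError
from .fixation import FixationPoint
from .geometry import (POLAR_MAX, fibonacci_sphere, rotation_between,
                       sample_cap_directions, sample_shell_radii, unit)

STRUCTURE_LABELS = ("globe", "retina", "lens", "cornea", "ciliary_body",
                    "macula", "optic_disc", "target")
OAR_LABELS = ("retina", "lens", "cornea", "ciliary_body", "macula", "optic_disc")

#: maximum admissible distance of any model point from the globe centre, mm
MODEL_EXTENT_LIMIT = 25.0


@dataclass
class StructureCloud:
    """A named anatomical structure represented as a 3D point cloud (mm)."""

    name: str
    points: np.ndarray  # (N, 3) float64

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.shape[0] == 0:
            raise ModelError(f"structure '{self.name}' has no points")
        if not np.all(np.isfinite(self.points)):
            raise ModelError(f"structure '{self.name}' contains non-finite coordinates")


@dataclass
class OrientationState:
    """Rigid transform realizing a gaze orientation: rotation about the rotation
    point followed by a translation bringing the target COM to the isocentre."""

    polar: float
    azimuth: float
    translation: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    rotation_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        rp = self.rotation_point
        return (points - rp) @ self.rotation.T + rp + self.translation

    def invert(self, points: np.ndarray) -> np.ndarray:
        rp = self.rotation_point
        return (points - rp - self.translation) @ self.rotation + rp


@dataclass
class TumorSpec:
    """Dome-shaped target on the inner eye wall.

    ``latitude`` is the elevation of the base centre from the equatorial plane
    (degrees; -90 = posterior pole, +90 = anterior pole), ``longitude`` the
    azimuth about the gaze axis (0 deg along +x).  ``volume`` may be left None,
    in which case the closed-form dome volume is used.
    """

    height: float            # mm, apex height measured radially from the wall
    base_area: float         # mm^2, spherical contact patch area on the wall
    latitude: float          # degrees
    longitude: float         # degrees
    volume: float | None = None  # mm^3

    def base_direction(self) -> np.ndarray:
        lat = np.radians(self.latitude)
        lon = np.radians(self.longitude)
        return np.array([np.cos(lat) * np.cos(lon),
                         np.cos(lat) * np.sin(lon),
                         np.sin(lat)])


@dataclass
class EyeModel:
    """Per-structure point clouds plus the rigid-body state of the eye."""

    structures: dict[str, StructureCloud]
    rotation_point: np.ndarray
    globe_radius: float
    globe_centre: np.ndarray
    laterality: str = "right"
    orientation: OrientationState | None = None
    tumor_spec: TumorSpec | None = None

    def __post_init__(self):
        self.rotation_point = np.asarray(self.rotation_point, dtype=float)
        self.globe_centre = np.asarray(self.globe_centre, dtype=float)

    # -- access helpers -------------------------------------------------
    def points(self, name: str) -> np.ndarray:
        try:
            return self.structures[name].points
        except KeyError:
            raise ModelError(f"model has no structure '{name}'") from None

    def has_structure(self, name: str) -> bool:
        return name in self.structures

    def target_com(self) -> np.ndarray:
        return self.points("target").mean(axis=0)

    def copy(self) -> "EyeModel":
        return EyeModel(
            structures={k: StructureCloud(k, v.points.copy())
                        for k, v in self.structures.items()},
            rotation_point=self.rotation_point.copy(),
            globe_radius=self.globe_radius,
            globe_centre=self.globe_centre.copy(),
            laterality=self.laterality,
            orientation=self.orientation,
            tumor_spec=self.tumor_spec,
        )

    def validate(self, require_target: bool = True) -> None:
        labels = set(STRUCTURE_LABELS) if require_target else set(STRUCTURE_LABELS) - {"target"}
        missing = labels - set(self.structures)
        if missing:
            raise ModelError(f"model missing structures: {sorted(missing)}")
        for cloud in self.structures.values():
            d = np.linalg.norm(cloud.points - self.globe_centre, axis=1)
            if d.max() > MODEL_EXTENT_LIMIT:
                raise ModelError(
                    f"structure '{cloud.name}' extends {d.max():.2f} mm from the "
                    f"globe centre (limit {MODEL_EXTENT_LIMIT} mm)")
        if np.linalg.norm(self.rotation_point - self.globe_centre) > self.globe_radius:
            raise ModelError("rotation point lies outside the globe")
        if require_target:
            dt = np.linalg.norm(self.points("target") - self.globe_centre, axis=1)
            if dt.max() > self.globe_radius + 1e-6:
                raise ModelError("target points lie outside the globe")

    def to_base(self) -> "EyeModel":
        """Return the model in the gaze-centered (un-oriented) frame."""
        if self.orientation is None:
            return self.copy()
        st = self.orientation
        m = self.copy()
        for cloud in m.structures.values():
            cloud.points = st.invert(cloud.points)
        m.rotation_point = st.invert(self.rotation_point[None])[0]
        m.globe_centre = st.invert(self.globe_centre[None])[0]
        m.orientation = None
        return m


@dataclass
class EyeGeometryParams:
    """Anatomy placement parameters (all configurable; defaults are a schematic
    adult eye).  Angles in degrees, lengths in mm, counts at density 1.0."""

    retina_thickness: float = 0.3
    retina_extent: float = 115.0        # polar angle from the posterior pole
    cornea_half_angle: float = 24.0     # cap about the anterior pole
    cornea_thickness: float = 0.6
    lens_depth: float = 5.3             # globe surface (anterior pole) to lens centre
    lens_semi_axes: tuple = (4.5, 4.5, 2.25)
    ciliary_band: tuple = (40.0, 58.0)  # polar angles from the anterior pole
    ciliary_thickness: float = 1.0
    macula_offset: float = 2.0          # temporal tilt from the posterior pole
    macula_radius_angle: float = 4.0    # angular radius of the macular patch
    disc_nasal_offset: float = 16.5     # nasal tilt of the optic disc from the pole
    disc_superior_offset: float = 1.5
    disc_radius_angle: float = 3.6
    n_globe: int = 700
    n_retina: int = 900
    n_lens: int = 250
    n_cornea: int = 220
    n_ciliary: int = 220
    n_macula: int = 70
    n_optic_disc: int = 70


def build_parametric_eye(globe_radius: float = 12.0, laterality: str = "right",
                         params: EyeGeometryParams | None = None,
                         seed: int = 0, density: float = 1.0) -> EyeModel:
    """Construct a schematic eye model (without target) in the gaze-centered frame.

    ``density`` scales all point counts; the globe surface uses a deterministic
    Fibonacci lattice, interior structures are seeded volume samples.
    """
    if not 10.0 <= globe_radius <= 14.0:
        raise ConfigurationError(f"globe_radius {globe_radius} mm outside [10, 14] mm")
    if laterality not in ("left", "right"):
        raise ConfigurationError(f"laterality must be 'left' or 'right', got {laterality!r}")
    p = params or EyeGeometryParams()
    for name in ("retina_thickness", "cornea_thickness", "lens_depth"):
        if getattr(p, name) is None:
            raise ConfigurationError(f"missing structure parameter '{name}'")
    rng = np.random.default_rng(seed)
    R = globe_radius
    n = lambda k: max(12, int(round(k * density)))
    ant = np.array([0.0, 0.0, 1.0])    # anterior (gaze) axis
    post = -ant

    structures: dict[str, StructureCloud] = {}
    structures["globe"] = StructureCloud("globe", fibonacci_sphere(n(p.n_globe), R))

    # retina: inner shell from the posterior pole up to retina_extent
    dirs = sample_cap_directions(rng, n(p.n_retina), post, p.retina_extent)
    radii = sample_shell_radii(rng, n(p.n_retina), R - p.retina_thickness, R)
    structures["retina"] = StructureCloud("retina", dirs * radii[:, None])

    # cornea: anterior cap of the wall shell
    dirs = sample_cap_directions(rng, n(p.n_cornea), ant, p.cornea_half_angle)
    radii = sample_shell_radii(rng, n(p.n_cornea), R - p.cornea_thickness, R)
    structures["cornea"] = StructureCloud("cornea", dirs * radii[:, None])

    # lens: oblate ellipsoid behind the cornea
    a, b, c = p.lens_semi_axes
    u = rng.standard_normal((n(p.n_lens), 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    rr = rng.uniform(0, 1, n(p.n_lens)) ** (1 / 3)
    pts = u * rr[:, None] * np.array([a, b, c])
    pts[:, 2] += R - p.lens_depth
    structures["lens"] = StructureCloud("lens", pts)

    # ciliary body: annular band on the inner wall around the lens equator
    lo, hi = p.ciliary_band
    cos_lo, cos_hi = np.cos(np.radians(lo)), np.cos(np.radians(hi))
    z = rng.uniform(cos_hi, cos_lo, n(p.n_ciliary))
    phi = rng.uniform(0, 2 * np.pi, n(p.n_ciliary))
    s = np.sqrt(1 - z * z)
    dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    radii = sample_shell_radii(rng, n(p.n_ciliary), R - p.ciliary_thickness - 0.2, R - 0.2)
    structures["ciliary_body"] = StructureCloud("ciliary_body", dirs * radii[:, None])

    # macula: patch slightly temporal to the posterior pole; optic disc nasal of it.
    # nasal = +x in the right-eye frame, temporal = -x.
    mac_dir = _tilt(post, np.array([-1.0, 0.0, 0.0]), p.macula_offset)
    dirs = sample_cap_directions(rng, n(p.n_macula), mac_dir, p.macula_radius_angle)
    radii = sample_shell_radii(rng, n(p.n_macula), R - 0.45, R - 0.1)
    structures["macula"] = StructureCloud("macula", dirs * radii[:, None])

    disc_dir = _tilt(post, np.array([1.0, 0.0, 0.0]), p.disc_nasal_offset - p.macula_offset)
    disc_dir = _tilt(disc_dir, np.array([0.0, 1.0, 0.0]), p.disc_superior_offset)
    dirs = sample_cap_directions(rng, n(p.n_optic_disc), disc_dir, p.disc_radius_angle)
    radii = sample_shell_radii(rng, n(p.n_optic_disc), R - 0.45, R - 0.1)
    structures["optic_disc"] = StructureCloud("optic_disc", dirs * radii[:, None])

    if laterality == "left":
        for cloud in structures.values():
            cloud.points = cloud.points * np.array([-1.0, 1.0, 1.0])

    return EyeModel(structures=structures, rotation_point=np.zeros(3),
                    globe_radius=globe_radius, globe_centre=np.zeros(3),
                    laterality=laterality)


def _tilt(axis: np.ndarray, toward: np.ndarray, angle_deg: float) -> np.ndarray:
    """Tilt a unit vector by ``angle_deg`` toward another direction."""
    perp = toward - np.dot(toward, axis) * axis
    perp = unit(perp)
    a = np.radians(angle_deg)
    return unit(np.cos(a) * axis + np.sin(a) * perp)


# ---------------------------------------------------------------------------
# Tumor dome geometry
# ---------------------------------------------------------------------------

def _dome_geometry(spec: TumorSpec, R: float):
    """Solve the dome construction: returns (theta_b, sagitta, z2, R2).

    theta_b: angular radius of the base patch; z2 the signed position of the
    second sphere's centre along the base axis; R2 its radius.  For a dome of
    height exactly equal to the base sagitta the cap is a plane (z2, R2 = inf).
    """
    cos_tb = 1.0 - spec.base_area / (2.0 * np.pi * R * R)
    if cos_tb < 0.0:
        raise GeometryError(
            f"tumor base area {spec.base_area:.1f} mm^2 exceeds a hemisphere "
            f"of the globe (radius {R} mm)")
    if not 0.0 < spec.height <= R:
        raise GeometryError(f"tumor height {spec.height} mm not in (0, {R}] mm")
    theta_b = float(np.arccos(cos_tb))
    sagitta = R * (1.0 - cos_tb)
    h = spec.height
    zb = R * cos_tb
    denom = (R - h) - zb          # = sagitta - h
    if abs(denom) < 1e-9 * R:
        return theta_b, sagitta, np.inf, np.inf
    z2 = ((R - h) ** 2 - R * R) / (2.0 * denom)
    R2 = abs((R - h) - z2)
    return theta_b, sagitta, z2, R2


def _sphere_cap_volume(R: float, s: float) -> float:
    """Volume of a spherical cap of sagitta ``s`` on a sphere of radius ``R``."""
    return np.pi * s * s * (3.0 * R - s) / 3.0


def _lens_volume(R1: float, R2: float, d: float) -> float:
    """Volume of the intersection of two balls with centre distance ``d``."""
    return (np.pi * (R1 + R2 - d) ** 2
            * (d * d + 2 * d * R2 - 3 * R2 * R2 + 2 * d * R1 + 6 * R1 * R2 - 3 * R1 * R1)
            / (12.0 * d))


def dome_volume(spec: TumorSpec, globe_radius: float) -> float:
    """Closed-form volume of the tumor dome (mm^3)."""
    theta_b, sagitta, z2, R2 = _dome_geometry(spec, globe_radius)
    R = globe_radius
    h = spec.height
    if np.isinf(R2):
        return _sphere_cap_volume(R, sagitta)
    if h > sagitta:
        # dome bulging inward beyond the base plane: ball-ball intersection
        return _lens_volume(R, R2, z2)
    # shallow dome: everything of the eye ball outside the second sphere
    return (4.0 / 3.0) * np.pi * R ** 3 - _lens_volume(R, R2, abs(z2))


def dome_contains(points: np.ndarray, spec: TumorSpec, globe_radius: float) -> np.ndarray:
    """Boolean mask of points (eye-centered frame) lying inside the tumor dome."""
    R = globe_radius
    theta_b, sagitta, z2, R2 = _dome_geometry(spec, R)
    u = spec.base_direction()
    rho = np.linalg.norm(points, axis=1)
    inside_ball = rho <= R + 1e-9
    if np.isinf(R2):
        return inside_ball & (points @ u >= R * np.cos(theta_b) - 1e-9)
    c2 = z2 * u
    d2 = np.linalg.norm(points - c2, axis=1)
    if spec.height > sagitta:
        return inside_ball & (d2 <= R2 + 1e-9)
    return inside_ball & (d2 >= R2 - 1e-9)


def place_tumor(model: EyeModel, spec: TumorSpec, n_points: int = 400,
                seed: int = 0, rel_tol: float = 0.10) -> EyeModel:
    """Add a dome-shaped target to a model; returns a new model.

    The realized point cloud is rejection-sampled uniformly within the dome;
    empirical height is checked against the spec within ``rel_tol``.
    """
    theta_b, sagitta, z2, R2 = _dome_geometry(spec, model.globe_radius)
    R = model.globe_radius
    rng = np.random.default_rng(seed)
    u_axis = spec.base_direction()
    pts = []
    need = n_points
    for _ in range(200):
        m = max(4 * need, 128)
        dirs = sample_cap_directions(rng, m, u_axis, np.degrees(theta_b))
        radii = sample_shell_radii(rng, m, R - spec.height, R)
        cand = dirs * radii[:, None]
        keep = dome_contains(cand, spec, R)
        pts.append(cand[keep])
        need = n_points - sum(len(a) for a in pts)
        if need <= 0:
            break
    cloud = np.concatenate(pts)[:n_points]
    if cloud.shape[0] < n_points:
        raise GeometryError("tumor rejection sampling failed to converge")
    # pin the apex so the realized height matches the spec exactly even at low
    # point counts (the apex sliver is rarely hit by uniform sampling)
    cloud[-1] = (R - spec.height) * u_axis
    # sampled in the eye-centered frame; shift by the globe centre
    cloud = cloud + model.globe_centre

    realized_height = R - np.linalg.norm(cloud - model.globe_centre, axis=1).min()
    if abs(realized_height - spec.height) > rel_tol * spec.height:
        warnings.warn(
            f"realized tumor height {realized_height:.2f} mm deviates more than "
            f"{rel_tol:.0%} from spec {spec.height:.2f} mm", stacklevel=2)

    out = model.copy()
    out.structures["target"] = StructureCloud("target", cloud)
    out.tumor_spec = replace(spec, volume=spec.volume if spec.volume is not None
                             else float(dome_volume(spec, R)))
    return out


def tumor_metrics(model: EyeModel) -> dict:
    """Empirical target metrics from the point cloud (mm / mm^2 / mm^3) plus
    analytic values when a TumorSpec is attached."""
    base = model.to_base()
    pts = base.points("target") - base.globe_centre
    rho = np.linalg.norm(pts, axis=1)
    R = model.globe_radius
    out = {"height_empirical": float(R - rho.min())}
    if model.tumor_spec is not None:
        spec = model.tumor_spec
        out["height"] = spec.height
        out["base_area"] = spec.base_area
        out["volume"] = float(spec.volume if spec.volume is not None
                              else dome_volume(spec, R))
    for oar in ("macula", "optic_disc", "ciliary_body"):
        out[f"distance_to_{oar}"] = structure_distance(model, "target", oar)
    return out


def structure_distance(model: EyeModel, a: str, b: str) -> float:
    """Minimum point-to-point distance between two structures (mm)."""
    pa, pb = model.points(a), model.points(b)
    tree = cKDTree(pb)
    d, _ = tree.query(pa, k=1)
    return float(d.min())


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def orient_model(model: EyeModel, fixation: FixationPoint) -> tuple[EyeModel, OrientationState]:
    """Orient the eye toward a fixation point and align the target to the isocentre.

    The rotation about the rotation point takes the primary gaze axis (+z of
    the gaze-centered frame) onto the gaze vector; the subsequent rigid
    translation brings the target centre of mass to the origin.  The input
    model is not modified; orientation is always computed from the
    gaze-centered frame, so re-orienting an oriented model is exact.
    """
    if fixation.polar > POLAR_MAX + 1e-9:
        raise FeasibilityError(
            f"fixation polar angle {fixation.polar:.3f} deg exceeds {POLAR_MAX} deg")
    base = model.to_base()
    g = fixation.gaze_vector()
    Rm = rotation_between(np.array([0.0, 0.0, 1.0]), g)
    rp = base.rotation_point
    # rotate, then translate target COM to the origin
    com = (base.target_com() - rp) @ Rm.T + rp
    t = -com
    state = OrientationState(polar=fixation.polar, azimuth=fixation.azimuth,
                             translation=t, rotation=Rm, rotation_point=rp.copy())
    out = base
    for cloud in out.structures.values():
        cloud.points = state.apply(cloud.points)
    out.globe_centre = state.apply(out.globe_centre[None])[0]
    out.rotation_point = state.apply(out.rotation_point[None])[0]
    out.orientation = state
    return out, state


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------

#: anatomical variability emulated by the cohort generator (min, max)
COHORT_RANGES = {
    "height": (2.35, 11.50),       # mm
    "base_area": (34.20, 671.65),  # mm^2
    "volume": (57.67, 2795.21),    # mm^3
}


def synthesize_cohort(n: int, seed: int = 0, density: float = 1.0,
                      tumor_points: int = 400) -> list[tuple[EyeModel, TumorSpec]]:
    """Generate ``n`` synthetic patients with tumor metrics inside the emulated
    clinical ranges and a mix of posterior and equator-spanning target sites."""
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    h_lo, h_hi = COHORT_RANGES["height"]
    a_lo, a_hi = COHORT_RANGES["base_area"]
    v_lo, v_hi = COHORT_RANGES["volume"]
    for i in range(n):
        globe_radius = float(rng.uniform(11.0, 13.0))
        laterality = "right" if rng.uniform() < 0.5 else "left"
        # rejection-sample (height, base area) until the implied dome volume
        # also falls inside the emulated clinical range
        while True:
            height = float(rng.uniform(h_lo, h_hi))
            base_area = float(rng.uniform(a_lo, a_hi))
            # posterior-equator in ~2/3 of patients, equator-spanning otherwise
            if rng.uniform() < 2.0 / 3.0:
                latitude = float(rng.uniform(-85.0, -15.0))
            else:
                latitude = float(rng.uniform(-15.0, 35.0))
            longitude = float(rng.uniform(0.0, 360.0))
            spec = TumorSpec(height=height, base_area=base_area,
                             latitude=latitude, longitude=longitude)
            try:
                vol = dome_volume(spec, globe_radius)
            except GeometryError:
                continue
            if v_lo <= vol <= v_hi:
                spec = replace(spec, volume=float(vol))
                break
        sub = int(rng.integers(0, 2 ** 31 - 1))
        model = build_parametric_eye(globe_radius=globe_radius, laterality=laterality,
                                     seed=sub, density=density)
        model = place_tumor(model, spec, n_points=tumor_points, seed=sub + 1)
        cohort.append((model, spec))
    return cohort
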