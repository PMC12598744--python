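"""Low-level geometric primitives shared by the eye model, dose engine and sampler.

All coordinates are millimetres.  The global frame convention: isocentre at the
origin, the treatment beam travels along -z (entering from the +z side where the
gaze fixation plane sits at z = +132.5 mm), azimuth 0 deg along +x measured
counterclockwise as seen from the fixation plane.
"""

from __future__ import annotations

import numpy as np

#: distance from isocentre to the gaze fixation plane, mm
PLANE_DISTANCE = 132.5
#: clinical polar-angle limit, degrees
POLAR_MAX = 25.0


def feasible_disk_radius(plane_distance: float = PLANE_DISTANCE,
                         polar_max: float = POLAR_MAX) -> float:
    """Radius on the fixation plane subtended by the polar-angle limit."""
    return plane_distance * np.tan(np.radians(polar_max))


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector ``a`` onto unit vector ``b``.

    Rodrigues construction about the axis a x b; for (anti)parallel inputs the
    identity (or a 180 deg flip about a perpendicular axis) is returned.
    """
    a = unit(a)
    b = unit(b)
    c = float(np.dot(a, b))
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis perpendicular to a
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = unit(np.cross(a, perp))
        K = _skew(axis)
        return np.eye(3) + 2.0 * K @ K
    axis = axis / s
    K = _skew(axis)
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Deterministic, near-uniform points on a sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return radius * np.column_stack([np.sin(phi) * np.cos(theta),
                                     np.sin(phi) * np.sin(theta),
                                     np.cos(phi)])


def sample_cap_directions(rng: np.random.Generator, n: int, axis: np.ndarray,
                          half_angle_deg: float) -> np.ndarray:
    """Uniform directions within the spherical cap of the given half-angle about ``axis``."""
    cos_min = np.cos(np.radians(half_angle_deg))
    z = rng.uniform(cos_min, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - z * z)
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    R = rotation_between(np.array([0.0, 0.0, 1.0]), axis)
    return local @ R.T


def sample_shell_radii(rng: np.random.Generator, n: int,
                       r_inner: float, r_outer: float) -> np.ndarray:
    """Radii distributed so points are uniform in 3D volume within the shell."""
    u = rng.uniform(r_inner ** 3, r_outer ** 3, n)
    return np.cbrt(u)


def polygon_area(poly: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as (E, 2) vertices."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def points_in_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (ray crossing) point-in-polygon test, vectorized over points."""
    x = points[:, 0][:, None]
    y = points[:, 1][:, None]
    x1, y1 = poly[:, 0][None, :], poly[:, 1][None, :]
    x2, y2 = np.roll(poly[:, 0], -1)[None, :], np.roll(poly[:, 1], -1)[None, :]
    straddle = (y1 <= y) != (y2 <= y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
    crossing = straddle & (x < xint)
    return np.sum(crossing, axis=1) % 2 == 1


def distance_to_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Unsigned Euclidean distance from each 2D point to the polygon boundary."""
    if points.shape[0] > 20000:  # bound temporary (N, E, 2) arrays
        return np.concatenate([distance_to_polygon(c, poly)
                               for c in np.array_split(points, points.shape[0] // 20000 + 1)])
    p = points[:, None, :]                       # (N, 1, 2)
    a = poly[None, :, :]                         # (1, E, 2)
    b = np.roll(poly, -1, axis=0)[None, :, :]
    ab = b - a
    ap = p - a
    denom = np.sum(ab * ab, axis=2)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.sum(ap * ab, axis=2) / denom, 0.0, 1.0)
    proj = a + t[:, :, None] * ab
    d = np.linalg.norm(p - proj, axis=2)
    return d.min(axis=1)


def signed_distance_to_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Signed distance to the polygon boundary: positive outside, negative inside."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = distance_to_polygon(points, poly)
    inside = points_in_polygon(points, poly)
    return np.where(inside, -d, d)


def circle_lattice(radius: float, spacing: float) -> np.ndarray:
    """Regular square lattice of 2D points covering a disk of the given radius."""
    k = int(np.floor(radius / spacing))
    ax = np.arange(-k, k + 1) * spacing
    X, Y = np.meshgrid(ax, ax)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    return pts[np.hypot(pts[:, 0], pts[:, 1]) <= radius]
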