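"""Gaze fixation points on the fixation plane 132.5 mm upstream of the isocentre.

A fixation point is described either by its transversal plane coordinates
(x, y) in mm or by the polar/azimuth angles of the corresponding gaze vector;
the two are linked by ``r = plane_distance * tan(polar)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FeasibilityError
from .geometry import PLANE_DISTANCE, POLAR_MAX

_ANGLE_TOL = 1e-9


@dataclass(frozen=True)
class FixationPoint:
    """A candidate gaze target on the fixation plane."""

    x: float
    y: float
    polar: float      # degrees, in [0, 25]
    azimuth: float    # degrees, in [0, 360)
    plane_distance: float = PLANE_DISTANCE

    @property
    def r(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])

    def gaze_vector(self) -> np.ndarray:
        """Unit gaze direction from the isocentre region toward the fixation point."""
        v = np.array([self.x, self.y, self.plane_distance])
        return v / np.linalg.norm(v)


def plane_from_angles(polar: float, azimuth: float,
                      plane_distance: float = PLANE_DISTANCE,
                      polar_max: float = POLAR_MAX) -> FixationPoint:
    """Fixation point from gaze angles (degrees)."""
    if not 0.0 <= polar <= polar_max + _ANGLE_TOL:
        raise FeasibilityError(
            f"polar angle {polar:.3f} deg outside the clinical limit [0, {polar_max}] deg")
    azimuth = float(azimuth) % 360.0
    r = plane_distance * np.tan(np.radians(polar))
    return FixationPoint(x=float(r * np.cos(np.radians(azimuth))),
                         y=float(r * np.sin(np.radians(azimuth))),
                         polar=float(polar), azimuth=azimuth,
                         plane_distance=plane_distance)


def angles_from_plane(x: float, y: float,
                      plane_distance: float = PLANE_DISTANCE,
                      polar_max: float = POLAR_MAX) -> FixationPoint:
    """Fixation point from plane coordinates (mm); validates the polar limit."""
    r = float(np.hypot(x, y))
    polar = float(np.degrees(np.arctan2(r, plane_distance)))
    if polar > polar_max + _ANGLE_TOL:
        raise FeasibilityError(
            f"plane point ({x:.2f}, {y:.2f}) mm corresponds to polar "
            f"{polar:.3f} deg > {polar_max} deg limit")
    azimuth = float(np.degrees(np.arctan2(y, x))) % 360.0 if r > 0 else 0.0
    return FixationPoint(x=float(x), y=float(y), polar=polar, azimuth=azimuth,
                         plane_distance=plane_distance)


def clamp_to_disk(x: float, y: float,
                  plane_distance: float = PLANE_DISTANCE,
                  polar_max: float = POLAR_MAX) -> FixationPoint:
    """Project a raw plane point onto the feasible disk along its azimuth."""
    rmax = plane_distance * np.tan(np.radians(polar_max))
    r = float(np.hypot(x, y))
    if r > rmax:
        scale = rmax / r
        x, y = x * scale, y * scale
    return angles_from_plane(x, y, plane_distance, polar_max)
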