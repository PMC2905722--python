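"""Analytic cylinder geometry: containment, ray intersection, normals.

The phantom is a finite cylinder with an embedded cylindrical source
region.  Regions carry an arbitrary rigid pose (base-center origin plus
unit axis); rays are transformed into the region's local frame — axis
along +z, bottom cap at z = 0 — where the intersection is solved
analytically, and results are mapped back to world coordinates.

Conventions: right-handed coordinates, millimetres.  Points exactly on a
surface count as inside; intersection parameters below 1e-9 mm are
discarded so that a packet sitting on a boundary after a reflection does
not immediately re-intersect the same surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .errors import GeometryError

SURFACE_NAMES = {0: "lateral", 1: "top_cap", 2: "bottom_cap"}


@dataclass(frozen=True)
class CylinderRegion:
    """Finite cylinder defined by base-center origin, unit axis, radius, height."""

    origin: np.ndarray
    axis: np.ndarray
    radius: float
    height: float
    role: str = "tissue"

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if abs(norm - 1.0) > 1e-12:
            if norm == 0.0:
                raise GeometryError("cylinder axis must be nonzero")
            axis = axis / norm
        object.__setattr__(self, "axis", axis)
        if self.role == "source":
            # degenerate source regions (point / line / disc emitters) are valid
            if self.radius < 0 or self.height < 0:
                raise GeometryError("source radius and height must be nonnegative")
        elif self.radius <= 0 or self.height <= 0:
            raise GeometryError("cylinder radius and height must be positive")

    @property
    def basis(self) -> np.ndarray:
        """Orthonormal local frame (e1, e2, axis) as rows."""
        a = self.axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(a, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        return np.vstack([e1, e2, a])

    def to_local(self, point: np.ndarray) -> np.ndarray:
        return self.basis @ (np.asarray(point, dtype=float) - self.origin)

    def to_local_dir(self, direction: np.ndarray) -> np.ndarray:
        return self.basis @ np.asarray(direction, dtype=float)

    def to_world(self, point: np.ndarray) -> np.ndarray:
        return self.basis.T @ np.asarray(point, dtype=float) + self.origin

    def to_world_dir(self, direction: np.ndarray) -> np.ndarray:
        return self.basis.T @ np.asarray(direction, dtype=float)


@dataclass(frozen=True)
class SurfaceHit:
    """Nearest forward ray-surface intersection."""

    point: np.ndarray
    normal: np.ndarray
    distance: float
    surface: str


def contains(point, region: CylinderRegion) -> bool:
    """True iff the point lies inside or on the cylinder surface."""
    p = region.to_local(point)
    if not 0.0 <= p[2] <= region.height:
        return False
    return p[0] * p[0] + p[1] * p[1] <= region.radius * region.radius


def first_intersection(
    origin, direction, region: CylinderRegion
) -> Optional[SurfaceHit]:
    """Nearest forward intersection of a ray with the cylinder surface.

    Returns ``None`` when the ray misses.  The returned normal is the
    geometric outward normal of the hit surface.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise GeometryError("ray direction must be nonzero")
    d = d / norm
    p = region.to_local(origin)
    u = region.to_local_dir(d)
    t, surf_id = _kernels.cyl_first_hit(
        p[0], p[1], p[2], u[0], u[1], u[2], region.radius, region.height
    )
    if surf_id < 0:
        return None
    hit_local = p + t * u
    if surf_id == 0:
        rl = np.hypot(hit_local[0], hit_local[1])
        n_local = np.array([hit_local[0] / rl, hit_local[1] / rl, 0.0])
    elif surf_id == 1:
        n_local = np.array([0.0, 0.0, 1.0])
    else:
        n_local = np.array([0.0, 0.0, -1.0])
    return SurfaceHit(
        point=region.to_world(hit_local),
        normal=region.to_world_dir(n_local),
        distance=float(t),
        surface=SURFACE_NAMES[surf_id],
    )
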