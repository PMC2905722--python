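"""Free-space transport through a thin-lens camera onto a CCD.

The camera lens is reduced to an ideal thin lens; every tissue-surface
point ``r`` is mapped along its *chief ray* — the unrefracted ray through
the lens center — onto the CCD plane at axial distance ``v_ccd`` behind
the lens (perspective projection).  A point at axial object distance ``u``
with a real image (``u > f``) focuses at ``v = 1 / (1/f - 1/u)``; all
surface points are assumed inside the depth of field, so the chief-ray
intersection with the CCD stands in for the exact image point.

Whether an exit package contributes is decided by a binary visibility
factor ``eps = alpha * beta``:

* ``beta`` (system visibility): the package's outgoing ray crosses the
  lens plane inside the aperture, i.e. it can enter the lens at all;
* ``alpha`` (field visibility): the surface point has a real image and its
  projection lands on the CCD active area.

Each accepted package deposits ``tau * P(r)`` into the pixel containing
its projection, where ``tau`` is the energy-loss coefficient of the
optical train (constant by default, optionally cos^4 vignetting).  The
resulting image is the Monte Carlo estimate of the detected flux
integral over the emitting surface.

All mapping operations broadcast over arrays of points: inputs of shape
(3,) or (n, 3) are both accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError, GeometryError, NoRealImageError

WORLD_UP = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class ThinLens:
    """Ideal thin lens: center, optical axis (object space -> detector),
    focal length and aperture diameter, all in millimetres."""

    center: np.ndarray
    axis: np.ndarray
    focal_length: float
    aperture_diameter: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0.0:
            raise GeometryError("lens axis must be nonzero")
        object.__setattr__(self, "axis", axis / norm)
        if self.focal_length <= 0 or self.aperture_diameter <= 0:
            raise ConfigurationError("focal length and aperture must be positive")

    @classmethod
    def from_f_number(
        cls, center, axis, focal_length: float, f_number: float
    ) -> "ThinLens":
        if f_number <= 0:
            raise ConfigurationError("f-number must be positive")
        return cls(center, axis, focal_length, focal_length / f_number)

    @property
    def aperture_radius(self) -> float:
        return 0.5 * self.aperture_diameter


@dataclass(frozen=True)
class DetectorModel:
    """CCD plane at distance v_ccd behind the lens, a centred pixel grid.

    ``flip`` records whether presentation output should be mirrored to
    undo the optical inversion; the raw accumulation never flips.
    """

    v_ccd: float
    pitch: float
    width: int
    height: int
    flip: bool = True

    def __post_init__(self):
        if self.v_ccd <= 0 or self.pitch <= 0:
            raise ConfigurationError("v_ccd and pixel pitch must be positive")
        if self.width < 1 or self.height < 1:
            raise ConfigurationError("detector resolution must be >= 1 pixel")


def detector_frame(lens: ThinLens, up=WORLD_UP):
    """CCD-plane origin and in-plane unit vectors (e1 horizontal, e2 vertical)."""
    up = np.asarray(up, dtype=float)
    e2 = up - (up @ lens.axis) * lens.axis
    n2 = np.linalg.norm(e2)
    if n2 < 1e-12:
        # axis parallel to up (e.g. a top-down camera): fall back to +y
        fallback = np.array([0.0, 1.0, 0.0])
        e2 = fallback - (fallback @ lens.axis) * lens.axis
        n2 = np.linalg.norm(e2)
    e2 = e2 / n2
    e1 = np.cross(e2, lens.axis)
    return e1, e2


def _chief_ray_masked(r, lens: ThinLens):
    """Like chief_ray but returns a validity mask instead of raising."""
    r = np.asarray(r, dtype=float)
    d = lens.center - r
    u = np.asarray(d @ lens.axis)
    valid = u > 0
    dist = np.linalg.norm(d, axis=-1)
    dist = np.where(dist == 0, 1.0, dist)
    s = d / dist[..., None]
    cos_a = np.asarray(s @ lens.axis)
    cos_a = np.where(valid, cos_a, 1.0)
    return s, cos_a, u, valid


def chief_ray(r, lens: ThinLens):
    """Unit direction from r through the lens center, its axial cosine, and
    the axial object distance u.  r must lie on the object side (u > 0)."""
    r = np.asarray(r, dtype=float)
    d = lens.center - r
    u = d @ lens.axis
    if np.any(u <= 0):
        raise GeometryError("surface point lies on or behind the lens plane")
    dist = np.linalg.norm(d, axis=-1)
    s = d / dist[..., None]
    cos_a = s @ lens.axis
    return s, cos_a, u


def image_distance(u, f: float):
    """Thin-lens law: v = 1 / (1/f - 1/u), defined for real images u > f."""
    u = np.asarray(u, dtype=float)
    if np.any(u <= f):
        raise NoRealImageError("object distance u must exceed the focal length")
    return u * f / (u - f)


def ideal_image_point(r, lens: ThinLens):
    """Point where r is exactly focused: r + ((u + v) / cos a) * s."""
    s, cos_a, u = chief_ray(r, lens)
    v = image_distance(u, lens.focal_length)
    return np.asarray(r, dtype=float) + (np.asarray((u + v) / cos_a))[..., None] * s


def project_to_ccd(r, lens: ThinLens, det: DetectorModel):
    """Chief-ray intersection with the CCD plane: r + ((u + v_ccd)/cos a) s.

    This is the perspective projection of the ideal image point through the
    lens center; when v_ccd equals the ideal image distance for r the two
    coincide.
    """
    s, cos_a, u = chief_ray(r, lens)
    return (
        np.asarray(r, dtype=float)
        + (np.asarray((u + det.v_ccd) / cos_a))[..., None] * s
    )


def system_visibility(r, s_r, lens: ThinLens):
    """beta: 1 iff the outgoing ray (r, s_r) crosses the lens plane inside
    the aperture, travelling toward the lens."""
    r = np.asarray(r, dtype=float)
    s_r = np.asarray(s_r, dtype=float)
    denom = s_r @ lens.axis
    u = (lens.center - r) @ lens.axis
    forward = (denom > 0) & (u > 0)
    t = np.where(forward, u / np.where(denom == 0, 1.0, denom), 0.0)
    hit = r + np.asarray(t)[..., None] * s_r
    q = hit - lens.center
    q_perp = q - (q @ lens.axis)[..., None] * lens.axis
    rad = np.linalg.norm(q_perp, axis=-1)
    return (forward & (rad <= lens.aperture_radius)).astype(np.uint8)


def field_visibility(r, lens: ThinLens, det: DetectorModel, up=WORLD_UP):
    """alpha: 1 iff r has a real image (u > f) whose perspective projection
    lands on the CCD active area."""
    r = np.asarray(r, dtype=float)
    s, cos_a, u, valid = _chief_ray_masked(r, lens)
    real = valid & (u > lens.focal_length)
    r_d = r + (np.asarray((u + det.v_ccd) / cos_a))[..., None] * s
    _, _, inb = pixel_index(r_d, lens, det, up)
    return (real & inb).astype(np.uint8)


def visibility(r, s_r, lens: ThinLens, det: DetectorModel, up=WORLD_UP):
    """eps = alpha * beta, the binary acceptance of an exit package."""
    return field_visibility(r, lens, det, up) * system_visibility(r, s_r, lens)


def pixel_index(r_d, lens: ThinLens, det: DetectorModel, up=WORLD_UP):
    """Map CCD-plane points to (column, row) pixel indices and a bounds mask."""
    e1, e2 = detector_frame(lens, up)
    ccd_center = lens.center + det.v_ccd * lens.axis
    q = np.asarray(r_d, dtype=float) - ccd_center
    ix = np.floor((q @ e1) / det.pitch + det.width / 2.0).astype(np.int64)
    iy = np.floor((q @ e2) / det.pitch + det.height / 2.0).astype(np.int64)
    inb = (ix >= 0) & (ix < det.width) & (iy >= 0) & (iy < det.height)
    return ix, iy, inb


# ---------------------------------------------------------------------------
# energy-loss models
# ---------------------------------------------------------------------------


class ConstantTau:
    """Constant optical-train transmittance tau = T0."""

    name = "constant"

    def __init__(self, t0: float = 1.0):
        if not 0.0 <= t0 <= 1.0:
            raise ConfigurationError("tau must lie in [0, 1]")
        self.t0 = t0

    def __call__(self, cos_a):
        return np.full_like(np.asarray(cos_a, dtype=float), self.t0)


class Cos4Tau:
    """cos^4 vignetting: tau = T0 * cos(a)^4."""

    name = "cos4"

    def __init__(self, t0: float = 1.0):
        if not 0.0 <= t0 <= 1.0:
            raise ConfigurationError("tau must lie in [0, 1]")
        self.t0 = t0

    def __call__(self, cos_a):
        return self.t0 * np.asarray(cos_a, dtype=float) ** 4


# ---------------------------------------------------------------------------
# flux accumulation
# ---------------------------------------------------------------------------


@dataclass
class FluxImage:
    """Accumulated detected power per CCD pixel (row = vertical index)."""

    data: np.ndarray
    metadata: dict = field(default_factory=dict)

    def total(self) -> float:
        return float(self.data.sum())

    def centroid_mm(self):
        """Power-weighted centroid in detector-frame mm (horizontal, vertical);
        (nan, nan) for an empty image."""
        total = self.data.sum()
        if total <= 0:
            return float("nan"), float("nan")
        ny, nx = self.data.shape
        pitch = self.metadata.get("pitch", 1.0)
        cols = (np.arange(nx) + 0.5 - nx / 2.0) * pitch
        rows = (np.arange(ny) + 0.5 - ny / 2.0) * pitch
        h = float((self.data.sum(axis=0) * cols).sum() / total)
        v = float((self.data.sum(axis=1) * rows).sum() / total)
        return h, v

    def oriented(self) -> np.ndarray:
        """Presentation copy: mirrored when the detector flip flag is set."""
        if self.metadata.get("flip", False):
            return self.data[::-1, ::-1].copy()
        return self.data


def accumulate(
    exits,
    lens: ThinLens,
    det: DetectorModel,
    tau_model=None,
    up=WORLD_UP,
    metadata: Optional[dict] = None,
) -> FluxImage:
    """Bin accepted exit packages onto the CCD pixel grid.

    For each exit record with visibility eps = 1, adds tau * P(r) to the
    pixel containing the perspective projection of r.  Returns the flux
    image; the count of accepted records is stored in its metadata.
    """
    if tau_model is None:
        tau_model = ConstantTau(1.0)
    img = np.zeros((det.height, det.width), dtype=np.float64)
    meta = {
        "v_ccd": det.v_ccd,
        "pitch": det.pitch,
        "flip": det.flip,
        "focal_length": lens.focal_length,
        "aperture_diameter": lens.aperture_diameter,
        "tau_model": getattr(tau_model, "name", type(tau_model).__name__),
        "accepted": 0,
        "n_exits": len(exits),
    }
    if metadata:
        meta.update(metadata)
    if len(exits) == 0:
        return FluxImage(img, meta)
    r = exits.positions
    s_r = exits.directions
    w = exits.weights

    beta = system_visibility(r, s_r, lens).astype(bool)
    s, cos_a, u, valid = _chief_ray_masked(r, lens)
    real = valid & (u > lens.focal_length)
    r_d = r + ((u + det.v_ccd) / cos_a)[:, None] * s
    ix, iy, inb = pixel_index(r_d, lens, det, up)
    accept = beta & real & inb
    tau = np.asarray(tau_model(cos_a), dtype=float)
    if np.any((tau < 0) | (tau > 1)):
        raise ConfigurationError("energy-loss coefficient tau must lie in [0, 1]")
    np.add.at(img, (iy[accept], ix[accept]), w[accept] * tau[accept])
    meta["accepted"] = int(accept.sum())
    return FluxImage(img, meta)
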