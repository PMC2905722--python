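"""Run configuration schema, validation, serialization and camera setup.

A :class:`RunConfig` fully determines a simulation: phantom geometry and
optical properties, source region and power, photon count and seed, lens
and detector parameters, camera perspective, worker count, roulette and
random-stream settings.  Configs round-trip losslessly through YAML, and
a canonical SHA-256 hash of the config guards result merging.

Perspectives are implemented by rotating the camera (lens + detector as a
rigid assembly) about the phantom axis; ``front`` looks along -x from
azimuth 0 deg, ``left``/``back``/``right`` sit at 90/180/270 deg.  The
source-hole offset of the bundled phantom preset lies on the +x axis,
i.e. on the front side.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .geometry import CylinderRegion
from .optics import ConstantTau, Cos4Tau, DetectorModel, ThinLens, image_distance
from .rng import MINSTD_MODULUS, MINSTD_MULTIPLIER
from .tissue import OpticalProperties

PERSPECTIVE_AZIMUTH_DEG = {"front": 0.0, "left": 90.0, "back": 180.0, "right": 270.0}


class OpticalConfig(BaseModel):
    """Medium optical properties; give mu_s or the reduced mu_s_prime."""

    mu_a: float = Field(ge=0)
    mu_s: Optional[float] = Field(default=None, ge=0)
    mu_s_prime: Optional[float] = Field(default=None, ge=0)
    g: float = Field(default=0.9, ge=-1, le=1)
    n: float = Field(default=1.4, ge=1)

    @model_validator(mode="after")
    def _check_scattering(self):
        if self.mu_s is None and self.mu_s_prime is None:
            raise ValueError("one of mu_s or mu_s_prime is required")
        if self.mu_s is not None and self.mu_s_prime is not None:
            if abs(self.mu_s * (1.0 - self.g) - self.mu_s_prime) > 1e-9:
                raise ValueError("mu_s, mu_s_prime and g are inconsistent")
        return self

    def properties(self) -> OpticalProperties:
        if self.mu_s is not None:
            return OpticalProperties(self.mu_a, self.mu_s, self.g, self.n)
        return OpticalProperties.from_reduced_scattering(
            self.mu_a, self.mu_s_prime, self.g, self.n
        )


class PhantomConfig(BaseModel):
    """Canonical cylinder phantom: axis +z, bottom cap at z = 0."""

    radius: float = Field(default=15.0, gt=0)
    height: float = Field(default=30.0, gt=0)
    optical: OpticalConfig
    n_outside: float = Field(default=1.0, ge=1)


class SourceConfig(BaseModel):
    """Embedded cylindrical source region, in the phantom frame.

    Degenerate radius/height (0) give point- or line-like emitters; the
    pencil emission mode launches every package along ``direction``.
    """

    center_x: float = 0.0
    center_y: float = 0.0
    z0: float = 0.0
    radius: float = Field(default=1.0, ge=0)
    height: float = Field(default=1.0, ge=0)
    total_power: float = Field(default=1.0, gt=0)
    emission: Literal["isotropic", "pencil"] = "isotropic"
    direction: Optional[Tuple[float, float, float]] = None

    @model_validator(mode="after")
    def _check_direction(self):
        if self.emission == "pencil":
            if self.direction is None:
                raise ValueError("pencil emission requires a direction")
            if np.linalg.norm(self.direction) == 0:
                raise ValueError("pencil direction must be nonzero")
        return self


class LensConfig(BaseModel):
    """Thin lens: focal length plus f-number or explicit aperture;
    ``standoff`` is the lens-center distance from the phantom axis."""

    focal_length: float = Field(default=55.0, gt=0)
    f_number: Optional[float] = Field(default=8.0, gt=0)
    aperture_diameter: Optional[float] = Field(default=None, gt=0)
    standoff: float = Field(default=200.0, gt=0)

    @model_validator(mode="after")
    def _check_aperture(self):
        if self.f_number is None and self.aperture_diameter is None:
            raise ValueError("one of f_number or aperture_diameter is required")
        return self

    def aperture(self) -> float:
        if self.aperture_diameter is not None:
            return self.aperture_diameter
        return self.focal_length / self.f_number


class DetectorConfig(BaseModel):
    """CCD plane; ``v_ccd`` None focuses on the phantom's nearest surface."""

    v_ccd: Optional[float] = Field(default=None, gt=0)
    pitch: float = Field(default=0.11, gt=0)
    width: int = Field(default=256, ge=1)
    height: int = Field(default=256, ge=1)
    flip: bool = True


class TauConfig(BaseModel):
    """Energy-loss coefficient of the optical train."""

    model: Literal["constant", "cos4"] = "constant"
    t0: float = Field(default=1.0, ge=0, le=1)

    def build(self):
        return ConstantTau(self.t0) if self.model == "constant" else Cos4Tau(self.t0)


class RouletteConfig(BaseModel):
    threshold_frac: float = Field(default=1e-4, gt=0, lt=1)
    chance: float = Field(default=0.1, gt=0, le=1)


class RngConfig(BaseModel):
    """Generator constants and the per-photon draw budget used to size
    dividing-cycle blocks for parallel runs."""

    multiplier: int = Field(default=MINSTD_MULTIPLIER, gt=0)
    modulus: int = Field(default=MINSTD_MODULUS, gt=1)
    draw_budget: int = Field(default=10_000, gt=0)


class RunConfig(BaseModel):
    """Complete, serializable description of one simulation run."""

    phantom: PhantomConfig
    source: SourceConfig
    photons: int = Field(default=100_000, ge=1)
    seed: int = Field(default=1, ge=1)
    workers: int = Field(default=1, ge=1)
    perspective: Literal["front", "left", "back", "right"] = "front"
    lens: LensConfig = LensConfig()
    detector: DetectorConfig = DetectorConfig()
    tau: TauConfig = TauConfig()
    roulette: RouletteConfig = RouletteConfig()
    rng: RngConfig = RngConfig()
    max_events: int = Field(default=1_000_000, ge=1)

    @model_validator(mode="after")
    def _check(self):
        src_r = math.hypot(self.source.center_x, self.source.center_y)
        if src_r + self.source.radius > self.phantom.radius + 1e-12:
            raise ValueError("source region must lie inside the phantom radius")
        if self.source.z0 < -1e-12 or (
            self.source.z0 + self.source.height > self.phantom.height + 1e-12
        ):
            raise ValueError("source region must lie inside the phantom height")
        if self.seed > self.rng.modulus - 1:
            raise ValueError("seed must lie in [1, modulus-1]")
        return self

    def source_region(self) -> CylinderRegion:
        """Source cylinder in the phantom frame (degenerate sizes allowed)."""
        return CylinderRegion(
            origin=np.array([self.source.center_x, self.source.center_y, self.source.z0]),
            axis=np.array([0.0, 0.0, 1.0]),
            radius=self.source.radius,
            height=self.source.height,
            role="source",
        )

    def phantom_region(self) -> CylinderRegion:
        return CylinderRegion(
            origin=np.zeros(3),
            axis=np.array([0.0, 0.0, 1.0]),
            radius=self.phantom.radius,
            height=self.phantom.height,
            role="tissue",
        )


def camera_for(
    config: RunConfig, perspective: Optional[str] = None
) -> tuple[ThinLens, DetectorModel]:
    """Thin lens + detector for a named perspective around the phantom.

    The camera sits at the configured standoff from the phantom axis at
    mid-height, looking horizontally at the phantom; its optical axis
    points away from the phantom toward the CCD.  When ``v_ccd`` is not
    set, the detector is placed so the phantom's nearest surface point is
    exactly in focus.
    """
    name = perspective or config.perspective
    try:
        az = math.radians(PERSPECTIVE_AZIMUTH_DEG[name])
    except KeyError:
        raise ConfigurationError(
            f"unknown perspective {name!r}; expected one of "
            f"{sorted(PERSPECTIVE_AZIMUTH_DEG)}"
        ) from None
    d = np.array([math.cos(az), math.sin(az), 0.0])
    center = np.array([0.0, 0.0, config.phantom.height / 2.0]) + config.lens.standoff * d
    lens = ThinLens(
        center=center,
        axis=d,
        focal_length=config.lens.focal_length,
        aperture_diameter=config.lens.aperture(),
    )
    v_ccd = config.detector.v_ccd
    if v_ccd is None:
        u_front = config.lens.standoff - config.phantom.radius
        v_ccd = float(image_distance(u_front, config.lens.focal_length))
    det = DetectorModel(
        v_ccd=v_ccd,
        pitch=config.detector.pitch,
        width=config.detector.width,
        height=config.detector.height,
        flip=config.detector.flip,
    )
    return lens, det


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    )


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    """Canonical SHA-256 of the config; used to guard result merging."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()
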