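"""Named fixture configurations.

``bench_phantom`` reproduces the bench experiment the model was designed
around: a nylon cylinder (diameter 30 mm, height 30 mm) with a drilled
source hole (diameter 2 mm, 16 mm deep from the top cap, 8 mm off
center) filled with a luminescent column, measured optical properties
mu_a = 0.0138 /mm and mu_s' = 0.91 /mm at ~660 nm, imaged by a 55 mm
lens stopped to f/8.  The anisotropy (g = 0.9), phantom refractive index
(1.4), camera standoff (200 mm) and detector pitch/resolution are not
part of the published description and are config-exposed defaults.

The remaining presets are verification scenes: a pure-absorber column for
the Beer-Lambert transmittance check and a vacuum point emitter for the
aperture solid-angle check.
"""

from __future__ import annotations

from .config import (
    DetectorConfig,
    LensConfig,
    OpticalConfig,
    PhantomConfig,
    RouletteConfig,
    RunConfig,
    SourceConfig,
)
from .errors import ConfigurationError


def bench_phantom() -> RunConfig:
    """Off-center luminescent column in a turbid 30 x 30 mm cylinder."""
    return RunConfig(
        phantom=PhantomConfig(
            radius=15.0,
            height=30.0,
            optical=OpticalConfig(mu_a=0.0138, mu_s_prime=0.91, g=0.9, n=1.4),
            n_outside=1.0,
        ),
        source=SourceConfig(
            center_x=8.0,
            center_y=0.0,
            z0=14.0,  # 16 mm deep from the 30 mm top surface
            radius=1.0,
            height=16.0,
            total_power=1.0,
            emission="isotropic",
        ),
        photons=1_000_000,
        lens=LensConfig(focal_length=55.0, f_number=8.0, standoff=200.0),
        detector=DetectorConfig(pitch=0.11, width=256, height=256),
    )


def slab_absorber(mu_a: float = 0.1, length: float = 10.0) -> RunConfig:
    """Pure absorber column of the given length, probed by a pencil beam.

    Packages launch at the bottom-cap center travelling +z; the exiting
    weight fraction through the top cap is exp(-mu_a * length).
    """
    return RunConfig(
        phantom=PhantomConfig(
            radius=20.0,
            height=length,
            optical=OpticalConfig(mu_a=mu_a, mu_s=0.0, g=0.0, n=1.0),
            n_outside=1.0,
        ),
        source=SourceConfig(
            center_x=0.0,
            center_y=0.0,
            z0=0.0,
            radius=0.0,
            height=0.0,
            emission="pencil",
            direction=(0.0, 0.0, 1.0),
        ),
        photons=100_000,
    )


def vacuum_point_source(distance: float = 100.0) -> RunConfig:
    """Isotropic point emitter in a transparent medium facing the lens.

    The emitter sits on the camera axis at ``distance`` mm from the lens
    center; the fraction of packages passing the aperture is the
    subtended solid-angle fraction.
    """
    height = 30.0
    return RunConfig(
        phantom=PhantomConfig(
            radius=15.0,
            height=height,
            optical=OpticalConfig(mu_a=0.0, mu_s=0.0, g=1.0, n=1.0),
            n_outside=1.0,
        ),
        source=SourceConfig(
            center_x=0.0, center_y=0.0, z0=height / 2.0, radius=0.0, height=0.0
        ),
        photons=100_000,
        lens=LensConfig(focal_length=55.0, f_number=8.0, standoff=distance),
    )


_REGISTRY = {
    "bench_phantom": bench_phantom,
    "slab_absorber": slab_absorber,
    "vacuum_point_source": vacuum_point_source,
}


def preset_names() -> list[str]:
    return sorted(_REGISTRY)


def get_preset(name: str) -> RunConfig:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {preset_names()}"
        ) from None
    return factory()
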