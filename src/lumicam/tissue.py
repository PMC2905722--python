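"""Monte Carlo photon-package transport inside the turbid phantom.

Light is carried by *photon packages*: particles with a continuous weight
equal to the source power divided by the package count.  Each package is
launched inside the source region, takes exponentially distributed steps
``d = -ln(zeta) / (mu_a + mu_s)``, deposits the fraction ``mu_a / mu_t``
of its weight at every interaction site, is deflected by a
Henyey-Greenstein scatter with anisotropy ``g``, and undergoes Fresnel
reflection / Snell refraction at the phantom boundary.  Low-weight
packages are terminated unbiasedly by Russian roulette.  A package ends
either absorbed (``photon_dead = 1``) or transmitted through the outer
boundary (``photon_dead = 0``), in which case an exit record (surface
point, refracted direction, residual power) is emitted for the free-space
stage.

Free space itself is the degenerate medium ``mu_a = mu_s = 0, g = 1``:
the step size diverges and packages fly ballistically.

The per-package operations (`launch`, `step_size`, `absorb`, `spin`,
`boundary_event`, `roulette`, `trace`) are a plain-Python reference path
sharing its numeric helpers with the compiled kernel used by `run_tissue`;
the two paths consume identical random streams and agree bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .errors import (
    ConfigurationError,
    GeometryError,
    RunawayPhotonError,
    StreamOverrunError,
)
from .geometry import CylinderRegion
from .rng import MCGState, next_uniform


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption, scattering, anisotropy and refractive index of a medium.

    Units: mu_a and mu_s in 1/mm; g dimensionless in [-1, 1]; n >= 1.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float = 1.0

    def __post_init__(self):
        if self.mu_a < 0 or self.mu_s < 0:
            raise ConfigurationError("mu_a and mu_s must be nonnegative")
        if not -1.0 <= self.g <= 1.0:
            raise ConfigurationError("anisotropy g must lie in [-1, 1]")
        if self.n < 1.0:
            raise ConfigurationError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s

    @property
    def mu_s_reduced(self) -> float:
        return self.mu_s * (1.0 - self.g)

    @classmethod
    def free_space(cls) -> "OpticalProperties":
        """The degenerate medium in which packages fly ballistically."""
        return cls(mu_a=0.0, mu_s=0.0, g=1.0, n=1.0)

    @classmethod
    def from_reduced_scattering(
        cls, mu_a: float, mu_s_prime: float, g: float, n: float = 1.0
    ) -> "OpticalProperties":
        """Recover mu_s from the reduced coefficient mu_s' = mu_s (1 - g)."""
        if g >= 1.0:
            raise ConfigurationError("g must be < 1 to recover mu_s from mu_s'")
        return cls(mu_a=mu_a, mu_s=mu_s_prime / (1.0 - g), g=g, n=n)


@dataclass
class PhotonPacket:
    """A weighted photon bundle in flight."""

    position: np.ndarray
    direction: np.ndarray
    weight: float
    photon_dead: int = 0  # 1 = absorbed in tissue, 0 = in flight / transmitted
    region: str = "tissue"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        # normalize only when off-unit: keeps already-unit vectors bit-intact
        norm = np.linalg.norm(d)
        if abs(norm - 1.0) > 1e-9:
            d = d / norm
        self.direction = d


@dataclass
class ExitRecord:
    """A package leaving the phantom: point r, direction s_r, power P(r)."""

    r: np.ndarray
    s_r: np.ndarray
    power: float


@dataclass
class WeightLedger:
    """Exact bookkeeping of launched / absorbed / exited / roulette weight."""

    launched: float = 0.0
    absorbed: float = 0.0
    exited: float = 0.0
    roulette_net: float = 0.0

    @property
    def closure_residual(self) -> float:
        """Relative imbalance of launched = absorbed + exited + roulette_net."""
        total = self.absorbed + self.exited + self.roulette_net
        scale = max(abs(self.launched), 1e-300)
        return abs(self.launched - total) / scale

    def add(self, other: "WeightLedger") -> "WeightLedger":
        return WeightLedger(
            self.launched + other.launched,
            self.absorbed + other.absorbed,
            self.exited + other.exited,
            self.roulette_net + other.roulette_net,
        )


class ExitRecords:
    """Column store of exit records (positions, directions, weights)."""

    def __init__(self, positions, directions, weights):
        self.positions = np.atleast_2d(np.asarray(positions, dtype=float))
        self.directions = np.atleast_2d(np.asarray(directions, dtype=float))
        self.weights = np.atleast_1d(np.asarray(weights, dtype=float))
        if self.positions.shape[0] == 0:
            self.positions = self.positions.reshape(0, 3)
            self.directions = self.directions.reshape(0, 3)

    def __len__(self) -> int:
        return self.weights.shape[0]

    def __eq__(self, other) -> bool:
        return (
            np.array_equal(self.positions, other.positions)
            and np.array_equal(self.directions, other.directions)
            and np.array_equal(self.weights, other.weights)
        )

    @classmethod
    def empty(cls) -> "ExitRecords":
        return cls(np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0))

    @classmethod
    def concatenate(cls, parts) -> "ExitRecords":
        parts = list(parts)
        if not parts:
            return cls.empty()
        return cls(
            np.concatenate([p.positions for p in parts]),
            np.concatenate([p.directions for p in parts]),
            np.concatenate([p.weights for p in parts]),
        )

    def total_power(self) -> float:
        return float(self.weights.sum())


# ---------------------------------------------------------------------------
# single-package operations (reference path)
# ---------------------------------------------------------------------------


def launch(
    source: CylinderRegion,
    total_power: float,
    n_packets: int,
    rng: MCGState,
    pencil_direction=None,
) -> PhotonPacket:
    """Create one package: uniform position in the source cylinder, isotropic
    direction (or a fixed pencil direction), weight = total_power / N."""
    if n_packets < 1:
        raise ConfigurationError("photon count N must be >= 1")
    xi1 = next_uniform(rng)
    xi2 = next_uniform(rng)
    xi3 = next_uniform(rng)
    rad = source.radius * math.sqrt(xi1)
    phi = 2.0 * math.pi * xi2
    local = np.array([rad * math.cos(phi), rad * math.sin(phi), source.height * xi3])
    if abs(source.axis[2] - 1.0) < 1e-12:
        # canonical pose: identical arithmetic to the compiled kernel
        position = source.origin + local
    else:
        position = source.to_world(local)
    if pencil_direction is not None:
        direction = np.asarray(pencil_direction, dtype=float)
    else:
        ct = 2.0 * next_uniform(rng) - 1.0
        phd = 2.0 * math.pi * next_uniform(rng)
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        direction = np.array([st * math.cos(phd), st * math.sin(phd), ct])
    return PhotonPacket(position, direction, total_power / n_packets)


def step_size(props: OpticalProperties, zeta: float) -> float:
    """Exponential free-path sample; infinite in the free-space medium."""
    if props.mu_t == 0.0:
        return math.inf
    if not 0.0 < zeta < 1.0:
        raise ConfigurationError("zeta must lie strictly inside (0, 1)")
    return -math.log(zeta) / props.mu_t


def absorb(
    packet: PhotonPacket, props: OpticalProperties, ledger: WeightLedger
) -> PhotonPacket:
    """Deposit the fraction mu_a / mu_t of the packet weight at this site."""
    if props.mu_t <= 0.0:
        return packet
    dw = packet.weight * (props.mu_a / props.mu_t)
    ledger.absorbed += dw
    packet.weight -= dw
    if packet.weight <= 0.0:
        packet.photon_dead = 1
    return packet


def spin(packet: PhotonPacket, g: float, rng: MCGState) -> PhotonPacket:
    """Henyey-Greenstein deflection with uniform azimuth."""
    xia = next_uniform(rng)
    xib = next_uniform(rng)
    ct = _kernels.hg_cos(g, xia)
    d = packet.direction
    packet.direction = np.array(
        _kernels.spin_direction(d[0], d[1], d[2], ct, 2.0 * math.pi * xib)
    )
    return packet


def boundary_event(
    packet: PhotonPacket,
    normal: np.ndarray,
    n_in: float,
    n_out: float,
    rng: MCGState,
):
    """Fresnel decision at an outward boundary crossing.

    Returns the reflected packet, or an :class:`ExitRecord` carrying the
    full residual weight along the refracted direction.  The random draw is
    skipped when the reflectance is exactly 0 or 1.
    """
    normal = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-9:
        raise GeometryError("boundary normal must be unit length")
    d = packet.direction
    # left-to-right sum: bit-identical to the compiled kernel's dot product
    cos_i = float(d[0] * normal[0] + d[1] * normal[1] + d[2] * normal[2])
    if cos_i <= 0.0:
        reflect = True
    else:
        rf = _kernels.fresnel_reflectance(n_in, n_out, cos_i)
        if rf >= 1.0:
            reflect = True
        elif rf <= 0.0:
            reflect = False
        else:
            reflect = next_uniform(rng) <= rf
    if reflect:
        packet.direction = d - 2.0 * cos_i * normal
        return packet
    eta = n_in / n_out
    cos_t = math.sqrt(max(0.0, 1.0 - eta * eta * (1.0 - cos_i * cos_i)))
    s_t = eta * d + (cos_t - eta * cos_i) * normal
    # explicit norm: bit-identical to the compiled kernel's arithmetic
    s_t = s_t / math.sqrt(s_t[0] ** 2 + s_t[1] ** 2 + s_t[2] ** 2)
    packet.photon_dead = 0
    return ExitRecord(r=packet.position.copy(), s_r=s_t, power=packet.weight)


def roulette(
    packet: PhotonPacket,
    threshold: float,
    chance: float,
    rng: MCGState,
    ledger: WeightLedger,
) -> Optional[PhotonPacket]:
    """Unbiased low-weight termination: survive with probability ``chance``
    and weight boosted by 1/chance, else die with the weight booked to the
    ledger's roulette channel."""
    if not 0.0 < chance <= 1.0:
        raise ConfigurationError("roulette chance must lie in (0, 1]")
    if packet.weight >= threshold:
        return packet
    if chance == 1.0:
        return packet
    if next_uniform(rng) <= chance:
        boost = packet.weight * (1.0 / chance - 1.0)
        ledger.roulette_net -= boost
        packet.weight += boost
        return packet
    ledger.roulette_net += packet.weight
    packet.photon_dead = 1
    return None


def trace(
    packet: PhotonPacket,
    phantom: CylinderRegion,
    props: OpticalProperties,
    n_outside: float,
    rng: MCGState,
    ledger: WeightLedger,
    roulette_threshold: float,
    roulette_chance: float = 0.1,
    max_events: int = 1_000_000,
):
    """Follow one package to absorption or exit (reference implementation).

    The phantom must be in its canonical pose (axis +z, base at z = 0);
    that is the frame the compiled kernel uses, and this path mirrors it
    event for event.
    """
    events = 0
    while True:
        events += 1
        if events > max_events:
            raise RunawayPhotonError(f"packet exceeded {max_events} events")
        if props.mu_t > 0.0:
            d = step_size(props, next_uniform(rng))
        else:
            d = math.inf
        p, u = packet.position, packet.direction
        t_exit, surf_id = _kernels.cyl_first_hit(
            p[0], p[1], p[2], u[0], u[1], u[2], phantom.radius, phantom.height
        )
        if surf_id < 0:
            raise GeometryError("packet escaped the phantom geometry")
        if d < t_exit:
            packet.position = p + d * u
            absorb(packet, props, ledger)
            if packet.photon_dead:
                return None
            if props.mu_s > 0.0:
                spin(packet, props.g, rng)
            if packet.weight < roulette_threshold:
                if roulette(packet, roulette_threshold, roulette_chance, rng, ledger) is None:
                    return None
        else:
            packet.position = p + t_exit * u
            if surf_id == 0:
                rl = math.sqrt(
                    packet.position[0] ** 2 + packet.position[1] ** 2
                )
                normal = np.array(
                    [packet.position[0] / rl, packet.position[1] / rl, 0.0]
                )
            elif surf_id == 1:
                normal = np.array([0.0, 0.0, 1.0])
            else:
                normal = np.array([0.0, 0.0, -1.0])
            out = boundary_event(packet, normal, props.n, n_outside, rng)
            if isinstance(out, ExitRecord):
                ledger.exited += out.power
                return out


# ---------------------------------------------------------------------------
# batch transport (compiled kernel)
# ---------------------------------------------------------------------------


@dataclass
class TissueResult:
    """Output of a tissue-stage run."""

    exits: ExitRecords
    ledger: WeightLedger
    draws: int
    absorption_grid: Optional[np.ndarray] = None
    exit_surface_ids: Optional[np.ndarray] = None


def run_tissue(
    phantom_radius: float,
    phantom_height: float,
    props: OpticalProperties,
    n_outside: float,
    source: CylinderRegion,
    total_power: float,
    n_photons: int,
    rng: MCGState,
    pencil_direction=None,
    roulette_threshold_frac: float = 1e-4,
    roulette_chance: float = 0.1,
    max_events: int = 1_000_000,
    draw_limit: int = 0,
    absorption_grid_shape=None,
    packet_weight: Optional[float] = None,
) -> TissueResult:
    """Trace ``n_photons`` packages through the canonical phantom cylinder.

    ``rng`` is advanced in place.  ``draw_limit`` > 0 enforces a
    dividing-cycle block budget: consuming more draws raises
    :class:`StreamOverrunError` instead of silently reusing another
    worker's block.  ``absorption_grid_shape`` enables the optional 3-D
    absorption tally over the phantom bounding box.
    """
    if n_photons < 0:
        raise ConfigurationError("photon count must be nonnegative")
    if n_photons == 0:
        return TissueResult(ExitRecords.empty(), WeightLedger(), 0)
    # source cylinder must be axis-aligned for the kernel
    if abs(abs(source.axis[2]) - 1.0) > 1e-12:
        raise GeometryError("kernel path requires an axis-aligned source cylinder")
    pencil = pencil_direction is not None
    pd = (
        np.asarray(pencil_direction, dtype=float)
        if pencil
        else np.array([0.0, 0.0, 1.0])
    )
    pd = pd / np.linalg.norm(pd)
    if absorption_grid_shape is not None:
        grid = np.zeros(absorption_grid_shape, dtype=np.float64)
        grid_on = True
    else:
        grid = np.zeros((1, 1, 1), dtype=np.float64)
        grid_on = False
    # a parallel worker passes the packet weight of the *whole* run so that
    # its packages are bit-identical to the serial run's
    w0 = packet_weight if packet_weight is not None else total_power / n_photons
    (
        ex, ey, ez, edx, edy, edz, ew, n_exit,
        absorbed, exited, rr_net, draws, status, final_state,
    ) = _kernels.transport_kernel(
        n_photons,
        rng.current,
        rng.multiplier,
        rng.modulus,
        phantom_radius,
        phantom_height,
        props.n,
        n_outside,
        source.origin[0],
        source.origin[1],
        source.origin[2],
        source.radius,
        source.height,
        pencil,
        pd[0],
        pd[1],
        pd[2],
        props.mu_a,
        props.mu_s,
        props.g,
        w0,
        roulette_threshold_frac * w0,
        roulette_chance,
        max_events,
        draw_limit,
        grid,
        grid_on,
    )
    if status == _kernels.STATUS_RUNAWAY:
        raise RunawayPhotonError(f"a packet exceeded {max_events} events")
    if status == _kernels.STATUS_ESCAPED:
        raise GeometryError("a packet escaped the phantom geometry")
    if status == _kernels.STATUS_DRAW_OVERRUN:
        raise StreamOverrunError(
            f"worker consumed {draws} draws, exceeding its block of {draw_limit}"
        )
    rng.current = int(final_state)
    exits = ExitRecords(
        np.column_stack([ex, ey, ez]),
        np.column_stack([edx, edy, edz]),
        ew,
    )
    ledger = WeightLedger(
        launched=n_photons * w0,
        absorbed=float(absorbed),
        exited=float(exited),
        roulette_net=float(rr_net),
    )
    return TissueResult(
        exits=exits,
        ledger=ledger,
        draws=int(draws),
        absorption_grid=grid if grid_on else None,
    )


def run_raycast(
    phantom_radius: float,
    phantom_height: float,
    n_in: float,
    n_outside: float,
    source: CylinderRegion,
    total_power: float,
    n_photons: int,
    rng: MCGState,
    pencil_direction=None,
    max_events: int = 1_000_000,
) -> TissueResult:
    """Ballistic ray-cast sharing launch draws and boundary rules with
    :func:`run_tissue`; the oracle for the degenerate free-space medium."""
    if n_photons == 0:
        return TissueResult(ExitRecords.empty(), WeightLedger(), 0)
    pencil = pencil_direction is not None
    pd = (
        np.asarray(pencil_direction, dtype=float)
        if pencil
        else np.array([0.0, 0.0, 1.0])
    )
    pd = pd / np.linalg.norm(pd)
    w0 = total_power / n_photons
    (
        ex, ey, ez, edx, edy, edz, ew, n_exit, exited, draws, status, final_state,
    ) = _kernels.raycast_kernel(
        n_photons,
        rng.current,
        rng.multiplier,
        rng.modulus,
        phantom_radius,
        phantom_height,
        n_in,
        n_outside,
        source.origin[0],
        source.origin[1],
        source.origin[2],
        source.radius,
        source.height,
        pencil,
        pd[0],
        pd[1],
        pd[2],
        w0,
        max_events,
    )
    if status == _kernels.STATUS_RUNAWAY:
        raise RunawayPhotonError(f"a packet exceeded {max_events} events")
    if status == _kernels.STATUS_ESCAPED:
        raise GeometryError("a packet escaped the phantom geometry")
    rng.current = int(final_state)
    exits = ExitRecords(
        np.column_stack([ex, ey, ez]),
        np.column_stack([edx, edy, edz]),
        ew,
    )
    ledger = WeightLedger(
        launched=n_photons * w0, exited=float(exited), absorbed=0.0, roulette_net=0.0
    )
    return TissueResult(exits=exits, ledger=ledger, draws=int(draws))
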