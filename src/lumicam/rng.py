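"""Multiplicative congruential generator with dividing-cycle partitioning.

The whole simulation draws from one multiplicative congruential generator
(MCG), ``x_{k+1} = a * x_k mod m`` with prime modulus ``m``, whose output
``x / m`` is a uniform deviate strictly inside (0, 1).  Parallel runs use
the *dividing-cycle* scheme: the single master sequence is cut into
contiguous blocks of ``L`` draws and the first value of each block seeds
one worker, so the concatenation of all worker streams reproduces the
serial stream exactly.  The block starts are located by modular
exponentiation (jump-ahead) rather than by literally iterating the master
sequence; the outputs are identical.

The default constants are the Lehmer "minimal standard" pair
(a = 16807, m = 2**31 - 1), a full-period generator: every seed in
[1, m-1] cycles through all m-1 nonzero states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .errors import ConfigurationError, PartitionOverflowError

MINSTD_MULTIPLIER = 16807
MINSTD_MODULUS = 2**31 - 1


@dataclass
class MCGState:
    """State of a multiplicative congruential generator.

    ``current`` is the last generated value (or the seed before the first
    draw); it must lie in [1, m-1] — zero is an absorbing invalid state.
    """

    multiplier: int = MINSTD_MULTIPLIER
    modulus: int = MINSTD_MODULUS
    current: int = 1

    def __post_init__(self) -> None:
        if self.multiplier <= 0 or self.modulus <= 1:
            raise ConfigurationError("multiplier and modulus must be positive")
        if self.multiplier * self.modulus >= 2**63:
            raise ConfigurationError(
                "multiplier * modulus must fit in 64-bit arithmetic"
            )
        if not 1 <= self.current <= self.modulus - 1:
            raise ConfigurationError(
                f"MCG state must lie in [1, {self.modulus - 1}], got {self.current}"
            )

    @property
    def period(self) -> int:
        """Cycle length of a full-period MCG (prime modulus)."""
        return self.modulus - 1

    def copy(self) -> "MCGState":
        return MCGState(self.multiplier, self.modulus, self.current)


def next_uniform(state: MCGState) -> float:
    """Advance the generator one step and return a uniform in (0, 1)."""
    if state.current == 0:
        raise ConfigurationError("zero MCG state is absorbing and invalid")
    state.current = (state.multiplier * state.current) % state.modulus
    # multiply by the reciprocal: bit-identical to the compiled loops
    return state.current * (1.0 / state.modulus)


def uniforms(state: MCGState, n: int) -> np.ndarray:
    """Draw ``n`` uniforms, advancing the state in place (compiled loop)."""
    out = np.empty(n, dtype=np.float64)
    state.current = int(
        _kernels.mcg_fill(state.current, state.multiplier, state.modulus, out)
    )
    return out


def jump_ahead(seed: int, k: int, multiplier: int, modulus: int) -> int:
    """State after ``k`` generator steps from ``seed``: a^k * seed mod m."""
    return (pow(multiplier, k, modulus) * seed) % modulus


def sample_inverse_cdf(distribution, xi: float, support=None, tol: float = 1e-10):
    """Sample by inverting a cumulative distribution at the deviate ``xi``.

    ``distribution`` may be a frozen scipy.stats distribution (its ``ppf``
    is used directly) or a callable CDF together with a finite ``support``
    interval ``(a, b)``, which is inverted numerically by bracketing.
    """
    if not 0.0 < xi < 1.0:
        raise ConfigurationError("xi must lie strictly inside (0, 1)")
    if hasattr(distribution, "ppf"):
        return distribution.ppf(xi)
    if support is None:
        raise ConfigurationError("a callable CDF needs a finite support interval")
    a, b = support
    ca, cb = distribution(a), distribution(b)
    if abs(ca) > 1e-8 or abs(cb - 1.0) > 1e-8:
        raise ConfigurationError(
            "CDF must rise from 0 to 1 over the support interval "
            f"(got {ca:.3g} .. {cb:.3g})"
        )
    return brentq(lambda x: distribution(x) - xi, a, b, xtol=tol)


@dataclass
class StreamPartition:
    """Dividing-cycle split of one MCG sequence into worker blocks.

    ``worker_seeds[i]`` is the master sequence *output* at index ``i * L``
    (0-based), i.e. the first random number of worker ``i``'s block; it is
    what the dividing-cycle scheme ships to that worker.  ``worker_state``
    builds the MCG state whose next draw is exactly that value.
    """

    master_seed: int
    worker_count: int
    block_length: int
    multiplier: int = MINSTD_MULTIPLIER
    modulus: int = MINSTD_MODULUS
    worker_seeds: list[int] = field(default_factory=list)

    def worker_state(self, i: int) -> MCGState:
        """State reproducing master-sequence indices [i*L, (i+1)*L)."""
        if not 0 <= i < self.worker_count:
            raise ConfigurationError(f"worker index {i} out of range")
        start = jump_ahead(
            self.master_seed, i * self.block_length, self.multiplier, self.modulus
        )
        return MCGState(self.multiplier, self.modulus, start)


def split_streams(
    master_seed: int,
    worker_count: int,
    block_length: int,
    multiplier: int = MINSTD_MULTIPLIER,
    modulus: int = MINSTD_MODULUS,
) -> StreamPartition:
    """Partition the master sequence into ``worker_count`` blocks of ``L``.

    Raises :class:`PartitionOverflowError` when the partition would use at
    least the full generator period, which would wrap worker blocks onto
    each other.
    """
    if worker_count < 1 or block_length < 1:
        raise ConfigurationError("worker_count and block_length must be >= 1")
    if not 1 <= master_seed <= modulus - 1:
        raise ConfigurationError("master seed must lie in [1, modulus-1]")
    period = modulus - 1
    if worker_count * block_length >= period:
        raise PartitionOverflowError(
            f"{worker_count} x {block_length} draws >= generator period {period}"
        )
    seeds = [
        jump_ahead(master_seed, i * block_length + 1, multiplier, modulus)
        for i in range(worker_count)
    ]
    return StreamPartition(
        master_seed=master_seed,
        worker_count=worker_count,
        block_length=block_length,
        multiplier=multiplier,
        modulus=modulus,
        worker_seeds=seeds,
    )
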