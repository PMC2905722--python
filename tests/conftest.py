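import numpy as np
import pytest

from lumicam.parallel import run_parallel
from lumicam.presets import bench_phantom
from lumicam.rng import MCGState


@pytest.fixture
def minstd():
    """Fresh minimal-standard generator state."""
    return MCGState(current=1)


@pytest.fixture
def small_mcg():
    """Tiny full-period MCG (a=3, m=7, period 6) for exhaustive oracles."""
    return dict(multiplier=3, modulus=7)


@pytest.fixture(scope="session")
def phantom_run_1e6():
    """One tissue-stage run of the turbid-phantom preset at 10^6 packages.

    Session-scoped: the four perspective renderings and the flux checks all
    reuse the same exit records, as the camera stage is a pure function of
    them.
    """
    cfg = bench_phantom()  # photons defaults to 10^6
    merged = run_parallel(cfg)
    return cfg, merged


def assert_unit(vec, tol=1e-9):
    assert abs(np.linalg.norm(vec) - 1.0) < tol
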