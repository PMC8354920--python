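import numpy as np
import pytest

from inkdose.spectra_core import HyperspectralCube, ReferencePair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return np.linspace(1000.0, 1600.0, 13)


@pytest.fixture
def small_refs(small_grid):
    white = np.full(small_grid.size, 30000.0)
    black = np.full(small_grid.size, 500.0)
    return ReferencePair(white=white, black=black)


@pytest.fixture
def raw_cube(rng, small_grid, small_refs):
    """Random reflectance cube with counts strictly between black and white."""
    frac = rng.uniform(0.05, 0.95, size=(4, 6, small_grid.size))
    white, black = small_refs.white[0], small_refs.black[0]
    counts = black + frac * (white - black)
    return HyperspectralCube(counts, small_grid)


@pytest.fixture(scope="session")
def noisy_calibration():
    """One desk-scale calibration at default (1%) detector noise, shared
    across tests that only read from it."""
    from inkdose.pipeline import build_calibration, simulate_calibration

    sim = simulate_calibration(7, noise_sd=0.01)
    return build_calibration(sim)
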