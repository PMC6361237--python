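import numpy as np
import pytest

from circoast.imaging import BinaryMask, CellModel
from circoast.network_synthesis import NetworkParams, generate_network
from circoast.validation import run_parameter_sweep

# one seed for the whole study; every test derives its streams from it
STUDY_SEED = 1234

SMALL_RANGES = {
    "width": 128, "height": 128, "min_point_distance": 16.0,
    "cell_diameter": (6.0, 16.0), "cell_number": (20, 60),
    "network_radius": (2, 5), "target_fraction": (0.1, 0.5),
}


@pytest.fixture(scope="session")
def small_network() -> BinaryMask:
    """A modest synthetic vessel network shared by cheap tests."""
    net = generate_network(
        NetworkParams(128, 128, network_radius=3, min_point_distance=16,
                      network_fraction=0.25), seed=STUDY_SEED)
    return net.mask


@pytest.fixture(scope="session")
def cell10() -> CellModel:
    return CellModel(10.0)


@pytest.fixture(scope="session")
def sweep_small():
    """A small randomized sweep for unit-level invariants."""
    return run_parameter_sweep(12, 300, seed=STUDY_SEED, ranges=SMALL_RANGES)


@pytest.fixture(scope="session")
def sweep300():
    """The full-scale randomized sweep: 300 images at 512x512, 2000
    Monte Carlo trials each."""
    return run_parameter_sweep(300, 2000, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def sweep100_hi():
    """100 images at 10^4 trials for the model-equivalence comparison."""
    return run_parameter_sweep(100, 10_000, seed=STUDY_SEED + 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(STUDY_SEED)
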