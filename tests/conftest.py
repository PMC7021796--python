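import numpy as np
import pytest

from cdi_freellk import (
    DiffractionPattern,
    PhantomSpec,
    SimulationSpec,
    Support,
    make_phantom,
    simulate_pattern,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disks_truth_64():
    """Small disks phantom with its exact support (session-cached)."""
    return make_phantom(PhantomSpec("disks", grid_size=64, oversampling=4, seed=7))


@pytest.fixture(scope="session")
def noiseless_pattern_64(disks_truth_64):
    obj, _ = disks_truth_64
    return simulate_pattern(obj, SimulationSpec(total_photons=None))


@pytest.fixture(scope="session")
def noisy_pattern_64(disks_truth_64):
    obj, _ = disks_truth_64
    return simulate_pattern(obj, SimulationSpec(total_photons=1e7, seed=11))


@pytest.fixture
def random_pattern(rng):
    """Small random pattern with nontrivial valid and free masks."""
    inten = rng.poisson(5.0, size=(24, 24)).astype(float)
    valid = rng.random((24, 24)) > 0.1
    free = (rng.random((24, 24)) > 0.8) & valid
    inten[~valid] = 0
    return DiffractionPattern(inten, valid, free)
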