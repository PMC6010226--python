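import pytest

from specdelim.registry import load_packaged_sites, load_packaged_specimens
from specdelim.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def sites():
    return load_packaged_sites()


@pytest.fixture(scope="session")
def specimens():
    return load_packaged_specimens()


@pytest.fixture(scope="session")
def small_dataset():
    """Five-species synthetic bundle used across modules (fixed seed)."""
    return simulate_dataset(
        SimulationConfig(K=5, seed=3, n_per_species=6, min_split_my=2.0)
    )
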