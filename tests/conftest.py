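import numpy as np
import pytest

from ldscape import GenotypeMatrix, LinkageMap, SimulationConfig
from ldscape.simulate import simulate_genotypes, simulate_map


@pytest.fixture
def tiny_map() -> LinkageMap:
    return LinkageMap.from_entries(
        [("m1", 1, 0.0), ("m2", 1, 5.0), ("m3", 1, 12.0), ("m4", 2, 3.0), ("m5", 2, 9.0)]
    )


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    dosage = np.array(
        [
            [0, 1, 2, 1],
            [2, 2, 0, 0],
            [1, 1, 1, -1],
            [0, 0, 2, 2],
            [2, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        ["m1", "m2", "m3", "m4", "m5"], ["s1", "s2", "s3", "s4"], dosage
    )


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(
        n_lg=4,
        n_markers_per_lg=100,
        n_individuals=150,
        missing_rate=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """Medium synthetic dataset shared across test modules."""
    rng = np.random.default_rng(sim_config.seed)
    lmap = simulate_map(sim_config, rng)
    gm = simulate_genotypes(lmap, sim_config, rng)
    return lmap, gm
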