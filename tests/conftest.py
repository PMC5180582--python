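import numpy as np
import pytest

from gbskit.enzymes import IUPAC_CODES, Enzyme
from gbskit.synthetic_data import (
    SimConfig,
    simulate_genome,
    simulate_observations,
    simulate_population,
)


def naive_cut_positions(sequence: str, enzyme: Enzyme) -> list[int]:
    """Independent O(n*m) sliding-window IUPAC matcher used as digestion oracle."""
    seq = sequence.upper()
    site = enzyme.site
    out = []
    for i in range(len(seq) - len(site) + 1):
        if all(seq[i + k] in IUPAC_CODES[site[k]] for k in range(len(site))):
            out.append(i + enzyme.cut_offset)
    return out


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(genome_len=300_000, n_chroms=2, n_samples=80, seed=11)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_population(small_genome, small_config):
    sequences, _ = small_genome
    return simulate_population(sequences, small_config)


@pytest.fixture(scope="session")
def small_observed(small_population, small_config):
    return simulate_observations(small_population, small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
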