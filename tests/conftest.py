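import numpy as np
import pytest

from parevo.synthetic import SimulationConfig, simulate_alignment, simulate_polymorphism


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=11, length=20_000, region_length=400_000,
                            n_diploid=10)


@pytest.fixture(scope="session")
def small_alignment(small_cfg):
    """A 20-kb five-taxon alignment with ancestors and its event log."""
    return simulate_alignment(small_cfg)


@pytest.fixture(scope="session")
def small_sites(small_cfg):
    """A 400-kb population sample of 10 diploids plus its reference."""
    return simulate_polymorphism(small_cfg)
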