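"""Shared fixtures: small simulated genomes reused across test modules."""

import numpy as np
import pytest

from tecurate.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def mini_sim():
    """Two families x 8 untruncated copies, zero noise, ~80 kb genome."""
    cfg = SimulationConfig(genome_length=60_000, n_families=2,
                           copies_per_family=8, seed=1)
    return simulate(cfg)


@pytest.fixture(scope="session")
def single_family_sim():
    """One clean 10-copy family with 15 bp TSDs only."""
    cfg = SimulationConfig(
        genome_length=45_000, n_families=1, copies_per_family=10,
        tsd_regime=((15, 1.0, (15,)),), seed=21)
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
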