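import numpy as np
import pandas as pd
import pytest

from spatialevo.simdata import SimulationConfig, simulate_tumor
from spatialevo.variants import PresenceMatrix


@pytest.fixture(scope="session")
def fast_cfg():
    """Small, quick simulation configuration for unit tests."""
    return SimulationConfig(
        lattice_circumference=20,
        lattice_length=30,
        deme_capacity=25,
        target_cells=600,
        mutation_rate=4.0,
        n_founder_mutations=30,
        max_steps=800,
    )


@pytest.fixture(scope="session")
def fast_state(fast_cfg):
    """One surviving tumor under the fast config."""
    seed = 0
    while True:
        seed += 1
        st = simulate_tumor(fast_cfg, seed=seed)
        if st.outcome == "target":
            return st


def make_presence(patterns: dict, regions) -> PresenceMatrix:
    """PresenceMatrix from {mutation: 0/1 vector} over ``regions``."""
    mat = pd.DataFrame(patterns, index=list(regions)).T.astype(bool)
    return PresenceMatrix(patient="PX", matrix=mat, min_alt=3, min_vaf=0.02)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
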