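import dataclasses

import numpy as np
import pytest

from seqherb.effect_sizes import compute_effect_sizes
from seqherb.pipeline import derive_moderator_columns
from seqherb.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small paper-shaped dataset (25 studies) shared across tests."""
    cfg = dataclasses.replace(SimulationConfig(seed=11), n_studies=25)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_es(small_sim):
    """Effect-size table with derived moderator columns for the small dataset."""
    ds, _ = small_sim
    return derive_moderator_columns(compute_effect_sizes(ds.frame))


@pytest.fixture(scope="session")
def recovery_sim():
    """One recovery-config replicate with its truth."""
    return simulate_dataset(SimulationConfig.recovery(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
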