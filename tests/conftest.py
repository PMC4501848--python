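import numpy as np
import pytest

from phosphodyn.simulate import SimulationConfig, simulate_dataset
from phosphodyn.types import TIME_GRID, KineticProfile, PhosphoSiteID


def make_profile(values, stimulus="heat", protein="YFG1", position=12,
                 residue="S", probs=None):
    """A 15-point profile from a value list (None entries become missing)."""
    log2fc = np.array([np.nan if v is None else float(v) for v in values])
    return KineticProfile(
        site=PhosphoSiteID(protein=protein, position=position, residue=residue),
        stimulus=stimulus,
        log2fc=log2fc,
        localization_probs=None if probs is None else np.asarray(probs, dtype=float),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded draw under the default study conditions, shared across tests."""
    config = SimulationConfig(n_sites=500, seed=11)
    matrix, tracks, truth = simulate_dataset(config)
    return config, matrix, tracks, truth


@pytest.fixture
def grid():
    return TIME_GRID
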