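import numpy as np
import pytest

from dropclock.gillespie import (
    build_default_clock,
    ensemble_species_matrix,
    gillespie_ensemble,
)
from dropclock.tables import TrajectorySet


@pytest.fixture(scope="session")
def clock_net():
    return build_default_clock()


@pytest.fixture(scope="session")
def clock_ensemble_64(clock_net):
    """64 default-clock cells over 240 h (shared across tests)."""
    return gillespie_ensemble(clock_net, 64, 240.0, 0.5, seed=1)


@pytest.fixture(scope="session")
def ccg_trajectories_64(clock_ensemble_64):
    sig = ensemble_species_matrix(clock_ensemble_64, "CCG2").astype(float)
    n = sig.shape[0]
    return TrajectorySet(
        values=sig,
        cell_ids=[f"c{i}" for i in range(n)],
        droplet_ids=[f"d{i}" for i in range(n)],
    )
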