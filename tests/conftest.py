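import numpy as np
import pytest

import gscross as g


@pytest.fixture(scope="session")
def map_small():
    """100 markers on 4 linkage groups of 120 cM."""
    return g.simulate_map(100, 4, 120, seed=11)


@pytest.fixture(scope="session")
def map_study():
    """The simulation-study map scale: 356 markers, 19 linkage groups."""
    return g.simulate_map(356, 19, 150, seed=12)


@pytest.fixture(scope="session")
def species_pair_small(map_small):
    """Two related 60-individual panels with 3 subpopulations each."""
    return g.simulate_species_pair(60, 60, map_small, 3, 0.25, 0.3, seed=13)


@pytest.fixture(scope="session")
def family_small(species_pair_small, map_small):
    panel_a, panel_b = species_pair_small
    fams = g.sample_parents_and_families(
        panel_a, panel_b, map_small, n_families=2, n_f1=10, n_f2=80, seed=14
    )
    return fams


@pytest.fixture
def rng():
    return np.random.default_rng(99)
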