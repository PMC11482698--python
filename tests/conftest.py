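import numpy as np
import pytest

import faunalregions as fr


@pytest.fixture(scope="session")
def checklist():
    return fr.load_snake_checklist()


@pytest.fixture(scope="session")
def full_checklist():
    return fr.load_snake_checklist(counted_only=False)


@pytest.fixture(scope="session")
def eco():
    return fr.load_region_ecoregions()


@pytest.fixture(scope="session")
def assignment(eco):
    return fr.kmeans_binary(eco, k=5, seed=0)


@pytest.fixture(scope="session")
def iran_matrix(checklist):
    return checklist.subset_units(fr.IRAN_REGIONS)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_binary_matrix(rng, n_taxa, n_units, p=0.5):
    """Random matrix whose units all have >= 1 presence and taxa are
    non-constant where needed by the caller."""
    while True:
        vals = (rng.random((n_taxa, n_units)) < p).astype(np.int8)
        if vals.sum(axis=0).min() > 0:
            return fr.PresenceAbsenceMatrix(
                vals,
                [f"Genus{i:03d} sp{i}" for i in range(n_taxa)],
                [f"U{j}" for j in range(n_units)],
            )
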