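import numpy as np
import pytest

from bitterevo.binding import load_catalog, load_reference_residues, load_species_variants
from bitterevo.phylo import load_empirical_model, poisson_model


@pytest.fixture(scope="session")
def jtt():
    return load_empirical_model("JTT")


@pytest.fixture(scope="session")
def poisson():
    return poisson_model()


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def table1():
    return load_reference_residues()


@pytest.fixture(scope="session")
def species_variants():
    return load_species_variants()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
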