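import numpy as np
import pytest

from mitokit.reference import CircularGenome
from mitokit.simulate import make_toy_genome


@pytest.fixture(scope="session")
def toy():
    """Small circular genome with planted CSBII motif and one NUMT decoy."""
    return make_toy_genome(L=1200, motif_start=297, numt_spec=((600, 1000, 0.02),), seed=11)


@pytest.fixture(scope="session")
def genome(toy):
    return toy.genome


@pytest.fixture()
def rng():
    return np.random.default_rng(202401)


@pytest.fixture(scope="session")
def small_genome():
    return CircularGenome("chrM", "ACGTACGTAC")
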