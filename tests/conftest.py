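import pytest

from numtrisk.cli import make_fixture
from numtrisk.simgen import generate_mitogenome, simulate_dataset


@pytest.fixture(scope="session")
def mito():
    return generate_mitogenome(seed=1, length=15000, coi_length=1536,
                               frame_offset=1)


@pytest.fixture(scope="session")
def small_dataset():
    """20 barcode-anchored NUMTs over 3 x 30 kb scaffolds."""
    return simulate_dataset(seed=1, n_numts=20)


@pytest.fixture(scope="session")
def c5star_pair():
    return make_fixture("c5star-pair")


@pytest.fixture(scope="session")
def ten_copies():
    return make_fixture("ten-copies")


@pytest.fixture(scope="session")
def residual_mito():
    return make_fixture("residual-mito")
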