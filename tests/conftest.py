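import numpy as np
import pytest

from tmdimer import synthetic as S


@pytest.fixture(scope="session")
def helix_spec():
    return S.IdealHelixSpec()


@pytest.fixture(scope="session")
def helix(helix_spec):
    return S.build_ideal_helix(helix_spec)


@pytest.fixture(scope="session")
def assignment(helix_spec):
    return S.default_assignment(helix_spec)


@pytest.fixture(scope="session")
def sc_helix():
    """Helix with one side-chain bead per residue (for contact tests)."""
    return S.build_ideal_helix(S.IdealHelixSpec(side_chain=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
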