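import numpy as np
import pytest

from allodyn.studies import landscape_run, network_run
from allodyn.synthetic import build_protein_dna_complex


@pytest.fixture(scope="session")
def landscape_study():
    """Seeded landscape-study run: (model, trajectory)."""
    return landscape_run(seed=1)


@pytest.fixture(scope="session")
def network_study():
    """Seeded network-study run: (model, trajectory)."""
    return network_run(seed=5)


@pytest.fixture(scope="session")
def dna_complex():
    """Synthetic protein-DNA complex with planted interaction counts."""
    return build_protein_dna_complex()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
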