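import pytest

from enumol import EnumeratorConfig, compute_properties, enumerate_set
from enumol.fixtures import analytic_conformers, toy_molecule_deck


@pytest.fixture(scope="session")
def default_config():
    """Frozen calibrated enumerator configuration."""
    return EnumeratorConfig()


@pytest.fixture(scope="session")
def small_run(default_config):
    """1,000 enumerated molecules for fast distribution checks."""
    return list(enumerate_set(default_config, 1000, master_seed=7))


@pytest.fixture(scope="session")
def deck():
    return toy_molecule_deck()


@pytest.fixture(scope="session")
def point_sets():
    return analytic_conformers()


@pytest.fixture(scope="session")
def deck_properties(deck):
    return {e.name: compute_properties(e.smiles) for e in deck}
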