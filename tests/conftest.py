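import numpy as np
import pytest

from latentmol import (
    AtomVocabulary,
    BondVocabulary,
    FixtureSpec,
    FlowConfig,
    FlowModel,
    generate_fixture_molecules,
    smiles_to_graph,
)

DN = 9  # node capacity used throughout the toy-scale tests


@pytest.fixture(scope="session")
def atom_vocab():
    return AtomVocabulary()


@pytest.fixture(scope="session")
def bond_vocab():
    return BondVocabulary()


@pytest.fixture(scope="session")
def fixture_smiles():
    """Twenty deterministic curation-clean molecules (<= 9 heavy atoms)."""
    return generate_fixture_molecules(FixtureSpec(n_molecules=20, seed=7))


@pytest.fixture(scope="session")
def fixture_graphs(fixture_smiles, atom_vocab, bond_vocab):
    return [smiles_to_graph(s, atom_vocab, bond_vocab, DN) for s in fixture_smiles]


@pytest.fixture(scope="session")
def toy_flow(atom_vocab, bond_vocab):
    """Freshly initialized 2-layer flow; treated as read-only by tests."""
    config = FlowConfig(dn=DN, dv=atom_vocab.dv, de=bond_vocab.de)
    return FlowModel(config, atom_vocab, bond_vocab, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
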