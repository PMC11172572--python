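"""SMILES <-> graph codec, validity repair and scoring metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem

from latentmol import (
    AtomVocabulary,
    BondVocabulary,
    correct_validity,
    graph_to_smiles,
    normalized_sas,
    smiles_to_graph,
    tanimoto_similarity,
)
from latentmol.chemgraph import graph_from_index_form, normalize_sas, raw_sas
from latentmol.errors import CapacityError, GraphContractError, ParseError, VocabularyError

DN = 9


def canonical(smiles):
    return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))


class TestCodec:
    def test_simple_chain_structure(self, atom_vocab, bond_vocab):
        g = smiles_to_graph("CCO", atom_vocab, bond_vocab, 5)
        assert g.n_atoms == 3
        types = sorted(atom_vocab.symbols[i] for i in g.V.argmax(1)[:3])
        assert types == ["C", "C", "O"]
        assert g.V.argmax(1)[3:].tolist() == [atom_vocab.pad_index] * 2
        # two single bonds, symmetric
        orders = g.E.argmax(2)
        bonded = [(i, j) for i in range(5) for j in range(i + 1, 5)
                  if orders[i, j] != bond_vocab.no_bond_index]
        assert len(bonded) == 2
        assert all(orders[i, j] == 0 for i, j in bonded)  # single-bond channel

    def test_cumulated_diene_has_two_double_bonds(self, atom_vocab, bond_vocab):
        g = smiles_to_graph("O=C=O", atom_vocab, bond_vocab, 5)
        orders = g.E.argmax(2)
        double = [(i, j) for i in range(5) for j in range(i + 1, 5) if orders[i, j] == 1]
        assert len(double) == 2
        # the shared atom of the two double bonds is the carbon
        (a1, b1), (a2, b2) = double
        center = ({a1, b1} & {a2, b2}).pop()
        assert atom_vocab.symbols[g.V.argmax(1)[center]] == "C"

    def test_capacity_error(self, atom_vocab, bond_vocab):
        with pytest.raises(CapacityError):
            smiles_to_graph("CCCCCC", atom_vocab, bond_vocab, 5)

    def test_parse_and_vocabulary_errors(self, atom_vocab, bond_vocab):
        with pytest.raises(ParseError):
            smiles_to_graph("not_a_smiles", atom_vocab, bond_vocab, DN)
        with pytest.raises(VocabularyError):
            smiles_to_graph("C[Si](C)C", atom_vocab, bond_vocab, DN)

    def test_roundtrip_on_fixture_molecules(self, fixture_smiles, atom_vocab, bond_vocab):
        for s in fixture_smiles:
            g = smiles_to_graph(s, atom_vocab, bond_vocab, DN)
            g.validate(atom_vocab, bond_vocab)
            assert graph_to_smiles(g, atom_vocab, bond_vocab) == canonical(s)

    def test_aromatic_ring_kekulized_roundtrip(self, atom_vocab, bond_vocab):
        g = smiles_to_graph("c1ccccc1", atom_vocab, bond_vocab, DN)
        # the stored graph is kekulized: alternating single/double channels
        orders = g.E.argmax(2)[:6, :6]
        assert sorted(np.unique(orders[orders != 3])) == [0, 1]
        assert graph_to_smiles(g, atom_vocab, bond_vocab) == canonical("c1ccccc1")

    def test_empty_graph_decodes_to_failure_marker(self, atom_vocab, bond_vocab):
        g = graph_from_index_form(
            np.full(DN, atom_vocab.pad_index), np.zeros((DN, DN), int),
            DN, atom_vocab, bond_vocab,
        )
        assert graph_to_smiles(g, atom_vocab, bond_vocab) is None

    def test_invariant_violation_is_contract_error(self, atom_vocab, bond_vocab):
        g = smiles_to_graph("CCO", atom_vocab, bond_vocab, 5)
        g.E[0, 1, :] = 0  # break one-hot
        with pytest.raises(GraphContractError):
            graph_to_smiles(g, atom_vocab, bond_vocab)


class TestCorrectValidity:
    def test_valid_graph_returned_unchanged(self, atom_vocab, bond_vocab):
        g = smiles_to_graph("CCO", atom_vocab, bond_vocab, 5)
        assert correct_validity(g, atom_vocab, bond_vocab) is g

    def test_overbonded_carbon_repaired_to_valence_table(self, atom_vocab, bond_vocab):
        # carbon with five single bonds to carbons
        types = np.array([0] * 6 + [atom_vocab.pad_index] * (DN - 6))
        orders = np.zeros((DN, DN), int)
        for j in range(1, 6):
            orders[0, j] = orders[j, 0] = 1
        g = graph_from_index_form(types, orders, DN, atom_vocab, bond_vocab)
        fixed = correct_validity(g, atom_vocab, bond_vocab)
        fixed.validate(atom_vocab, bond_vocab)
        ftypes, forders = fixed.to_index_form(atom_vocab, bond_vocab)
        for i in np.flatnonzero(ftypes != atom_vocab.pad_index):
            assert forders[i].sum() <= 4
        # repair demotes the tie at the lowest partner index first, then
        # keeps the largest remaining component
        assert graph_to_smiles(fixed, atom_vocab, bond_vocab) is not None

    def test_disconnected_keeps_largest_component(self, atom_vocab, bond_vocab):
        # 4-chain and a 2-chain, no bond between them
        types = np.array([0, 0, 0, 0, 2, 2] + [atom_vocab.pad_index] * (DN - 6))
        orders = np.zeros((DN, DN), int)
        for i, j in [(0, 1), (1, 2), (2, 3), (4, 5)]:
            orders[i, j] = orders[j, i] = 1
        g = graph_from_index_form(types, orders, DN, atom_vocab, bond_vocab)
        fixed = correct_validity(g, atom_vocab, bond_vocab)
        assert fixed.n_atoms == 4
        assert graph_to_smiles(fixed, atom_vocab, bond_vocab) == "CCCC"

    def test_idempotent(self, atom_vocab, bond_vocab, rng):
        # random junk graphs: repair twice equals repair once
        for _ in range(20):
            types = rng.integers(0, atom_vocab.dv, size=DN)
            orders = rng.integers(0, 4, size=(DN, DN))
            orders = np.triu(orders, 1)
            orders = orders + orders.T
            orders[types == atom_vocab.pad_index, :] = 0
            orders[:, types == atom_vocab.pad_index] = 0
            g = graph_from_index_form(types, orders, DN, atom_vocab, bond_vocab)
            once = correct_validity(g, atom_vocab, bond_vocab)
            twice = correct_validity(once, atom_vocab, bond_vocab)
            assert np.array_equal(once.V, twice.V) and np.array_equal(once.E, twice.E)
            assert graph_to_smiles(once, atom_vocab, bond_vocab) is not None or once.n_atoms == 0


class TestMetrics:
    def test_self_similarity_is_one(self):
        assert tanimoto_similarity("CCO", "CCO") == 1.0

    def test_disjoint_fingerprints_give_zero(self):
        assert tanimoto_similarity("C", "O") == 0.0

    @given(st.integers(0, 19), st.integers(0, 19))
    @settings(deadline=None, max_examples=25)
    def test_symmetry(self, fixture_smiles, i, j):
        a, b = fixture_smiles[i], fixture_smiles[j]
        assert tanimoto_similarity(a, b) == tanimoto_similarity(b, a)

    def test_matches_independent_bit_set_enumeration(self):
        # independent route: unfolded Morgan environment counts, folded by
        # hash modulo the bit length, compared as explicit python sets
        radius, n_bits = 2, 2048
        def bit_set(smiles):
            mol = Chem.MolFromSmiles(smiles)
            info = AllChem.GetMorganFingerprint(mol, radius)
            return {h % n_bits for h in info.GetNonzeroElements()}
        for a, b in [("CCO", "CCC"), ("c1ccccc1", "C1CCCCC1"), ("CC(=O)O", "CCO")]:
            sa, sb = bit_set(a), bit_set(b)
            expected = len(sa & sb) / len(sa | sb)
            assert tanimoto_similarity(a, b, radius, n_bits) == pytest.approx(expected)

    def test_sas_normalization_endpoints(self):
        assert normalize_sas(1.0) == 0.0
        assert normalize_sas(10.0) == 1.0

    def test_sas_range_and_ordering(self, fixture_smiles):
        for s in fixture_smiles:
            assert 0.0 <= normalized_sas(s) <= 1.0
        simple = normalized_sas("CCO")
        gnarly = normalized_sas("CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2(O)C#C")
        assert simple < gnarly

    def test_raw_score_within_native_scale(self):
        assert 1.0 <= raw_sas("CCO") <= 10.0
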