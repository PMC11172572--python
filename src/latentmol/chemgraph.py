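"""SMILES <-> one-hot graph codec and candidate-scoring metrics.

A molecule is a pair of binary tensors: a node-type matrix ``V`` of
shape (dn, dv) and an edge-type tensor ``E`` of shape (dn, dn, de).
Heavy atoms only — hydrogens are implicit.  The last node channel is a
padding/virtual type and the last edge channel means "no bond"; aromatic
rings are kekulized before encoding so the bond channels are exactly
{single, double, triple, none}.

The module also provides the two metrics used to score generated
candidates: Tanimoto similarity of Morgan (circular) fingerprints and a
synthetic-accessibility score normalized from its native [1, 10] range
to [0, 1] (lower = easier to make).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .errors import CapacityError, GraphContractError, ParseError, VocabularyError

RDLogger.DisableLog("rdApp.*")

#: Heavy elements commonly found in organic compounds (the curation whitelist,
#: hydrogen excluded since hydrogens are implicit).
DEFAULT_ELEMENTS = ("C", "N", "O", "F", "P", "S", "Cl", "Se", "Br", "I")

#: Maximum total bond order per neutral atom used by :func:`correct_validity`.
VALENCE_TABLE = {
    "C": 4, "N": 3, "O": 2, "F": 1, "P": 5,
    "S": 6, "Cl": 1, "Se": 6, "Br": 1, "I": 1,
}

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


@dataclass(frozen=True)
class AtomVocabulary:
    """Ordered heavy-atom element symbols plus a reserved padding type.

    The padding/virtual type always occupies the *last* index ``pad_index``.
    """

    symbols: tuple = DEFAULT_ELEMENTS

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("atom symbols must be unique")
        if "H" in self.symbols:
            raise ValueError("hydrogen is implicit and never a graph node")

    @property
    def dv(self) -> int:
        return len(self.symbols) + 1

    @property
    def pad_index(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise VocabularyError(f"element {symbol!r} not in vocabulary {self.symbols}") from None


@dataclass(frozen=True)
class BondVocabulary:
    """Bond orders {single, double, triple} plus a reserved no-bond channel (last)."""

    bond_orders: tuple = (1, 2, 3)

    @property
    def de(self) -> int:
        return len(self.bond_orders) + 1

    @property
    def no_bond_index(self) -> int:
        return len(self.bond_orders)


@dataclass
class MolGraph:
    """One-hot molecular graph with fixed node capacity ``dn``.

    Invariants (checked by :meth:`validate`): every row of ``V`` and
    every pair slice ``E[i, j, :]`` is one-hot; ``E`` is symmetric in its
    first two axes; the diagonal and every pair involving a padding node
    carry the no-bond channel.
    """

    V: np.ndarray
    E: np.ndarray
    n_atoms: int
    dn: int

    def validate(self, atom_vocab: AtomVocabulary, bond_vocab: BondVocabulary) -> None:
        dv, de = atom_vocab.dv, bond_vocab.de
        if self.V.shape != (self.dn, dv) or self.E.shape != (self.dn, self.dn, de):
            raise GraphContractError("tensor shapes do not match dn/dv/de")
        if not (np.isin(self.V, (0, 1)).all() and np.isin(self.E, (0, 1)).all()):
            raise GraphContractError("tensors must be binary")
        if not (self.V.sum(axis=1) == 1).all():
            raise GraphContractError("V rows must be one-hot")
        if not (self.E.sum(axis=2) == 1).all():
            raise GraphContractError("E pair slices must be one-hot")
        if not (self.E == self.E.transpose(1, 0, 2)).all():
            raise GraphContractError("E must be symmetric")
        nb = bond_vocab.no_bond_index
        if not (self.E[np.arange(self.dn), np.arange(self.dn), nb] == 1).all():
            raise GraphContractError("diagonal must be no-bond")
        pad = self.V[:, atom_vocab.pad_index] == 1
        if int((~pad).sum()) != self.n_atoms:
            raise GraphContractError("n_atoms inconsistent with padding rows")
        if pad.any():
            if not (self.E[pad, :, nb] == 1).all() or not (self.E[:, pad, nb] == 1).all():
                raise GraphContractError("padding nodes must have no bonds")

    # index-form helpers used by the codec, the validity repair and decoding
    def to_index_form(self, atom_vocab, bond_vocab):
        types = self.V.argmax(axis=1)
        channels = self.E.argmax(axis=2)
        orders = np.zeros((self.dn, self.dn), dtype=int)
        for k, order in enumerate(bond_vocab.bond_orders):
            orders[channels == k] = order
        return types, orders


def graph_from_index_form(types, orders, dn, atom_vocab, bond_vocab) -> MolGraph:
    """Build a one-hot :class:`MolGraph` from atom-type indices and a bond-order matrix.

    Non-padding atoms are compacted to the leading rows (relative order
    preserved); diagonal and padding pairs are forced to no-bond.
    """
    types = np.asarray(types)
    orders = np.asarray(orders)
    keep = np.flatnonzero(types != atom_vocab.pad_index)
    dv, de, nb = atom_vocab.dv, bond_vocab.de, bond_vocab.no_bond_index
    V = np.zeros((dn, dv), dtype=np.int8)
    E = np.zeros((dn, dn, de), dtype=np.int8)
    V[:, atom_vocab.pad_index] = 1
    E[:, :, nb] = 1
    order_to_channel = {o: k for k, o in enumerate(bond_vocab.bond_orders)}
    for new_i, old_i in enumerate(keep):
        V[new_i, atom_vocab.pad_index] = 0
        V[new_i, types[old_i]] = 1
    for a, i in enumerate(keep):
        for b, j in enumerate(keep):
            if a == b:
                continue
            o = int(orders[i, j])
            if o > 0:
                E[a, b, nb] = 0
                E[a, b, order_to_channel[o]] = 1
    return MolGraph(V=V, E=E, n_atoms=len(keep), dn=dn)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def smiles_to_graph(smiles, atom_vocab, bond_vocab, dn) -> MolGraph:
    """Encode a SMILES string as a one-hot graph with capacity ``dn``.

    Atoms are reordered by the molecule's canonical atom ranking so the
    encoding is deterministic for a given canonical SMILES; aromatic
    rings are kekulized first.
    """
    mol = _mol_from_smiles(smiles)
    n = mol.GetNumHeavyAtoms()
    if n > dn:
        raise CapacityError(f"{n} heavy atoms exceed capacity dn={dn}")
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in atom_vocab.symbols:
            raise VocabularyError(f"element {atom.GetSymbol()!r} not in vocabulary")
        if atom.GetFormalCharge() != 0:
            raise VocabularyError("charged atoms cannot be represented (neutralize upstream)")
    ranks = list(Chem.CanonicalRankAtoms(mol))
    perm = sorted(range(n), key=lambda i: ranks[i])
    mol = Chem.RenumberAtoms(mol, perm)
    Chem.Kekulize(mol, clearAromaticFlags=True)

    types = np.full(dn, atom_vocab.pad_index, dtype=int)
    for atom in mol.GetAtoms():
        types[atom.GetIdx()] = atom_vocab.index(atom.GetSymbol())
    orders = np.zeros((dn, dn), dtype=int)
    for bond in mol.GetBonds():
        o = int(bond.GetBondTypeAsDouble())
        if o not in bond_vocab.bond_orders:
            raise VocabularyError(f"bond order {o} not representable")
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        orders[i, j] = orders[j, i] = o
    return graph_from_index_form(types, orders, dn, atom_vocab, bond_vocab)


def graph_to_mol(graph, atom_vocab, bond_vocab):
    """Build an (unsanitized) RDKit molecule from a graph; empty graph -> None."""
    types, orders = graph.to_index_form(atom_vocab, bond_vocab)
    keep = np.flatnonzero(types != atom_vocab.pad_index)
    if len(keep) == 0:
        return None
    rw = Chem.RWMol()
    index_map = {}
    for i in keep:
        index_map[i] = rw.AddAtom(Chem.Atom(atom_vocab.symbols[types[i]]))
    for a_pos, i in enumerate(keep):
        for j in keep[a_pos + 1 :]:
            if orders[i, j] > 0:
                rw.AddBond(index_map[i], index_map[j], _BOND_TYPES[int(orders[i, j])])
    return rw.GetMol()


def graph_to_smiles(graph, atom_vocab, bond_vocab):
    """Decode a graph to canonical SMILES, or ``None`` if chemically invalid.

    Raises :class:`GraphContractError` for invariant-violating inputs —
    a contract breach, distinct from mere chemical invalidity.
    """
    graph.validate(atom_vocab, bond_vocab)
    mol = graph_to_mol(graph, atom_vocab, bond_vocab)
    if mol is None:
        return None
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def correct_validity(graph, atom_vocab, bond_vocab) -> MolGraph:
    """Repair a graph into a chemically valid molecule; valid inputs pass through.

    Repair is deterministic and minimal-change: while an atom's total
    bond order exceeds its standard maximum valence, its highest-order
    bond is demoted by one step (ties broken by lowest partner index);
    if the result is disconnected only the largest connected component
    (by heavy-atom count, ties by lowest atom index) is retained,
    mirroring the ion-pair curation rule.  The function is total and
    idempotent; in the worst case it returns a single-atom molecule.
    """
    graph.validate(atom_vocab, bond_vocab)
    types, orders = graph.to_index_form(atom_vocab, bond_vocab)
    orders = orders.copy()
    atoms = np.flatnonzero(types != atom_vocab.pad_index)
    changed = False

    # valence repair (totals only ever decrease, one ascending pass suffices)
    for i in atoms:
        max_val = VALENCE_TABLE[atom_vocab.symbols[types[i]]]
        while orders[i].sum() > max_val:
            partners = np.flatnonzero(orders[i] > 0)
            best = max(partners, key=lambda j: (orders[i, j], -j))
            orders[i, best] -= 1
            orders[best, i] -= 1
            changed = True

    # largest connected component
    if len(atoms) > 0:
        seen, components = set(), []
        for start in atoms:
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in np.flatnonzero(orders[u] > 0):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            components.append(sorted(comp))
        if len(components) > 1:
            components.sort(key=lambda c: (-len(c), min(c)))
            dropped = {u for c in components[1:] for u in c}
            for u in dropped:
                types[u] = atom_vocab.pad_index
                orders[u, :] = 0
                orders[:, u] = 0
            changed = True

    if not changed:
        return graph

    repaired = graph_from_index_form(types, orders, graph.dn, atom_vocab, bond_vocab)
    if graph_to_smiles(repaired, atom_vocab, bond_vocab) is None and repaired.n_atoms > 0:
        # last-resort fallback: keep only the first atom
        t2 = np.full(graph.dn, atom_vocab.pad_index, dtype=int)
        t2[0] = types[np.flatnonzero(types != atom_vocab.pad_index)[0]]
        repaired = graph_from_index_form(
            t2, np.zeros((graph.dn, graph.dn), dtype=int), graph.dn, atom_vocab, bond_vocab
        )
    return repaired


# ---------------------------------------------------------------------------
# candidate-scoring metrics
# ---------------------------------------------------------------------------

def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048):
    """Folded Morgan (circular) fingerprint bit vector of a molecule."""
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprint(mol)


def tanimoto_similarity(smiles_a, smiles_b, radius: int = 2, n_bits: int = 2048) -> float:
    """|A ∩ B| / |A ∪ B| over the two molecules' Morgan fingerprint bit sets."""
    fa = morgan_fingerprint(smiles_a, radius, n_bits)
    fb = morgan_fingerprint(smiles_b, radius, n_bits)
    return float(DataStructs.TanimotoSimilarity(fa, fb))


_sascorer = None


def _get_sascorer():
    global _sascorer
    if _sascorer is None:
        import os
        import sys

        from rdkit.Chem import RDConfig

        path = os.path.join(RDConfig.RDContribDir, "SA_Score")
        if path not in sys.path:
            sys.path.append(path)
        import sascorer  # fragment-contribution + complexity-penalty score

        _sascorer = sascorer
    return _sascorer


def raw_sas(smiles: str) -> float:
    """Raw synthetic-accessibility score on its native [1, 10] scale."""
    mol = _mol_from_smiles(smiles)
    return float(_get_sascorer().calculateScore(mol))


def normalize_sas(raw: float) -> float:
    """Affine map of a raw [1, 10] score onto [0, 1]."""
    return float(np.clip((raw - 1.0) / 9.0, 0.0, 1.0))


def normalized_sas(smiles: str) -> float:
    """Synthetic-accessibility score in [0, 1]; lower = easier to synthesize."""
    return normalize_sas(raw_sas(smiles))
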