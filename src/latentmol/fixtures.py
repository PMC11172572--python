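"""Synthetic screening-table generator with known statistical structure.

Emits small, valid, whitelist-only organic molecules paired with a GI50
score that is an exact linear function of cheap structural descriptors
plus Gaussian noise:

    GI50 = A * (heavy-atom count) + B * (ring count) + eps,
    eps ~ N(0, noise_sd^2),  A = -0.5,  B = -1.0.

Bigger / ringier molecules are therefore "more potent" (lower GI50), so
the regression head has a recoverable signal and the latent optimizer a
learnable descent direction at toy scale.  With ``include_dirty_rows``
the table additionally carries one hand-audited specimen of every
curation hazard — an ion pair, a charged-oxygen molecule, an
off-whitelist molecule, an unparseable SMILES, an exact replicate pair
and a sanitization-collision pair — together with a ledger of the exact
expected post-curation outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import FeasibilityError

#: Structure -> score coefficients (heavy atoms, rings).
GI50_ATOM_COEF = -0.5
GI50_RING_COEF = -1.0

CELL_LINE = "SK-MEL-28"
OTHER_CELL_LINE = "MCF7"

_SCAFFOLDS = (
    "C", "CC", "CCC", "CCO", "CCN", "COC", "CC=C", "CC#N",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCOC1", "C1CCNC1",
    "c1ccccc1", "C1CCNCC1", "C1COCCO1",
)
_SUBSTITUENTS = ("C", "C", "C", "O", "O", "N", "F", "Cl", "Br", "S")

# molecules reserved for the hand-audited dirty rows; the clean generator
# must never emit their canonical forms
_REPLICATE_SMILES = "NCCO"
_COLLISION_SOURCES = ("CC(=O)[O-].[Na+]", "CC(=O)[O-].[K+]")
_ION_PAIR_SMILES = "OCC(=O)[O-].[Na+]"
_CHARGED_OXYGEN_SMILES = "C[O+](C)C"
_OFF_WHITELIST_SMILES = "C[Si](C)C"
_UNPARSEABLE_SMILES = "not_a_smiles"


def _canonical(smiles: str) -> str:
    return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))

REPLICATE_CANONICAL = _canonical(_REPLICATE_SMILES)
COLLISION_CANONICAL = _canonical("CC(=O)O")
ION_PAIR_CANONICAL = _canonical("OCC(=O)O")
_RESERVED = {REPLICATE_CANONICAL, COLLISION_CANONICAL, ION_PAIR_CANONICAL}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic screening table."""

    n_molecules: int = 50
    max_heavy_atoms: int = 9
    noise_sd: float = 0.5
    seed: int = 0
    include_dirty_rows: bool = False

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.max_heavy_atoms < 2:
            raise ValueError("max_heavy_atoms must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_fixture_molecules(spec: FixtureSpec) -> list:
    """Seeded random assembly of unique, curation-clean SMILES.

    A scaffold is drawn from a curated set (alkanes, alcohols, amines,
    ethers, simple rings) and decorated with single-bonded substituents
    at atoms with free valence, up to ``max_heavy_atoms`` heavy atoms.
    Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    scaffolds = [
        s for s in _SCAFFOLDS
        if Chem.MolFromSmiles(s).GetNumHeavyAtoms() <= spec.max_heavy_atoms
    ]
    out, seen = [], set(_RESERVED)
    attempts, max_attempts = 0, 300 * spec.n_molecules + 1000
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise FeasibilityError(
                f"could not assemble {spec.n_molecules} unique molecules with "
                f"<= {spec.max_heavy_atoms} heavy atoms"
            )
        scaffold = scaffolds[rng.integers(len(scaffolds))]
        mol = Chem.RWMol(Chem.MolFromSmiles(scaffold))
        room = spec.max_heavy_atoms - mol.GetNumHeavyAtoms()
        for _ in range(int(rng.integers(0, room + 1))):
            mol.UpdatePropertyCache(strict=False)
            sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]
            if not sites:
                break
            site = sites[rng.integers(len(sites))]
            new = mol.AddAtom(Chem.Atom(_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]))
            mol.AddBond(site, new, Chem.BondType.SINGLE)
        try:
            probe = mol.GetMol()
            Chem.SanitizeMol(probe)
        except Exception:
            continue
        smiles = Chem.MolToSmiles(probe)
        if smiles in seen:
            continue
        seen.add(smiles)
        out.append(smiles)
    return out


def structural_gi50(smiles: str) -> float:
    """The exact deterministic part of the synthetic structure -> score map."""
    mol = Chem.MolFromSmiles(smiles)
    return (
        GI50_ATOM_COEF * mol.GetNumHeavyAtoms()
        + GI50_RING_COEF * mol.GetRingInfo().NumRings()
    )


def assign_synthetic_gi50(smiles_list, spec: FixtureSpec):
    """Build screening-table rows for a SMILES list; returns (table, ledger).

    The table uses the same CSV dialect the curation module reads.  The
    ledger records the exact expected curation outcome (row and
    rejection counts, the replicate-mean and collision-min entries) and
    is only populated with hazards when ``include_dirty_rows`` is set.
    """
    rng = np.random.default_rng(spec.seed + 10007)
    rows = []
    nsc = 1000
    for smiles in smiles_list:
        gi50 = structural_gi50(smiles) + rng.normal(0.0, spec.noise_sd)
        rows.append((nsc, smiles, CELL_LINE, round(float(gi50), 6)))
        nsc += 1

    n_clean = len(smiles_list)
    ledger = {
        "n_clean": n_clean,
        "rows_in": n_clean,
        "rows_kept": n_clean,
        "rejected": {"parse": 0, "element": 0, "charged_oxygen": 0, "charge": 0},
        "unique_molecules": n_clean,
    }
    if spec.include_dirty_rows:
        dirty = [
            (nsc + 0, _REPLICATE_SMILES, CELL_LINE, -5.0),
            (nsc + 0, _REPLICATE_SMILES, CELL_LINE, -6.0),
            (nsc + 1, _COLLISION_SOURCES[0], CELL_LINE, -5.0),
            (nsc + 2, _COLLISION_SOURCES[1], CELL_LINE, -7.0),
            (nsc + 3, _ION_PAIR_SMILES, CELL_LINE, -4.0),
            (nsc + 4, _CHARGED_OXYGEN_SMILES, CELL_LINE, -3.0),
            (nsc + 5, _OFF_WHITELIST_SMILES, CELL_LINE, -3.0),
            (nsc + 6, _UNPARSEABLE_SMILES, CELL_LINE, -3.0),
        ]
        rows.extend(dirty)
        ledger.update(
            rows_in=n_clean + 8,
            rows_kept=n_clean + 5,
            rejected={"parse": 1, "element": 1, "charged_oxygen": 1, "charge": 0},
            unique_molecules=n_clean + 3,
            replicate_entry={"smiles": REPLICATE_CANONICAL, "gi50": -5.5},
            collision_entry={"smiles": COLLISION_CANONICAL, "gi50": -7.0},
            ion_pair_entry={"smiles": ION_PAIR_CANONICAL, "gi50": -4.0},
        )
    # off-panel rows exercise the cell-line filter; they never reach curation
    rows.append((9001, "CCC", OTHER_CELL_LINE, -2.0))
    rows.append((9002, "CCO", OTHER_CELL_LINE, -2.5))

    table = pd.DataFrame(rows, columns=["NSC", "SMILES", "CELL_NAME", "AVERAGE"])
    return table, ledger


def write_fixture_table(spec: FixtureSpec, csv_path, ledger_path=None):
    """Generate molecules, score them and write the CSV (+ ledger JSON)."""
    smiles_list = generate_fixture_molecules(spec)
    table, ledger = assign_synthetic_gi50(smiles_list, spec)
    table.to_csv(csv_path, index=False)
    if ledger_path is not None:
        with open(ledger_path, "w") as fh:
            json.dump(ledger, fh, indent=2)
    return table, ledger
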