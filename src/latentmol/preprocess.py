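"""Curation of GI50 growth-inhibition screening tables.

Turns a raw per-experiment screening table (compound identifier, SMILES,
cell line, GI50) into a training set of unique molecules, each with one
GI50 value.  GI50 is treated as an opaque log-scale score where lower
means more potent.  The curation rules, applied in order:

1. keep only rows for the requested cell line;
2. drop unparseable SMILES;
3. for multi-fragment records ("ion pairs"), keep only the largest
   connected component (heavy-atom count; ties by lexicographically
   smallest canonical SMILES);
4. drop molecules containing elements outside the organic whitelist;
5. drop molecules with a positively charged oxygen;
6. neutralize remaining formal charges where chemically possible, else
   drop the record;
7. average GI50 over replicate experiments of the same source structure;
8. when distinct source structures collapse to one canonical SMILES
   through sanitization, keep only the minimum (most potent) of the
   per-structure averages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemgraph import DEFAULT_ELEMENTS, AtomVocabulary, BondVocabulary
from .errors import SchemaError

#: Whitelisted heavy elements; hydrogen is additionally allowed implicitly.
DEFAULT_WHITELIST = frozenset(DEFAULT_ELEMENTS)

#: Column names of the public NCI-60 GI50 release.
DEFAULT_COLUMNS = {
    "nsc": "NSC",
    "smiles": "SMILES",
    "cell_line": "CELL_NAME",
    "gi50": "AVERAGE",
}


class RejectReason(str, Enum):
    PARSE = "parse"
    ELEMENT = "element"
    CHARGED_OXYGEN = "charged_oxygen"
    CHARGE = "charge"


@dataclass(frozen=True)
class ScreeningRecord:
    """One screening experiment: compound id, structure, cell line, GI50."""

    nsc_id: int
    smiles: str
    cell_line: str
    gi50: float

    def __post_init__(self):
        if self.nsc_id < 0:
            raise ValueError("nsc_id must be non-negative")
        if not self.smiles:
            raise ValueError("smiles must be non-empty")


@dataclass(frozen=True)
class FilterResult:
    """Outcome of :func:`filter_record`: a sanitized record or a rejection."""

    record: ScreeningRecord | None
    reason: RejectReason | None

    @property
    def kept(self) -> bool:
        return self.record is not None


@dataclass
class ProcessedDataset:
    """Curated unique molecules with one GI50 each, plus derived model dims."""

    entries: list  # list of (canonical_smiles, gi50)
    atom_vocab: AtomVocabulary
    bond_vocab: BondVocabulary
    dn: int
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)

    @property
    def smiles(self):
        return [s for s, _ in self.entries]

    @property
    def gi50(self):
        return np.array([g for _, g in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["canonical_smiles", "gi50"])

    def save(self, curated_csv, vocab_json, provenance_json) -> None:
        self.to_frame().to_csv(curated_csv, index=False)
        with open(vocab_json, "w") as fh:
            json.dump(
                {
                    "atom_symbols": list(self.atom_vocab.symbols),
                    "bond_orders": list(self.bond_vocab.bond_orders),
                    "dn": self.dn,
                },
                fh,
                indent=2,
            )
        with open(provenance_json, "w") as fh:
            json.dump(self.provenance, fh, indent=2)

    @classmethod
    def load(cls, curated_csv, vocab_json, provenance_json=None) -> "ProcessedDataset":
        df = pd.read_csv(curated_csv)
        with open(vocab_json) as fh:
            meta = json.load(fh)
        prov = {}
        if provenance_json is not None:
            with open(provenance_json) as fh:
                prov = json.load(fh)
        return cls(
            entries=list(zip(df["canonical_smiles"], df["gi50"].astype(float))),
            atom_vocab=AtomVocabulary(tuple(meta["atom_symbols"])),
            bond_vocab=BondVocabulary(tuple(meta["bond_orders"])),
            dn=int(meta["dn"]),
            provenance=prov,
        )


def parse_screening_table(path, cell_line, columns=None) -> list:
    """Read a delimited screening table and keep rows for one cell line.

    Malformed rows (missing SMILES/GI50, non-numeric GI50) are counted
    and skipped, not fatal.  A missing required column raises
    :class:`SchemaError`.
    """
    cols = dict(DEFAULT_COLUMNS, **(columns or {}))
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"required column(s) absent: {missing}")
    records = []
    for _, row in df.iterrows():
        if str(row[cols["cell_line"]]).strip() != cell_line:
            continue
        try:
            records.append(
                ScreeningRecord(
                    nsc_id=int(row[cols["nsc"]]),
                    smiles=str(row[cols["smiles"]]),
                    cell_line=cell_line,
                    gi50=float(row[cols["gi50"]]),
                )
            )
        except (ValueError, TypeError):
            continue
    return records


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    # largest heavy-atom count; ties by lexicographically smallest canonical SMILES
    return min(frags, key=lambda m: (-m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))


def _neutralize(mol: Chem.Mol) -> Chem.Mol | None:
    """Zero out formal charges where an H count adjustment makes that legal."""
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        q = atom.GetFormalCharge()
        if q == 0:
            continue
        hs = atom.GetNumExplicitHs() + atom.GetNumImplicitHs()
        if q > 0 and hs >= q:  # e.g. protonated amine -> amine
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(max(atom.GetNumExplicitHs() - q, 0))
        elif q < 0:  # e.g. carboxylate -> acid
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - q)
        else:
            return None
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        return None
    return mol


def filter_record(record: ScreeningRecord, whitelist=DEFAULT_WHITELIST) -> FilterResult:
    """Apply the structure-level curation rules to a single record.

    Ion pairs are reduced to their largest connected component before
    the element / charged-oxygen checks run on the retained fragment.
    Surviving records carry the canonicalized (neutralized) SMILES.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        return FilterResult(None, RejectReason.PARSE)
    mol = _largest_fragment(mol)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "H":
            continue
        if atom.GetSymbol() not in whitelist:
            return FilterResult(None, RejectReason.ELEMENT)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "O" and atom.GetFormalCharge() > 0:
            return FilterResult(None, RejectReason.CHARGED_OXYGEN)
    if any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        mol = _neutralize(mol)
        if mol is None:
            return FilterResult(None, RejectReason.CHARGE)
    canonical = Chem.MolToSmiles(mol)
    return FilterResult(
        ScreeningRecord(record.nsc_id, canonical, record.cell_line, record.gi50), None
    )


def apply_filters(records, whitelist=DEFAULT_WHITELIST):
    """Filter a record list; returns (kept records, rejection counts)."""
    kept, rejected = [], {r.value: 0 for r in RejectReason}
    for rec in records:
        res = filter_record(rec, whitelist)
        if res.kept:
            kept.append((rec, res.record))
        else:
            rejected[res.reason.value] += 1
    return kept, rejected


def build_dataset(records, whitelist=DEFAULT_WHITELIST) -> ProcessedDataset:
    """Run the full curation on raw records and derive the model dimensions.

    Grouping order: sanitize/canonicalize each record, mean-average the
    GI50 of replicate experiments of the same *source* structure (the raw
    SMILES string), then resolve cross-structure canonical collisions by
    keeping the minimum per-structure average (lower GI50 = more potent).
    """
    kept_pairs, rejected = apply_filters(records, whitelist)

    by_source: dict = {}
    for raw, clean in kept_pairs:
        by_source.setdefault(raw.smiles, []).append(clean)
    per_structure = []  # (canonical_smiles, mean gi50)
    for group in by_source.values():
        canonical = group[0].smiles
        per_structure.append((canonical, float(np.mean([r.gi50 for r in group]))))

    by_canonical: dict = {}
    for canonical, mean_gi50 in per_structure:
        if canonical not in by_canonical or mean_gi50 < by_canonical[canonical]:
            by_canonical[canonical] = mean_gi50
    entries = sorted(by_canonical.items())

    elements = set()
    dn = 0
    for smiles, _ in entries:
        mol = Chem.MolFromSmiles(smiles)
        dn = max(dn, mol.GetNumHeavyAtoms())
        elements.update(a.GetSymbol() for a in mol.GetAtoms())
    symbols = tuple(e for e in DEFAULT_ELEMENTS if e in elements) or ("C",)

    provenance = {
        "rows_in": len(records),
        "rows_kept": len(kept_pairs),
        "rejected": rejected,
        "source_structures": len(per_structure),
        "replicate_rows_merged": len(kept_pairs) - len(per_structure),
        "collisions_resolved": len(per_structure) - len(entries),
        "unique_molecules": len(entries),
    }
    return ProcessedDataset(
        entries=entries,
        atom_vocab=AtomVocabulary(symbols),
        bond_vocab=BondVocabulary(),
        dn=dn,
        provenance=provenance,
    )
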