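"""Molecule parsing, pH standardization, featurization, and dataset I/O.

All chemistry goes through RDKit; molecules are exchanged as canonical
SMILES. Graphs are heavy-atom only (hydrogens implicit), which matches how
atom-level explanation masks are rendered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "Molecule",
    "FeatureSpec",
    "FeaturizedGraph",
    "LabeledRecord",
    "DatasetReadResult",
    "ParseError",
    "FeaturizationError",
    "parse_smiles",
    "canonical_form",
    "standardize",
    "to_graph",
    "read_dataset",
    "write_dataset",
]


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""


class FeaturizationError(ValueError):
    """Raised when a molecule cannot be featurized under a FeatureSpec."""


@dataclass
class Molecule:
    """A heavy-atom molecular graph wrapping an RDKit mol.

    ``canonical_form`` is the canonical SMILES and round-trips to an
    isomorphic molecule; it is the interchange/deduplication key everywhere.
    """

    rdmol: Chem.Mol
    canonical_form: str

    @property
    def num_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def num_bonds(self) -> int:
        return self.rdmol.GetNumBonds()

    @property
    def atoms(self) -> list[tuple[str, int, bool]]:
        """(element symbol, formal charge, aromatic flag) per atom."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
            for a in self.rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[int, int, object]]:
        """(begin index, end index, order) per bond; order is 1/2/3 or 'aromatic'."""
        out = []
        for b in self.rdmol.GetBonds():
            if b.GetIsAromatic():
                order: object = "aromatic"
            else:
                order = int(b.GetBondTypeAsDouble())
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        return out


def parse_smiles(smiles: str) -> Molecule:
    """Parse SMILES into a Molecule with perceived aromaticity, implicit H.

    Raises ParseError naming the offending input on unparseable or
    valence-violating SMILES.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES string")
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ParseError(f"cannot parse SMILES: {smiles!r}")
    return Molecule(rdmol=rdmol, canonical_form=Chem.MolToSmiles(rdmol))


def canonical_form(mol: Molecule) -> str:
    """Canonical SMILES; identical for isomorphic molecules regardless of atom order."""
    return Chem.MolToSmiles(mol.rdmol)


# --------------------------------------------------------------------------
# pH standardization: a fixed, ordered (pattern, pKa, action) rule table.
# An acid rule fires when pH > pKa (deprotonate), a base rule when pH < pKa
# (protonate). First matching rule per site wins; unmatched molecules pass
# through unchanged. This is a documented deterministic stand-in for a pKa
# predictor and covers the common ionizable groups.
# --------------------------------------------------------------------------

# (name, SMARTS, index of the site atom within the match, pKa, kind)
PROTONATION_RULES: list[tuple[str, str, int, float, str]] = [
    ("carboxylic acid", "[CX3](=O)[OX2H1]", 2, 4.8, "acid"),
    ("phosphate/phosphonate O-H", "[OX2H1][PX4](=O)", 0, 2.0, "acid"),
    ("tetrazole N-H", "[nH]1nnnc1", 0, 4.9, "acid"),
    ("guanidine", "[NX3;+0][CX3;+0](=[NX2;+0])[NX3;+0]", 2, 13.6, "base"),
    (
        "aliphatic amine",
        "[NX3;+0;H0,H1,H2;!$([N]-[CX3]=[O,S,N]);!$([N]-a);!$([N]=*);!$([N]#*)]",
        0,
        10.6,
        "base",
    ),
]


def standardize(mol: Molecule, pH: float = 7.4) -> Molecule:
    """Set charge states by the ordered protonation rule table at the given pH.

    Idempotent: charged forms no longer match the neutral patterns. Molecules
    matching no rule pass through unchanged.
    """
    rw = Chem.RWMol(mol.rdmol)
    modified: set[int] = set()
    for _name, smarts, site_pos, pka, kind in PROTONATION_RULES:
        patt = Chem.MolFromSmarts(smarts)
        fires = (pH > pka) if kind == "acid" else (pH < pka)
        if not fires:
            continue
        for match in rw.GetSubstructMatches(patt):
            site = match[site_pos]
            if site in modified:
                continue
            atom = rw.GetAtomWithIdx(site)
            if kind == "acid":
                if atom.GetTotalNumHs() < 1:
                    continue
                atom.SetFormalCharge(atom.GetFormalCharge() - 1)
                atom.SetNumExplicitHs(max(atom.GetTotalNumHs() - 1, 0))
                atom.SetNoImplicit(True)
            else:
                atom.SetFormalCharge(atom.GetFormalCharge() + 1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
            modified.add(site)
    if not modified:
        return mol
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Molecule(rdmol=out, canonical_form=Chem.MolToSmiles(out))


# --------------------------------------------------------------------------
# Featurization
# --------------------------------------------------------------------------

_BOND_ORDERS = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE,
                Chem.BondType.AROMATIC)


@dataclass(frozen=True)
class FeatureSpec:
    """Fixed feature layout shared by every molecule under one spec.

    Node vector: one-hot element | degree | formal charge | aromatic | in-ring.
    Edge vector: one-hot bond order (single, double, triple, aromatic) | in-ring.
    """

    elements: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")

    @property
    def node_dim(self) -> int:
        return len(self.elements) + 4

    @property
    def edge_dim(self) -> int:
        return 5

    def to_dict(self) -> dict:
        return {"elements": list(self.elements)}

    @staticmethod
    def from_dict(d: dict) -> "FeatureSpec":
        return FeatureSpec(elements=tuple(d["elements"]))


@dataclass
class FeaturizedGraph:
    """Numeric graph: per-node features, directed edge list (both directions),
    per-directed-edge features."""

    node_features: np.ndarray  # (num_nodes, node_dim)
    edge_index: np.ndarray  # (num_directed_edges, 2) int, [source, target]
    edge_features: np.ndarray  # (num_directed_edges, edge_dim)

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[0]


def to_graph(mol: Molecule, spec: FeatureSpec) -> FeaturizedGraph:
    """One node per heavy atom, two directed edges per bond; deterministic.

    Raises FeaturizationError naming the element if it is outside the spec's
    vocabulary.
    """
    rdmol = mol.rdmol
    n = rdmol.GetNumAtoms()
    elem_index = {e: i for i, e in enumerate(spec.elements)}
    X = np.zeros((n, spec.node_dim), dtype=np.float64)
    for i, atom in enumerate(rdmol.GetAtoms()):
        sym = atom.GetSymbol()
        if sym not in elem_index:
            raise FeaturizationError(f"element {sym!r} not in feature vocabulary")
        X[i, elem_index[sym]] = 1.0
        base = len(spec.elements)
        X[i, base] = atom.GetDegree()
        X[i, base + 1] = atom.GetFormalCharge()
        X[i, base + 2] = float(atom.GetIsAromatic())
        X[i, base + 3] = float(atom.IsInRing())
    edges = []
    efeat = []
    for bond in rdmol.GetBonds():
        ev = np.zeros(spec.edge_dim, dtype=np.float64)
        bt = bond.GetBondType()
        if bt in _BOND_ORDERS:
            ev[_BOND_ORDERS.index(bt)] = 1.0
        ev[4] = float(bond.IsInRing())
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((i, j))
        efeat.append(ev)
        edges.append((j, i))
        efeat.append(ev)
    edge_index = (
        np.array(edges, dtype=np.int64) if edges else np.zeros((0, 2), dtype=np.int64)
    )
    edge_features = (
        np.array(efeat, dtype=np.float64)
        if efeat
        else np.zeros((0, spec.edge_dim), dtype=np.float64)
    )
    return FeaturizedGraph(node_features=X, edge_index=edge_index, edge_features=edge_features)


# --------------------------------------------------------------------------
# Labeled datasets
# --------------------------------------------------------------------------


@dataclass
class LabeledRecord:
    """A molecule with a binary aggregation label (1 = aggregator)."""

    molecule: Molecule
    label: int
    source_id: str = ""


@dataclass
class DatasetReadResult:
    """Sequence of LabeledRecord plus the read report (skips, duplicates)."""

    records: list[LabeledRecord] = field(default_factory=list)
    n_skipped: int = 0
    n_duplicates: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def read_dataset(path: str | Path, format: str = "csv",
                 label_field: str = "label") -> DatasetReadResult:
    """Read a labeled molecule set from CSV (columns smiles,label[,id]) or SDF.

    Invalid rows are skipped with a logged warning and counted; duplicate
    canonical forms are counted in the report.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"dataset file not found: {path}")
    result = DatasetReadResult()
    seen: set[str] = set()

    def add(smiles_or_mol, label_raw, source_id):
        try:
            label = int(label_raw)
            if label not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {label_raw!r}")
            if isinstance(smiles_or_mol, Molecule):
                mol = smiles_or_mol
            else:
                mol = parse_smiles(str(smiles_or_mol))
        except (ValueError, TypeError) as exc:
            logger.warning("skipping record %s: %s", source_id, exc)
            result.n_skipped += 1
            return
        if mol.canonical_form in seen:
            result.n_duplicates += 1
        seen.add(mol.canonical_form)
        result.records.append(LabeledRecord(molecule=mol, label=label, source_id=source_id))

    if format == "csv":
        df = pd.read_csv(path)
        missing = {"smiles", "label"} - set(df.columns)
        if missing:
            raise IOError(f"CSV missing required columns: {sorted(missing)}")
        has_id = "id" in df.columns
        for i, row in df.iterrows():
            add(row["smiles"], row["label"], str(row["id"]) if has_id else str(i))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, rdmol in enumerate(supplier):
            if rdmol is None:
                logger.warning("skipping unreadable SDF record %d", i)
                result.n_skipped += 1
                continue
            if not rdmol.HasProp(label_field):
                logger.warning("skipping SDF record %d: no %r property", i, label_field)
                result.n_skipped += 1
                continue
            mol = Molecule(rdmol=rdmol, canonical_form=Chem.MolToSmiles(rdmol))
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else str(i)
            add(mol, rdmol.GetProp(label_field), name)
    else:
        raise ValueError(f"unknown dataset format: {format!r}")
    return result


def write_dataset(records, path: str | Path) -> None:
    """Write records as the standard CSV (smiles,label,id)."""
    df = pd.DataFrame(
        {
            "smiles": [r.molecule.canonical_form for r in records],
            "label": [r.label for r in records],
            "id": [r.source_id for r in records],
        }
    )
    df.to_csv(path, index=False)
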