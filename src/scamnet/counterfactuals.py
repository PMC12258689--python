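"""Counterfactual generation: single-graph-edit neighbors ranked by prediction deviation.

A counterfactual is a molecule one graph edit away from the query whose
prediction deviates maximally from the query's — ideally with a flipped
class label. The edit vocabulary spans atom substitution, atom
addition/deletion, bond-order change, and bond addition/deletion; every
candidate must survive RDKit sanitization (valence check + aromaticity
re-perception), and candidates are deduplicated by canonical SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chemio import FeaturizationError, Molecule, to_graph
from .model import ExplanationMask, ModelParameters, forward

__all__ = [
    "Edit",
    "CounterfactualResult",
    "EDIT_KINDS",
    "DEFAULT_VOCABULARY",
    "enumerate_single_edits",
    "rank_counterfactuals",
]

EDIT_KINDS: tuple[str, ...] = (
    "substitute_atom",
    "add_atom",
    "delete_atom",
    "change_bond_order",
    "add_bond",
    "delete_bond",
)

DEFAULT_VOCABULARY: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")

_ORDERS = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
_ORDER_NAMES = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2, Chem.BondType.TRIPLE: 3}
_PT = Chem.GetPeriodicTable()


@dataclass(frozen=True)
class Edit:
    """One graph edit; `sites` are atom indices of the source molecule."""

    kind: str
    sites: tuple[int, ...]
    value: str | int | None = None

    def describe(self) -> str:
        if self.kind == "substitute_atom":
            return f"substitute atom {self.sites[0]} with {self.value}"
        if self.kind == "add_atom":
            return f"add {self.value} bonded to atom {self.sites[0]}"
        if self.kind == "delete_atom":
            return f"delete terminal atom {self.sites[0]}"
        if self.kind == "change_bond_order":
            return f"set bond {self.sites[0]}-{self.sites[1]} order to {self.value}"
        if self.kind == "add_bond":
            return f"add single bond {self.sites[0]}-{self.sites[1]}"
        return f"delete bond {self.sites[0]}-{self.sites[1]}"


@dataclass
class CounterfactualResult:
    molecule: Molecule
    edit: Edit  # the last edit applied (the only one at depth 1)
    deviation: float  # |p_aggregator(edited) - p_aggregator(source)|
    flipped: bool
    probabilities: np.ndarray
    mask: ExplanationMask
    edits: tuple[Edit, ...] = ()  # full edit path from the source molecule


def _finalize(rw: Chem.RWMol) -> Molecule | None:
    """Sanitize (valence + aromaticity re-perception); None if invalid."""
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
        smiles = Chem.MolToSmiles(out)
        if not smiles:
            return None
        # round-trip so atom order matches the canonical form
        reparsed = Chem.MolFromSmiles(smiles)
        if reparsed is None:
            return None
        return Molecule(rdmol=reparsed, canonical_form=Chem.MolToSmiles(reparsed))
    except Exception:
        return None


def _kekulized(rdmol: Chem.Mol) -> Chem.Mol:
    copy = Chem.Mol(rdmol)
    Chem.Kekulize(copy, clearAromaticFlags=True)
    return copy


def enumerate_single_edits(
    mol: Molecule,
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
    kinds: tuple[str, ...] = EDIT_KINDS,
) -> list[tuple[Molecule, Edit]]:
    """All valence-valid unique single-edit neighbors of `mol`.

    Enumeration order is deterministic: edit kind (as listed in EDIT_KINDS),
    then site index, then vocabulary/order position. Duplicates (by canonical
    form) keep the first-generated edit; the source molecule is excluded.
    Deletions that would disconnect the molecule are not emitted.
    """
    if not vocabulary:
        raise ValueError("element vocabulary must be non-empty")
    base = _kekulized(mol.rdmol)
    n = base.GetNumAtoms()
    source_canonical = mol.canonical_form
    seen: set[str] = {source_canonical}
    results: list[tuple[Molecule, Edit]] = []

    def try_add(rw: Chem.RWMol, edit: Edit):
        cand = _finalize(rw)
        if cand is None or cand.num_atoms == 0 or cand.canonical_form in seen:
            return
        seen.add(cand.canonical_form)
        results.append((cand, edit))

    for kind in EDIT_KINDS:
        if kind not in kinds:
            continue
        if kind == "substitute_atom":
            for i in range(n):
                for elem in vocabulary:
                    if base.GetAtomWithIdx(i).GetSymbol() == elem:
                        continue
                    rw = Chem.RWMol(base)
                    atom = rw.GetAtomWithIdx(i)
                    atom.SetAtomicNum(_PT.GetAtomicNumber(elem))
                    atom.SetFormalCharge(0)
                    atom.SetNumExplicitHs(0)
                    atom.SetNoImplicit(False)
                    try_add(rw, Edit("substitute_atom", (i,), elem))
        elif kind == "add_atom":
            for i in range(n):
                for elem in vocabulary:
                    rw = Chem.RWMol(base)
                    j = rw.AddAtom(Chem.Atom(_PT.GetAtomicNumber(elem)))
                    rw.AddBond(i, j, Chem.BondType.SINGLE)
                    try_add(rw, Edit("add_atom", (i,), elem))
        elif kind == "delete_atom":
            for i in range(n):
                if base.GetAtomWithIdx(i).GetDegree() != 1 or n <= 1:
                    continue
                rw = Chem.RWMol(base)
                rw.RemoveAtom(i)
                try_add(rw, Edit("delete_atom", (i,)))
        elif kind == "change_bond_order":
            for bond in base.GetBonds():
                i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
                for order in _ORDERS:
                    if bond.GetBondType() == order:
                        continue
                    rw = Chem.RWMol(base)
                    rw.GetBondBetweenAtoms(i, j).SetBondType(order)
                    try_add(rw, Edit("change_bond_order", (i, j), _ORDER_NAMES[order]))
        elif kind == "add_bond":
            for i in range(n):
                for j in range(i + 1, n):
                    if base.GetBondBetweenAtoms(i, j) is not None:
                        continue
                    rw = Chem.RWMol(base)
                    rw.AddBond(i, j, Chem.BondType.SINGLE)
                    try_add(rw, Edit("add_bond", (i, j)))
        elif kind == "delete_bond":
            for bond in base.GetBonds():
                i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
                rw = Chem.RWMol(base)
                rw.RemoveBond(i, j)
                if len(Chem.GetMolFrags(rw.GetMol())) > 1:
                    continue  # disconnection is not a single-molecule edit
                try_add(rw, Edit("delete_bond", (i, j)))
    return results


def rank_counterfactuals(
    params: ModelParameters,
    mol: Molecule,
    k: int,
    flipped_only: bool = False,
    vocabulary: tuple[str, ...] | None = None,
    kinds: tuple[str, ...] = EDIT_KINDS,
    depth: int = 1,
    expansion_budget: int = 25,
) -> list[CounterfactualResult]:
    """Top-k edited neighbors by |change in aggregator probability|.

    Sorted by deviation descending, ties broken by canonical form ascending.
    Depth 1 (the default, matching "minimal structural change") scores every
    single-edit neighbor. depth > 1 continues by best-first expansion: at
    each extra level the `expansion_budget` highest-deviation candidates of
    the previous level are themselves edited. Deviation and flipped status
    are always measured against the original source molecule. Neighbors with
    elements outside the model's feature vocabulary are skipped (they cannot
    be scored).
    """
    if k < 1:
        raise ValueError("k must be positive")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    vocab = vocabulary if vocabulary is not None else tuple(params.spec.elements)
    source_pred = forward(params, to_graph(mol, params.spec))
    p_source = source_pred.probabilities[1]
    cls_source = source_pred.predicted_class

    def score(cand: Molecule, edits: tuple[Edit, ...]) -> CounterfactualResult | None:
        try:
            graph = to_graph(cand, params.spec)
        except FeaturizationError:
            return None
        pred = forward(params, graph)
        return CounterfactualResult(
            molecule=cand,
            edit=edits[-1],
            deviation=float(abs(pred.probabilities[1] - p_source)),
            flipped=pred.predicted_class != cls_source,
            probabilities=pred.probabilities,
            mask=pred.mask,
            edits=edits,
        )

    results: dict[str, CounterfactualResult] = {}
    for cand, edit in enumerate_single_edits(mol, vocabulary=vocab, kinds=kinds):
        r = score(cand, (edit,))
        if r is not None:
            results[cand.canonical_form] = r

    for level in range(2, depth + 1):
        frontier = sorted(
            (r for r in results.values() if len(r.edits) == level - 1),
            key=lambda r: (-r.deviation, r.molecule.canonical_form),
        )[:expansion_budget]
        for parent in frontier:
            for cand, edit in enumerate_single_edits(
                parent.molecule, vocabulary=vocab, kinds=kinds
            ):
                if cand.canonical_form in results or cand.canonical_form == mol.canonical_form:
                    continue
                r = score(cand, parent.edits + (edit,))
                if r is not None:
                    results[cand.canonical_form] = r

    scored = sorted(results.values(), key=lambda r: (-r.deviation, r.molecule.canonical_form))
    if flipped_only:
        scored = [r for r in scored if r.flipped]
    return scored[:k]
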