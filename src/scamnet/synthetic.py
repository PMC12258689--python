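"""Synthetic labeled molecule sets with a planted, position-sensitive motif.

The positive ("aggregator") class is determined entirely by a substructure
rule — by default a 2-hydroxypyridine-type HO-C-N motif: a hydroxyl on the
aromatic carbon adjacent to a ring nitrogen. Hydroxyl groups at other ring
positions are planted as decoys in the negative class, so a model cannot
reach perfect accuracy by merely counting hydroxyls: it must resolve the
substitution position. Truth masks (the motif atoms, in canonical atom
order) provide ground truth for testing explanation quality.

Chemistry here is deliberately simple — small decorated (aza)arenes — and
emulates only the label structure and class imbalance of a real aggregation
screen, not its chemical space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chemio import LabeledRecord, Molecule, parse_smiles, write_dataset

__all__ = [
    "MotifRule",
    "SyntheticDataset",
    "DEFAULT_RULES",
    "TWO_MOTIF_RULES",
    "generate_dataset",
    "motif_atoms",
    "write_synthetic",
    "load_synthetic",
]


@dataclass(frozen=True)
class MotifRule:
    """A substructure pattern that decides the label when present.

    ``plant_fragment`` is the substituent (SMILES, attachment at atom 0)
    the generator grafts onto a ring carbon adjacent to an aromatic
    nitrogen to create the motif by construction.
    """

    name: str
    smarts: str
    label_effect: int  # 1 = aggregator, 0 = non-aggregator
    plant_fragment: str = "O"

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in rule {self.name!r}: {self.smarts!r}")
        return patt


# Hydroxyl on the ring carbon adjacent to a ring nitrogen (HO-C-N).
DEFAULT_RULES: tuple[MotifRule, ...] = (
    MotifRule("hydroxyl-adjacent-to-ring-N", "[OX2H1]-[c]:[n]", 1, plant_fragment="O"),
)

# A second independent positive motif (amino instead of hydroxyl) for
# concept-separation experiments.
TWO_MOTIF_RULES: tuple[MotifRule, ...] = (
    MotifRule("hydroxyl-adjacent-to-ring-N", "[OX2H1]-[c]:[n]", 1, plant_fragment="O"),
    MotifRule("amino-adjacent-to-ring-N", "[NX3H2]-[c]:[n]", 1, plant_fragment="N"),
)

SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",  # benzene
    "c1ccncc1",  # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "c1ccc2ncccc2c1",  # quinoline
)

SUBSTITUENTS: tuple[str, ...] = ("O", "N", "C", "Cl", "F", "OC", "C(=O)OC")


@dataclass
class SyntheticDataset:
    """Records plus per-record truth masks (canonical-order atom indices)."""

    records: list[LabeledRecord]
    truth_masks: list[frozenset[int]]
    seed: int
    rules: tuple[MotifRule, ...]
    deciding_rules: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def motif_atoms(mol: Molecule, rule: MotifRule) -> frozenset[int]:
    """Atom indices of all matches of the rule's pattern; empty if no match."""
    matches = mol.rdmol.GetSubstructMatches(rule.pattern())
    return frozenset(i for match in matches for i in match)


def _apply_rules(mol: Molecule, rules) -> tuple[int, MotifRule | None]:
    """First matching rule in list order decides the label; default label 0."""
    for rule in rules:
        if mol.rdmol.HasSubstructMatch(rule.pattern()):
            return rule.label_effect, rule
    return 0, None


def _free_ring_carbons(rdmol: Chem.Mol, adjacent_to_n: bool | None = None) -> list[int]:
    """Aromatic CH carbons, optionally filtered by adjacency to aromatic N."""
    out = []
    for atom in rdmol.GetAtoms():
        if not (atom.GetIsAromatic() and atom.GetSymbol() == "C" and atom.GetTotalNumHs() >= 1):
            continue
        near_n = any(
            nb.GetIsAromatic() and nb.GetSymbol() == "N" for nb in atom.GetNeighbors()
        )
        if adjacent_to_n is None or near_n == adjacent_to_n:
            out.append(atom.GetIdx())
    return out


def _attach(rdmol: Chem.Mol, site: int, frag_smiles: str) -> Chem.Mol:
    """Graft a substituent (attachment at fragment atom 0) onto `site`."""
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(rdmol, frag))
    combo.AddBond(site, rdmol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _decorate(rdmol: Chem.Mol, rng: np.random.Generator, k: int) -> Chem.Mol:
    for _ in range(k):
        sites = _free_ring_carbons(rdmol)
        if not sites:
            break
        site = sites[rng.integers(len(sites))]
        frag = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        rdmol = _attach(rdmol, site, frag)
    return rdmol


def _random_molecule(rng: np.random.Generator) -> Molecule:
    scaffold = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
    rdmol = Chem.MolFromSmiles(scaffold)
    rdmol = _decorate(rdmol, rng, int(rng.integers(0, 4)))
    return parse_smiles(Chem.MolToSmiles(rdmol))


def _planted_positive(rng: np.random.Generator, rule: MotifRule) -> Molecule:
    """Nitrogen scaffold with the rule's fragment at a position adjacent to N."""
    scaffold = ("c1ccncc1", "c1ccc2ncccc2c1")[rng.integers(2)]
    rdmol = Chem.MolFromSmiles(scaffold)
    sites = _free_ring_carbons(rdmol, adjacent_to_n=True)
    rdmol = _attach(rdmol, sites[rng.integers(len(sites))], rule.plant_fragment)
    rdmol = _decorate(rdmol, rng, int(rng.integers(0, 3)))
    return parse_smiles(Chem.MolToSmiles(rdmol))


def _planted_decoy(rng: np.random.Generator) -> Molecule:
    """Hydroxyl at a ring position NOT adjacent to a ring nitrogen."""
    scaffold = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
    rdmol = Chem.MolFromSmiles(scaffold)
    sites = _free_ring_carbons(rdmol, adjacent_to_n=False)
    rdmol = _attach(rdmol, sites[rng.integers(len(sites))], "O")
    rdmol = _decorate(rdmol, rng, int(rng.integers(0, 3)))
    return parse_smiles(Chem.MolToSmiles(rdmol))


DECOY_FRACTION = 0.3  # of negatives carry a non-adjacent hydroxyl by construction


def generate_dataset(
    n: int,
    aggregator_fraction: float,
    seed: int,
    rules: tuple[MotifRule, ...] = DEFAULT_RULES,
) -> SyntheticDataset:
    """Seeded dataset with exactly round(n * fraction) aggregators.

    Labels are consistent with the rules by construction (re-deriving the
    label from the rule set reproduces the stored label for every record).
    Identical arguments give identical output.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 < aggregator_fraction < 1.0):
        raise ValueError("aggregator_fraction must be in (0, 1)")
    if not rules:
        raise ValueError("rules must be non-empty")
    agg_rules = [r for r in rules if r.label_effect == 1]
    if not agg_rules:
        raise ValueError("need at least one aggregator rule")

    rng = np.random.default_rng(seed)
    n_pos = int(round(n * aggregator_fraction))
    n_neg = n - n_pos
    n_decoy = int(np.ceil(DECOY_FRACTION * n_neg))

    mols: list[Molecule] = []
    labels: list[int] = []
    masks: list[frozenset[int]] = []
    deciding: list[str] = []

    def emit(mol: Molecule, want_label: int) -> bool:
        label, rule = _apply_rules(mol, rules)
        if label != want_label:
            return False
        mols.append(mol)
        labels.append(label)
        masks.append(motif_atoms(mol, rule) if rule is not None else frozenset())
        deciding.append(rule.name if rule is not None else "")
        return True

    for _ in range(n_pos):
        while True:
            rule = agg_rules[rng.integers(len(agg_rules))]
            if emit(_planted_positive(rng, rule), 1):
                break
    made_decoys = 0
    while made_decoys < n_decoy:
        if emit(_planted_decoy(rng), 0):
            made_decoys += 1
    for _ in range(n_neg - n_decoy):
        while True:
            if emit(_random_molecule(rng), 0):
                break

    order = rng.permutation(len(mols))
    records = [
        LabeledRecord(molecule=mols[i], label=labels[i], source_id=f"syn-{j:05d}")
        for j, i in enumerate(order)
    ]
    return SyntheticDataset(
        records=records,
        truth_masks=[masks[i] for i in order],
        seed=seed,
        rules=tuple(rules),
        deciding_rules=[deciding[i] for i in order],
    )


def write_synthetic(dataset: SyntheticDataset, csv_path: str | Path,
                    json_path: str | Path | None = None) -> None:
    """Standard CSV (smiles,label,id) plus a JSON sidecar with seed, rules,
    and truth masks in canonical-form atom order."""
    csv_path = Path(csv_path)
    write_dataset(dataset.records, csv_path)
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    sidecar = {
        "seed": dataset.seed,
        "rules": [
            {"name": r.name, "smarts": r.smarts, "label_effect": r.label_effect}
            for r in dataset.rules
        ],
        "truth_masks": {
            rec.source_id: sorted(mask)
            for rec, mask in zip(dataset.records, dataset.truth_masks)
        },
        "deciding_rules": {
            rec.source_id: name
            for rec, name in zip(dataset.records, dataset.deciding_rules)
        },
    }
    Path(json_path).write_text(json.dumps(sidecar, sort_keys=True, indent=1))


def load_synthetic(csv_path: str | Path, json_path: str | Path | None = None) -> SyntheticDataset:
    """Rebuild a SyntheticDataset from the CSV + JSON sidecar pair."""
    from .chemio import read_dataset

    csv_path = Path(csv_path)
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    sidecar = json.loads(Path(json_path).read_text())
    result = read_dataset(csv_path, format="csv")
    rules = tuple(
        MotifRule(r["name"], r["smarts"], r["label_effect"]) for r in sidecar["rules"]
    )
    masks = [
        frozenset(sidecar["truth_masks"].get(rec.source_id, [])) for rec in result.records
    ]
    deciding = [sidecar.get("deciding_rules", {}).get(rec.source_id, "") for rec in result.records]
    return SyntheticDataset(
        records=result.records,
        truth_masks=masks,
        seed=int(sidecar["seed"]),
        rules=rules,
        deciding_rules=deciding,
    )
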