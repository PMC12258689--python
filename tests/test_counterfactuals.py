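"""Single-edit enumeration and deviation-ranked counterfactual search."""

import numpy as np
import pytest
from rdkit import Chem

from scamnet import (
    canonical_form,
    enumerate_single_edits,
    generate_dataset,
    init_params,
    parse_smiles,
    rank_counterfactuals,
    to_graph,
)
from scamnet.counterfactuals import EDIT_KINDS
from scamnet.model import forward


def test_methane_neighbors_exact():
    neighbors = enumerate_single_edits(parse_smiles("C"), vocabulary=("C", "N", "O"))
    forms = sorted(n.canonical_form for n, _ in neighbors)
    assert forms == ["CC", "CN", "CO", "N", "O"]


def test_benzene_single_nitrogen_substitution_dedups_to_pyridine():
    neighbors = enumerate_single_edits(
        parse_smiles("c1ccccc1"), vocabulary=("N",), kinds=("substitute_atom",)
    )
    assert len(neighbors) == 1
    assert neighbors[0][0].canonical_form == canonical_form(parse_smiles("c1ccncc1"))


def test_clioquinol_neighbors_contain_methylclioquinol():
    clioquinol = parse_smiles("Oc1c(I)cc(Cl)c2cccnc12")
    methylclioquinol = canonical_form(parse_smiles("COc1c(I)cc(Cl)c2cccnc12"))
    forms = {n.canonical_form for n, _ in enumerate_single_edits(clioquinol)}
    assert methylclioquinol in forms


def test_neighbors_are_unique_and_exclude_source():
    mol = parse_smiles("Oc1ccccn1")
    neighbors = enumerate_single_edits(mol)
    forms = [n.canonical_form for n, _ in neighbors]
    assert len(forms) == len(set(forms))
    assert mol.canonical_form not in forms


def test_enumeration_deterministic():
    mol = parse_smiles("CC(=O)Oc1ccccc1")
    a = [(n.canonical_form, e.kind, e.sites) for n, e in enumerate_single_edits(mol)]
    b = [(n.canonical_form, e.kind, e.sites) for n, e in enumerate_single_edits(mol)]
    assert a == b


def test_all_neighbors_are_valid_molecules():
    for smi in ("Oc1ccccn1", "CC(=O)O", "C1CC1"):
        for n, _ in enumerate_single_edits(parse_smiles(smi)):
            assert Chem.MolFromSmiles(n.canonical_form) is not None


@pytest.mark.parametrize("smi", ["CCO", "Oc1ccccn1"])
def test_edit_distance_one_count_deltas(smi):
    """Atom/bond count deltas must be consistent with the claimed single edit."""
    mol = parse_smiles(smi)
    na, nb = mol.num_atoms, mol.num_bonds
    for cand, edit in enumerate_single_edits(mol):
        da, db = cand.num_atoms - na, cand.num_bonds - nb
        if edit.kind == "substitute_atom":
            assert (da, db) == (0, 0)
        elif edit.kind == "add_atom":
            assert (da, db) == (1, 1)
        elif edit.kind == "delete_atom":
            assert (da, db) == (-1, -1)
        elif edit.kind == "change_bond_order":
            assert (da, db) == (0, 0)
        elif edit.kind == "add_bond":
            assert (da, db) == (0, 1)
        elif edit.kind == "delete_bond":
            assert (da, db) == (0, -1)


def test_empty_vocabulary_rejected():
    with pytest.raises(ValueError):
        enumerate_single_edits(parse_smiles("C"), vocabulary=())


# --------------------------------------------------------------------------
# Ranking
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def rank_params(small_config, spec):
    return init_params(small_config, spec, seed=3)


def test_constant_model_ties_break_by_canonical_form(small_config, spec):
    params = init_params(small_config, spec, seed=0)
    for t in params.weights.values():
        t.data[:] = 0.0  # equal logits for every input
    results = rank_counterfactuals(params, parse_smiles("CCO"), k=10)
    assert all(r.deviation == 0.0 for r in results)
    forms = [r.molecule.canonical_form for r in results]
    assert forms == sorted(forms)
    assert not any(r.flipped for r in results)


def test_k_truncation_and_flipped_consistency(rank_params):
    mol = parse_smiles("Oc1ccccn1")
    all_results = rank_counterfactuals(rank_params, mol, k=10_000)
    top3 = rank_counterfactuals(rank_params, mol, k=3)
    assert len(top3) == 3
    assert [r.molecule.canonical_form for r in top3] == [
        r.molecule.canonical_form for r in all_results[:3]
    ]
    devs = [r.deviation for r in all_results]
    assert devs == sorted(devs, reverse=True)
    flipped = rank_counterfactuals(rank_params, mol, k=10_000, flipped_only=True)
    assert all(r.flipped for r in flipped)
    assert {r.molecule.canonical_form for r in flipped} <= {
        r.molecule.canonical_form for r in all_results if r.flipped
    }


def brute_force_rank(params, mol, spec):
    """Independent enumerate-score-sort: raw RDKit loops, no shared ranking code."""
    base = Chem.Mol(mol.rdmol)
    Chem.Kekulize(base, clearAromaticFlags=True)
    pt = Chem.GetPeriodicTable()
    n = base.GetNumAtoms()
    candidates = {}

    def consider(rw):
        try:
            m = rw.GetMol()
            Chem.SanitizeMol(m)
            smi = Chem.MolToSmiles(m)
        except Exception:
            return
        # round-trip to the canonical form of the reparsed molecule, the
        # interchange convention used everywhere in the package
        reparsed = Chem.MolFromSmiles(smi) if smi else None
        if reparsed is None:
            return
        smi = Chem.MolToSmiles(reparsed)
        if smi and smi != mol.canonical_form and reparsed.GetNumAtoms() > 0:
            candidates.setdefault(smi, reparsed)

    vocab = spec.elements
    for i in range(n):
        for elem in vocab:
            if base.GetAtomWithIdx(i).GetSymbol() != elem:
                rw = Chem.RWMol(base)
                a = rw.GetAtomWithIdx(i)
                a.SetAtomicNum(pt.GetAtomicNumber(elem))
                a.SetFormalCharge(0)
                a.SetNumExplicitHs(0)
                a.SetNoImplicit(False)
                consider(rw)
            rw = Chem.RWMol(base)
            j = rw.AddAtom(Chem.Atom(pt.GetAtomicNumber(elem)))
            rw.AddBond(i, j, Chem.BondType.SINGLE)
            consider(rw)
        if base.GetAtomWithIdx(i).GetDegree() == 1 and n > 1:
            rw = Chem.RWMol(base)
            rw.RemoveAtom(i)
            consider(rw)
    for bond in base.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for order in (Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            if bond.GetBondType() != order:
                rw = Chem.RWMol(base)
                rw.GetBondBetweenAtoms(i, j).SetBondType(order)
                consider(rw)
        rw = Chem.RWMol(base)
        rw.RemoveBond(i, j)
        if len(Chem.GetMolFrags(rw.GetMol())) == 1:
            consider(rw)
    for i in range(n):
        for j in range(i + 1, n):
            if base.GetBondBetweenAtoms(i, j) is None:
                rw = Chem.RWMol(base)
                rw.AddBond(i, j, Chem.BondType.SINGLE)
                consider(rw)

    p_src = forward(params, to_graph(mol, spec)).probabilities[1]
    scored = []
    for smi in candidates:
        reparsed = parse_smiles(smi)
        p = forward(params, to_graph(reparsed, spec)).probabilities[1]
        scored.append((abs(p - p_src), smi))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [smi for _, smi in scored]


def test_ranking_matches_brute_force_oracle(rank_params, spec):
    ds = generate_dataset(60, 0.5, seed=77)
    mols = [r.molecule for r in ds.records if r.molecule.num_atoms <= 12][:10]
    assert len(mols) == 10
    for mol in mols:
        ours = [
            r.molecule.canonical_form
            for r in rank_counterfactuals(rank_params, mol, k=10_000)
        ]
        oracle = brute_force_rank(rank_params, mol, spec)
        assert ours == oracle


def test_multi_edit_search_extends_depth_one(rank_params):
    mol = parse_smiles("CCO")
    shallow = rank_counterfactuals(rank_params, mol, k=10_000)
    deep = rank_counterfactuals(rank_params, mol, k=10_000, depth=2, expansion_budget=5)
    assert all(len(r.edits) == 1 for r in shallow)
    assert {len(r.edits) for r in deep} == {1, 2}
    # depth-1 candidates are all retained, and deviations stay sorted
    assert {r.molecule.canonical_form for r in shallow} <= {
        r.molecule.canonical_form for r in deep
    }
    devs = [r.deviation for r in deep]
    assert devs == sorted(devs, reverse=True)
    # deterministic
    again = rank_counterfactuals(rank_params, mol, k=10_000, depth=2, expansion_budget=5)
    assert [r.molecule.canonical_form for r in again] == [
        r.molecule.canonical_form for r in deep
    ]


def test_edit_kind_filter_subset():
    mol = parse_smiles("CCO")
    subs_only = enumerate_single_edits(mol, kinds=("substitute_atom",))
    assert {e.kind for _, e in subs_only} == {"substitute_atom"}
    everything = enumerate_single_edits(mol, kinds=EDIT_KINDS)
    assert {n.canonical_form for n, _ in subs_only} <= {
        n.canonical_form for n, _ in everything
    }
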