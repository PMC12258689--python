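"""Generate a planted-motif dataset and inspect its label structure.

The positive class is defined by a hydroxyl on the ring carbon adjacent to a
ring nitrogen (HO-C-N); hydroxyls elsewhere are decoys in the negative class.
"""

from scamnet import DEFAULT_RULES, generate_dataset, motif_atoms, write_synthetic

ds = generate_dataset(n=200, aggregator_fraction=0.5, seed=7)
n_pos = sum(r.label for r in ds.records)
print(f"{len(ds.records)} molecules, {n_pos} aggregators")

example = next(r for r in ds.records if r.label == 1)
mask = next(m for r, m in zip(ds.records, ds.truth_masks) if r is example)
print(f"example aggregator: {example.molecule.canonical_form}")
print(f"  motif atoms (explanation ground truth): {sorted(mask)}")

decoy = next(
    r
    for r in ds.records
    if r.label == 0 and "O" in r.molecule.canonical_form
    and not motif_atoms(r.molecule, DEFAULT_RULES[0])
)
print(f"example decoy (hydroxyl, wrong position, label 0): {decoy.molecule.canonical_form}")

write_synthetic(ds, "scratch_dataset.csv")
print("wrote scratch_dataset.csv + scratch_dataset.json (truth masks, rules, seed)")
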