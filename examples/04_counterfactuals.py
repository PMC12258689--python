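"""Find minimal structural edits that flip the model's aggregation call.

Requires the checkpoint from 02_train_and_evaluate.py.
"""

from scamnet import load_checkpoint, parse_smiles, rank_counterfactuals

params = load_checkpoint("scratch_model.npz")
query = parse_smiles("Oc1ccccn1")  # 2-hydroxypyridine, a planted aggregator

results = rank_counterfactuals(params, query, k=5, flipped_only=True)
print(f"query: {query.canonical_form}")
print(f"top {len(results)} label-flipping single edits "
      "(sorted by deviation in aggregator probability):")
for r in results:
    print(f"  dev={r.deviation:.3f}  p_agg={r.probabilities[1]:.3f}  "
          f"{r.molecule.canonical_form:<24} {r.edit.describe()}")
print("each candidate is exactly one valence-valid graph edit from the query")
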