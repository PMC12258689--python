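# scamnet

Self-explaining screening for **small colloidally aggregating molecules
(SCAMs)** — compounds that self-assemble into colloids in aqueous buffer and
poison high-throughput assays with false positives. `scamnet` provides:

- a **two-channel graph attention classifier** over heavy-atom molecular
  graphs that predicts *aggregator* vs *non-aggregator* and, in the same
  forward pass, emits one **explanation mask** per class: importance values
  in [0, 1] for every atom and bond, derived from the internal attention
  values. Channel 1 collects structural evidence *for* aggregation, channel 0
  evidence *against* it;
- **counterfactual generation**: enumeration of all valence-valid
  single-graph-edit neighbors of a query molecule, ranked by the deviation
  they cause in the predicted aggregation probability, optionally restricted
  to label-flipping edits;
- **global concept extraction**: high-importance subgraphs are pooled into
  embeddings, reduced to 8 dimensions, and density-clustered per channel into
  recurring structural concepts with consensus substructures;
- a **planted-motif synthetic data generator** so that training, explanation
  quality, counterfactual search, and concept extraction are all testable
  offline with known ground truth.

## Model

Molecules are heavy-atom graphs with one-hot element, degree, charge,
aromaticity, and ring-membership node features. The classifier runs one
message-passing stream per output class *k*. Per layer ℓ and channel *k*,
each directed edge (i→j) gets an attention logit

    a_ij = w_a · [h_i ; h_j ; e_ij] + b_a

and node j aggregates softmax-weighted messages over its in-edges:

    h_j ← ReLU(W_self h_j + Σ_i softmax_i(a_ij) · W_msg h_i + b)

Node importance for channel *k* is
`sigmoid(Σ_ℓ incident attention logits) × sigmoid(gate(h_j))`; edge
importance is the sigmoid of the summed logits. The graph embedding of
channel *k* is the importance-weighted sum of its node embeddings — the mask
is the **only** path from structure to class evidence — and the concatenated
per-channel embeddings feed a small dense network ending in a softmax.

Training minimizes

    L = CE(p, y) + β · CE(softmax(Σ_atoms mask_k), y) + γ · mean(mask)

i.e. cross-entropy, an explanation co-training term that ties channel *k* to
class *k* through mask magnitudes alone, and an L1 sparsity term. Class
imbalance is handled by oversampling the minority class to parity each epoch.

## Worked example

```sh
scamnet generate --n 1000 --fraction 0.5 --seed 42 --out data.csv
scamnet train --data data.csv --epochs 15 --seed 42 --out model.npz
scamnet predict --smiles "Oc1ccccn1" --model model.npz --out pred.json
scamnet counterfactual --smiles "Oc1ccccn1" --model model.npz --k 3 --flipped-only
```

Running the equivalent library calls (`examples/02_train_and_evaluate.py`)
prints:

```
epoch  0  loss 1.631  val accuracy 0.500
epoch  5  loss 1.013  val accuracy 1.000
epoch 10  loss 0.728  val accuracy 1.000

test accuracy 1.000, F1 1.000 (tp=100 fn=0 tn=100 fp=0)
localization AUC 0.880: how well aggregator-channel importances rank the
planted motif atoms above the rest (1.0 = perfect)
```

The synthetic positive class is defined by a 2-hydroxypyridine-type HO–C–N
motif (hydroxyl on the ring carbon adjacent to a ring nitrogen); hydroxyls at
other ring positions are decoys in the negative class. A localization AUC
near 1 means the aggregator channel's atom importances concentrate on the
motif that actually determines the label. `examples/03–05` show per-atom
explanations for a motif molecule vs its positional decoy, label-flipping
single edits, and concept clusters that separate two planted motifs.

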