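# Methods

## Problem setting

Colloidal aggregators are small molecules that self-assemble into colloidal
particles in aqueous buffer and non-specifically inhibit assay targets,
producing false-positive hits. `scamnet` frames SCAM detection as binary
graph classification with built-in attributional explanations: the model must
not only predict *aggregator* / *non-aggregator* but also say *which atoms
and bonds* carry the evidence, separately for each class, and support
"what-if" queries (counterfactual edits) and corpus-level summaries (concept
clusters).

## Chemical standardization

Molecules enter as SMILES and are parsed with RDKit; graphs are heavy-atom
only (hydrogens implicit), matching how atom-level masks are displayed and
halving graph size. Protonation states at a given pH (default 7.4,
physiological) are set by a fixed, ordered rule table of
(SMARTS pattern, pKa, action):

| group | pattern | pKa | action at pH 7.4 |
|---|---|---|---|
| carboxylic acid | `[CX3](=O)[OX2H1]` | 4.8 | deprotonate (−1) |
| phosphate/phosphonate O–H | `[OX2H1][PX4](=O)` | 2.0 | deprotonate (−1) |
| tetrazole N–H | `[nH]1nnnc1` | 4.9 | deprotonate (−1) |
| guanidine | `[NX3][CX3](=[NX2])[NX3]` | 13.6 | protonate (+1) |
| aliphatic amine | `[NX3;+0;!$(N-C=O);!$(N-a);…]` | 10.6 | protonate (+1) |

An acid rule fires when pH > pKa, a base rule when pH < pKa; the first
matching rule per site wins, and molecules matching no rule pass through
unchanged. The table is a deterministic, documented device, not a pKa
predictor: it covers the common ionizable groups, is exactly idempotent
(charged forms no longer match the neutral patterns), and is trivially
auditable. Tautomer enumeration and salt handling beyond the input fragment
are out of scope.

## Model

One message-passing stream per output class ("channel"; K = 2). All streams
share a linear input embedding of the node features
(one-hot element over {C,N,O,S,F,Cl,Br,I,P}, degree, formal charge, aromatic
flag, ring flag; edges: one-hot bond order + ring flag). Per layer ℓ and
channel k, a single-layer perceptron over (source embedding, target
embedding, edge features) produces an edge attention logit; incoming messages
are combined with a softmax over each node's in-edges; the node update is
`ReLU(W_self h + message + b)`. Defaults: 3 layers, hidden width 64, readout
widths (64, 32, 2).

Explanation masks are functions of the internal attention values:

- node importance (channel k) = `sigmoid(Σ_layers incident edge logits) ×
  sigmoid(w_g·h + b_g)` — a learned gate sharpens or vetoes the attention
  signal; the product of two sigmoids guarantees the [0, 1] range;
- edge importance = `sigmoid(Σ_layers edge logit)`.

The channel-k graph embedding is the importance-weighted sum of channel-k
node embeddings. The readout sees only the concatenated per-channel pooled
embeddings, so each channel influences the logits exclusively through its
mask — masking is structural, not post hoc.

## Loss and training

`L = CE(p, y) + β·CE(softmax(s), y) + γ·mean(importances)` where
`s_k = Σ_atoms node_importance_k`. The co-training term forces the mask
*magnitudes alone* to identify the class, aligning channel k with class k;
the sparsity term (mean of all node and edge importances, an L1 penalty since
they are nonnegative) pushes irrelevant atoms toward zero. Defaults β = 1.0,
γ = 0.01: β of order one makes channel/class alignment a first-class
objective; γ is kept two orders smaller so sparsity shapes rather than
dominates the masks.

Optimization is Adam with a fixed step of 1e-3 and batch size 32 — a
first-order, fixed-step scheme chosen for reproducibility over tuning.
Batches are disjoint unions of molecular graphs. Class imbalance is handled
by oversampling the minority class to parity within each epoch (every
minority record appears ⌊maj/min⌋ times plus a seeded random remainder),
a mechanism that is directly testable by counting sampled labels. All
randomness (init, shuffling, oversampling) flows from one integer seed;
training is bit-reproducible on the same data.

Gradients come from a compact reverse-mode autodiff core over float64 NumPy
arrays (`autodiff.py`) providing exactly the required operations — dense
algebra, pointwise nonlinearities, row gather, segment sums, and
per-segment softmax. Its gradients are verified against central finite
differences in the test suite.

## Synthetic planted-motif data

The generator emulates the *label structure* of an aggregation screen, not
its chemistry. Scaffolds (benzene, pyridine, naphthalene, quinoline) are
decorated with 0–3 substituents from {OH, NH₂, CH₃, Cl, F, OCH₃, CO₂CH₃} at
seeded random ring positions; molecules stay ≤ ~15 heavy atoms so a full
train/test cycle runs in minutes on one CPU. The positive class is defined
by a substructure rule — default: hydroxyl on the ring carbon adjacent to a
ring nitrogen (`[OX2H1]-[c]:[n]`, the HO–C–N hydrogen-bonding motif). Labels
are *re-derived from the rules* for every emitted record, so they are
correct by construction; the first matching rule in list order decides when
rules overlap, and its match atoms (in canonical SMILES atom order) are the
record's truth mask. At least 30% of negatives carry a hydroxyl at a
non-adjacent ring position, so position-blind shortcuts (e.g. counting
hydroxyls) cannot reach perfect accuracy. Exact class counts
(`round(n × fraction)`) and byte-identical reruns are guaranteed for fixed
(n, fraction, seed, rules). A two-motif rule set (hydroxyl + amino variants)
supports concept-separation experiments.

What passing tests on this generator do **not** show: performance on real
screening data, whose labels come from noisy assays, whose chemistry is far
more diverse, and where no single substructure determines the outcome. The
generator validates the *machinery* — learnability, explanation
localization, counterfactual ranking, concept recovery — under a known
ground truth.

## Evaluation

Accuracy, balanced accuracy (mean of per-class recalls), and F1 are computed
from argmax predictions (threshold 0.5 on binary probabilities, no
calibration). `metrics_from_confusion` exposes the same formulas for printed
confusion counts; on an external validation table of 30 aggregators and 28
non-aggregators with 15 and 24 correct respectively, plain accuracy is
39/58 ≈ 67.2% while balanced accuracy ≈ 67.9% rounds to 68% — a quoted "68%"
on such a table is most consistent with balanced accuracy, and both are
reported since sources rarely say which was meant.

Explanation quality is quantified as **localization AUC**: per
aggregator-labeled record, the ROC AUC of channel-1 node importances as a
ranker of truth-mask membership, averaged over records (records whose mask
covers no atoms or all atoms carry no ranking signal and are skipped).

## Counterfactuals

The edit vocabulary spans atom substitution (elements
{C,N,O,S,F,Cl,Br,I,P}), single-atom addition by a single bond, deletion of
terminal atoms, bond-order changes among single/double/triple, bond
addition, and bond deletion. Edits are applied to a kekulized copy; each
candidate must survive full sanitization (valence check + aromaticity
re-perception). Candidates are deduplicated by canonical SMILES (first
generated wins), the source molecule is excluded, and deletions that would
disconnect the molecule are not emitted — a disconnected result is two
molecules, not a minimal edit of one. Enumeration order is fixed (edit kind,
site index, vocabulary position), and ranking sorts by |Δ p(aggregator)|
descending with canonical-form ascending tie-breaks, so outputs are fully
deterministic. Deviation is measured on the probability, not the logit,
matching how prediction confidence is reported. Depth-1 search is the
default — a minimal structural change is one edit — but a best-first
multi-edit mode is available (`depth`, `expansion_budget`): at each extra
level the highest-deviation candidates so far are themselves edited, with
deviation always measured against the original query. No chemical stability
or synthesizability filter is applied.

## Concepts

Per record and channel, nodes with importance ≥ τ (default 0.5 — the natural
midpoint of the mask range) form connected components; components of ≥ 2
atoms get an importance-weighted mean embedding from that channel's
final-layer node embeddings. Per channel, embeddings are reduced to 8
dimensions by PCA (deterministic, adequate for well-separated motif
embeddings) and clustered with DBSCAN (min cluster size default 5, radius
set data-adaptively to the median distance to the (min_size−1)-th nearest
neighbor). Density clustering leaves noise unassigned and discovers the
number of concepts from the data. Cluster counts depend on the trained model
and data and are *reported, not matched* to any external figure. Each
cluster is summarized by up to 10 representatives nearest the centroid and a
consensus substructure (RDKit maximum common substructure with a 5 s cap,
falling back to the most frequent member-fragment SMILES).

## Problem sizes and numerical choices

The benchmark configuration generates 4000 molecules (aggregator fraction
0.5, one seed), splits 3000/1000 train/test, and trains 30 epochs — chosen
as the smallest round configuration at which test accuracy and localization
comfortably saturate. Concept experiments use 700 two-motif molecules and
25 epochs. Equality tolerances: probability simplex 1e-6; permutation
equivariance 1e-5 (summation-order effects); pooling consistency 1e-6.
Degenerate inputs: single-atom molecules have no edges (attention block is a
no-op; node importance reduces to `sigmoid(0) × gate`); empty clusters and
empty cluster lists produce empty, well-formed reports.

## Limitations

- The attention/mask layer math is one concrete, documented realization of a
  multi-channel attention explainer; other published variants differ in the
  attention form and mask derivation.
- The protonation table covers five functional-group classes; it is not a
  pKa model.
- The synthetic benchmark bounds what the tests can claim about real
  aggregation data (see above); headline real-data accuracies in the
  literature (~82%/81% accuracy/F1 on ~190k molecules) require the original
  screening datasets and are deliberately not reproduced here.
- CPU-only, float64, desk scale; no GPU kernels or minibatch sharding beyond
  disjoint-union batching.
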