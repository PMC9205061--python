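# Methods

## Protein representation

A protein of N residues is featurized from (sequence, contact map)
alone; no alignment, PSSM or 3-D coordinates are used.

**Contact maps.** An N×N matrix of contact probabilities in [0, 1].
On load or synthesis the matrix is symmetrized by averaging with its
transpose (predictor outputs are near- but rarely exactly symmetric);
values outside [0, 1] by more than 1e-6 raise a warning and are
clipped. For sequences longer than a predictor's input limit the
sequence is cut into windows of length L = 1000 with step L/2 (the
final window clamped to the sequence end, never padded), each window is
mapped independently, and the full map is reassembled by averaging
overlapping entries. Residue pairs never co-resident in any window get
probability 0 — the model treats "never jointly predicted" as "no
contact". This is a deliberate choice; the alternative (NaN/masking)
would propagate into the graph builder for no benefit, since such pairs
are far apart in sequence and overwhelmingly non-contacting.

**Residue graph.** Nodes carry 33 features: a 21-slot one-hot residue
type (20 canonical + one unknown/non-standard slot for X/B/Z/U...),
five chemical-class flags (aliphatic AILMV, aromatic FWY, polar-neutral
CNQST, acidic DE, basic HKR), and seven continuous physicochemical
properties (molecular weight; pKa of α-COOH, α-NH₃⁺ and side chain;
isoelectric point; hydrophobicity at pH 2 and pH 7). The property
values are shipped in `data/residue_properties.csv` (CRC Handbook
dissociation constants and weights; Monera et al. 1995 hydrophobicity
scales). Continuous columns are min–max scaled to [0, 1] over the 20
canonical residues — unscaled weights (~100×) would dominate the
one-hot block. Unknown residues get column-mean continuous values and
zero flags. Side chains with no ionizable group carry pKa 0 in the
table; after scaling this is simply the block minimum.

Edges: self-loops (weight 1), peptide-bond neighbours |i−j| = 1
(weight 1), and every pair with |i−j| > 1 whose contact probability
**strictly exceeds** 0.5, weighted by that probability. "Exceeding" is
read strictly, so a probability of exactly 0.5 produces no edge.
`use_weights=False` keeps the identical edge set with unit weights (the
ablation arm).

## Molecule representation

SMILES are parsed with RDKit; hydrogens stay implicit (their counts are
features). Nodes carry 78 features: a 44-slot element one-hot (43 named
symbols + an "other" overflow slot, `data/atom_symbols.txt`), 11-slot
one-hots for degree, total H count and implicit H count (0–10, clamped
above), and an aromaticity flag. The three 11-slot blocks plus the
44-slot block sum to 77; the aromaticity bit is the 78th feature —
the reference feature tables this follows list 78 total without
itemizing the last bit, and the aromatic flag is the standard choice in
the GraphDTA feature lineage. Bonds become bidirectional unit-weight
edges; every atom gets a self-loop. No bond-type or 3-D features.

## Network

Both branches stack `gnn_layers = 3` message-passing layers
(ReLU between layers) and global mean pooling, so the latent dimension
(default 128) is independent of graph size and the encoders are
node-permutation invariant.

- **GCN layer**: H' = σ(D̂^{-1/2} Â D̂^{-1/2} H W). Â is the weighted
  adjacency *including self-loops* (unit self-loops are added for any
  node lacking one, i.e. Â = A + I for a bare edge list); D̂ uses
  *weighted* degrees — required for the edge weights to influence
  propagation at all. Uniformly rescaling all weights (self-loops
  included) cancels in the symmetric normalization.
- **GAT layer**: α_ij = softmax over j ∈ N(i) of
  LeakyReLU₀.₂(a · [W x_i ‖ W x_j]), h_i = σ(Σ_j α_ij W x_j), with
  N(i) containing i. The attention rows sum to 1 by construction.
  Since learned attention ignores given edge weights, the "weighted
  GAT" encoder is 1 GCN layer (injecting the weights) followed by 2 GAT
  layers; the molecule branch mirrors this for symmetry.
- **Head**: the two 128-d latents are concatenated and passed through
  256 → 1024 → 512 → 1 fully-connected layers with ReLU and dropout
  0.2 (training only). CPI applies a sigmoid; DTA leaves the output
  unbounded. Hidden widths, depth and dropout are package defaults
  (configurable); the reference architecture fixes only layer count,
  pooling and output activation.

Training: Adam, MSE loss (DTA) or logit binary cross-entropy (CPI).
Reference settings are lr 0.001, batch 512, 1000 (CPI) / 2000 (DTA)
epochs; desk-scale runs in the tests use 10–200 epochs with lr
0.005–0.05 (Adam's per-parameter step scale means ~200 full-batch steps
at lr 0.001 cannot move the output bias by the several pKd units the
labels span; raising lr rather than epochs keeps runtimes in seconds to
minutes). Everything is seeded: parameter init, batch shuffling and
dropout masks derive from one integer, and two runs with the same seed
produce identical loss logs.

The layers are implemented on a minimal NumPy reverse-mode autodiff
engine (`_autograd.py`) with an Adam optimizer, because the execution
environment provides no deep-learning framework. The GCN/GAT forward
math is shared between the trainable layers and the functional
`gcn_layer`/`gat_layer` ops, which the tests check against independent
dense/enumeration oracles to 1e-6.

## Metrics

- Precision = TP/(TP+FP), Recall = TP/(TP+FN); undefined cases (empty
  denominator) warn and return NaN rather than a silent 0.
- F1 is the standard harmonic mean 2PR/(P+R). (A printed reference
  form, 2(P+R)/(PR), is its reciprocal and unbounded; the harmonic mean
  is the only form consistent with F1 ∈ [0, 1].)
- Concordance index: Harrell's pairwise definition over strictly
  ordered true pairs, 0.5 credit for prediction ties (cross-checked
  against lifelines).
- ROC-AUC via scikit-learn's rank statistic; Pearson via SciPy.
- CPI decision threshold for precision/recall is 0.5 on the sigmoid
  output (conventional; configurable in `classification_metrics`).
- pKd = −log₁₀(Kd/10⁹) converts nanomolar dissociation constants.

5-fold cross validation uses a seeded random partition into folds whose
sizes differ by at most one; class-imbalance experiments subsample
negatives without replacement to 1:1 / 1:3 / 1:5, clamped to
availability with a warning.

## Synthetic data

`generate_synthetic_dataset` emulates the *shape* of a DTA/CPI corpus,
not its biology. Proteins are uniform random sequences over the 20
canonical residues: 10 short ones (80–400 residues, typical single
domains) and — whenever `max_seq_len > 1000` — two long ones
(1001–1200), whose contact maps are produced through the actual window
split/merge path so the long-sequence machinery is exercised end to
end. Contact maps are sampled with probability 1 on the diagonal,
[0.6, 1] within a band of width 4 (local structure), a 2% fraction of
long-range pairs in (0.5, 1] and everything else below 0.5 — the
qualitative signature of predicted maps (dense near-diagonal contacts,
sparse long-range ones). Molecules come from a fixed pool of 26 valid
SMILES (linear/branched alkanes, alkylbenzenes, small fused/linked
aromatics) whose aromatic-atom fraction spans [0, 1].

The planted label is linear:
`y = 5·(aromatic residue fraction) + 5·(aromatic atom fraction) + ε`,
ε ~ N(0, 0.3²), giving labels on a pKd-like 0–7 scale with variance ≈
4.5, dominated by a signal both encoders can read directly off node
features (the aromaticity flag / residue one-hots under mean pooling).
CPI labels threshold the noisy score at the pool median of the
noiseless score, giving roughly balanced classes. The generator returns
the signal description (weights, σ, threshold, per-entity fractions) so
tests can verify label variance against the closed form and measure
signal recovery.

What a green learnability test establishes: the full pipeline — map →
weighted graph → encoder → head → training loop — can extract a known
signal through both encoder variants. What it does not establish:
performance on real binding data, where the signal is nonlinear,
structure-dependent and far weaker; nothing here calibrates to Davis/
KIBA-scale benchmarks.

## Numerical and degenerate-input choices

- Contact-map text format: whitespace-delimited square matrix, 8
  significant digits on write; `.npy` as the binary dialect.
- Softmax in attention subtracts the per-neighbourhood maximum (a
  constant shift; exact for gradients).
- Exponentials are clipped at ±700 (±60 inside sigmoids) to avoid
  overflow; binary cross-entropy is computed on logits via softplus.
- Zero weighted degree in the convolution raises an error; it cannot
  occur for graphs built by this package (self-loops are universal).
- Empty sequences, empty molecules, non-square maps, length mismatches
  and task/label mismatches raise typed errors naming the offending
  entity, not asserts.
- Dropout makes the *training-mode* loss log noisy; capacity checks
  (e.g. fitting a constant label) should set `dropout=0`.

## Known limitations

- No contact-predictor integration is bundled: maps come from files,
  the synthetic sampler, or any caller-provided source honouring the
  same contract. (A language-model predictor is a drop-in: anything
  producing an N×N probability matrix.)
- Single attention head; no edge features in attention; no bond types.
- CPU-only NumPy training: fine for hundreds of pairs and thousands of
  residues, not for benchmark-scale corpora (tens of thousands of pairs
  × 1000+ epochs).
- The distance-weighted structure-based variant (real inter-residue
  distances as edge weights) is supported mechanically — any weight in
  (0, 1] per edge — but not validated against structural data here.
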