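# wgnn-dta

Sequence-based prediction of drug–target binding, for computational
chemists and ML practitioners doing virtual screening when no crystal
structure of the target is available. Two tasks share one architecture:

- **DTA** (drug–target affinity): regress a continuous binding strength
  such as pKd = −log₁₀(K_d/10⁹) for a molecule–protein pair.
- **CPI** (compound–protein interaction): classify whether the pair
  binds at all.

## The model

A protein is represented as a **weighted residue graph** derived from a
contact probability map (an N×N symmetric matrix of residue–residue
contact probabilities, e.g. from a protein language model). Residues are
nodes with 33-dimensional physicochemical feature vectors; an edge is
added wherever the contact probability exceeds 0.5, **weighted by that
probability**, plus unit-weight peptide-bond edges and self-loops.
Contact predictors with a length limit are handled by cutting the
sequence into windows of length L = 1000 with step L/2 and averaging the
merged per-window maps on their overlaps. A molecule is parsed from
SMILES into an atom graph (78-dimensional atom features, bond edges,
self-loops).

Both graphs are encoded by three graph-neural-network layers and global
mean pooling. The convolution layer propagates with the symmetrically
normalized weighted adjacency,

    H^{l+1} = σ( D̂^{-1/2} Â D̂^{-1/2} H^l W^{l+1} ),

where Â is the weighted adjacency with self-loops and D̂ its weighted
degree matrix, so the contact probabilities modulate message passing.
The attention variant uses softmax-normalized attention coefficients
α_ij (GAT); because attention cannot consume edge weights directly, one
leading convolution layer injects them before two attention layers. The
two pooled latents are concatenated and passed through a fully-connected
head; CPI adds a sigmoid on the output. Setting
`ModelConfig(use_edge_weights=False)` reproduces the unweighted-graph
ablation.

Everything runs on plain NumPy/SciPy (a small built-in reverse-mode
autodiff engine and Adam optimizer) — no deep-learning framework needed.

## Worked example

```python
import numpy as np
from wgnn_dta import (ModelConfig, TrainConfig, evaluate,
                      generate_synthetic_dataset, train)

# 120 molecule-protein pairs with a planted aromaticity signal
dataset, signal = generate_synthetic_dataset(120, task="dta", seed=1,
                                             max_seq_len=600)
idx = np.random.default_rng(1).permutation(len(dataset))
model, loss_log = train(dataset.subset(idx[:96]),
                        ModelConfig(task="dta", encoder_kind="gcn"),
                        TrainConfig(epochs=120, learning_rate=0.005, seed=1))
print(evaluate(model, dataset, idx[96:]).as_dict())
```

prints

```
{'mse': 0.09298582128595705, 'ci': 0.8568840579710145, 'pearson': 0.9876161794817732}
```

i.e. on 24 held-out pairs the model explains the planted affinity signal
almost completely (Pearson r ≈ 0.99), ranks pairs well (concordance
index 0.86) and has a squared error far below the label variance (≈ 4.5
for this generator). The same pipeline is exposed on the command line:

```sh
wgnn-dta synth-data --n-pairs 120 --seed 1 --out-dir data/
wgnn-dta train --data-dir data/ --epochs 120 --learning-rate 0.005 \
               --checkpoint model.npz
wgnn-dta evaluate --data-dir data/ --checkpoint model.npz
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
re-runs the core computation from scratch — synthetic dataset
generation, weighted-graph featurization, GCN training and held-out
evaluation — and writes its result JSON to `--out`.
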