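"""Weighted residue graphs from sequences and contact maps.

Each residue becomes a node carrying a 33-dimensional feature vector:
a 21-slot one-hot residue type (20 canonical residues plus an
unknown/non-standard slot), five chemical-class flags (aliphatic,
aromatic, polar-neutral, acidic, basic) and seven continuous
physicochemical properties (molecular weight, the pKa values of the
alpha-COOH, alpha-NH3+ and side-chain groups, isoelectric point, and
hydrophobicity at pH 2 and pH 7), min-max scaled to [0, 1] over the 20
canonical residues so they do not dominate the one-hot block.

Edges come from the contact map: every residue gets a self-loop of
weight 1, adjacent residues (peptide bonds) are connected with weight 1,
and residue pairs whose contact probability strictly exceeds the 0.5
threshold are connected with that probability as the edge weight.  The
``use_weights`` switch keeps the edge set but forces all weights to 1 —
the unweighted-graph ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .contact_maps import ContactMap

__all__ = [
    "RESIDUE_FEATURE_DIM",
    "CANONICAL_RESIDUES",
    "residue_features",
    "residue_feature_matrix",
    "build_weighted_protein_graph",
    "WeightedProteinGraph",
    "CONTACT_THRESHOLD",
]

RESIDUE_FEATURE_DIM = 33
CONTACT_THRESHOLD = 0.5

CANONICAL_RESIDUES = "ARNDCQEGHILKMFPSTWYV"

ALIPHATIC = set("AILMV")
AROMATIC = set("FWY")
POLAR_NEUTRAL = set("CNQST")
ACIDIC = set("DE")
BASIC = set("HKR")


def _load_property_table() -> pd.DataFrame:
    path = resources.files("wgnn_dta.data") / "residue_properties.csv"
    with resources.as_file(path) as p:
        tab = pd.read_csv(p, comment="#").set_index("code")
    return tab.loc[list(CANONICAL_RESIDUES)]


def _build_feature_table() -> dict[str, np.ndarray]:
    """Precompute the 33-dim vector for each canonical residue plus the
    unknown fallback (one-hot slot 21, zero flags, column-mean continuous
    values)."""
    props = _load_property_table()
    cont = props.to_numpy(dtype=np.float64)
    lo, hi = cont.min(axis=0), cont.max(axis=0)
    cont_scaled = (cont - lo) / (hi - lo)
    table: dict[str, np.ndarray] = {}
    for idx, code in enumerate(CANONICAL_RESIDUES):
        vec = np.zeros(RESIDUE_FEATURE_DIM)
        vec[idx] = 1.0
        vec[21] = float(code in ALIPHATIC)
        vec[22] = float(code in AROMATIC)
        vec[23] = float(code in POLAR_NEUTRAL)
        vec[24] = float(code in ACIDIC)
        vec[25] = float(code in BASIC)
        vec[26:33] = cont_scaled[idx]
        table[code] = vec
    unknown = np.zeros(RESIDUE_FEATURE_DIM)
    unknown[20] = 1.0
    unknown[26:33] = cont_scaled.mean(axis=0)
    table["*"] = unknown
    return table


_FEATURE_TABLE = _build_feature_table()


def residue_features(residue_code: str) -> np.ndarray:
    """33-dim feature vector for a one-letter residue code.

    Non-canonical symbols (X, B, Z, U, ...) map to the 21st one-hot slot
    with zero class flags and column-mean continuous properties.
    """
    if not residue_code:
        raise ValueError("empty residue code")
    code = residue_code.upper()
    vec = _FEATURE_TABLE.get(code, _FEATURE_TABLE["*"])
    return vec.copy()


def residue_feature_matrix(sequence: str) -> np.ndarray:
    """Stack per-residue features into an ``(N, 33)`` matrix."""
    if not sequence:
        raise ValueError("empty sequence")
    return np.stack([residue_features(c) for c in sequence])


@dataclass(frozen=True)
class WeightedProteinGraph:
    """Residue graph: ``(N, 33)`` node features and a symmetric directed
    edge list ``edge_index`` (2, E) with per-edge ``edge_weight`` in (0, 1]."""

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_weight: np.ndarray
    sequence: str

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    def edges(self) -> list[tuple[int, int, float]]:
        """Edge list as (i, j, weight) triples."""
        return [
            (int(i), int(j), float(w))
            for (i, j), w in zip(self.edge_index.T, self.edge_weight)
        ]


def build_weighted_protein_graph(
    sequence: str,
    cmap: ContactMap,
    threshold: float = CONTACT_THRESHOLD,
    use_weights: bool = True,
) -> WeightedProteinGraph:
    """Build the weighted residue graph for a sequence and its contact map.

    Edge set: self-loops and peptide-bond neighbours at weight 1, plus
    every pair with ``|i - j| > 1`` whose contact probability strictly
    exceeds ``threshold``, weighted by that probability.  Ties at exactly
    the threshold produce no edge ("exceeding" is read strictly).  With
    ``use_weights=False`` the same edge set is emitted with all weights 1.
    """
    n = len(sequence)
    if n != cmap.length:
        raise ValueError(
            f"sequence length {n} does not match contact map side {cmap.length}"
        )
    probs = cmap.probs
    iu, ju = np.triu_indices(n, k=2)
    keep = probs[iu, ju] > threshold
    ci, cj, cw = iu[keep], ju[keep], probs[iu, ju][keep]

    idx = np.arange(n)
    src = [idx, idx[:-1], idx[1:], ci, cj]
    dst = [idx, idx[1:], idx[:-1], cj, ci]
    wgt = [
        np.ones(n),
        np.ones(n - 1),
        np.ones(n - 1),
        cw,
        cw,
    ]
    edge_index = np.stack([np.concatenate(src), np.concatenate(dst)])
    edge_weight = np.concatenate(wgt)
    if not use_weights:
        edge_weight = np.ones_like(edge_weight)
    return WeightedProteinGraph(
        node_features=residue_feature_matrix(sequence),
        edge_index=edge_index.astype(np.int64),
        edge_weight=edge_weight,
        sequence=sequence,
    )
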