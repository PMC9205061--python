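"""Molecular graphs from SMILES.

Heavy atoms become nodes; each node carries a 78-dimensional feature
vector: a 44-slot one-hot element type (43 named symbols plus an "other"
overflow slot), 11-slot one-hots for degree, total hydrogen count and
implicit hydrogen count (0-10, clamped above), and an aromaticity flag.
Bonds become undirected (bidirectional) unit-weight edges and every atom
gets a self-loop, mirroring the protein-graph construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem

__all__ = [
    "ATOM_FEATURE_DIM",
    "ATOM_SYMBOLS",
    "SmilesParseError",
    "atom_features",
    "build_molecular_graph",
    "MolecularGraph",
]

ATOM_FEATURE_DIM = 78
_ONE_HOT_MAX = 10  # degree / H-count one-hots cover 0..10


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


def _load_symbols() -> list[str]:
    path = resources.files("wgnn_dta.data") / "atom_symbols.txt"
    with resources.as_file(path) as p:
        lines = [ln.strip() for ln in p.read_text().splitlines()]
    return [ln for ln in lines if ln and not ln.startswith("#")]


ATOM_SYMBOLS = _load_symbols()
_SYMBOL_INDEX = {s: i for i, s in enumerate(ATOM_SYMBOLS)}


def _clamped_one_hot(value: int, size: int) -> np.ndarray:
    vec = np.zeros(size)
    vec[min(value, size - 1)] = 1.0
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """78-dim feature vector for an RDKit atom.

    Element symbols outside the fixed 44-symbol list map to the final
    "other" slot; degree and hydrogen counts above 10 clamp to the last
    slot of their block.
    """
    sym = np.zeros(len(ATOM_SYMBOLS))
    sym[_SYMBOL_INDEX.get(atom.GetSymbol(), len(ATOM_SYMBOLS) - 1)] = 1.0
    return np.concatenate(
        [
            sym,
            _clamped_one_hot(atom.GetDegree(), _ONE_HOT_MAX + 1),
            _clamped_one_hot(atom.GetTotalNumHs(), _ONE_HOT_MAX + 1),
            _clamped_one_hot(atom.GetNumImplicitHs(), _ONE_HOT_MAX + 1),
            [float(atom.GetIsAromatic())],
        ]
    )


@dataclass(frozen=True)
class MolecularGraph:
    """Atom graph: ``(M, 78)`` node features and a symmetric directed edge
    list including self-loops; all edge weights are 1."""

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_weight: np.ndarray
    smiles: str

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    def edges(self) -> list[tuple[int, int, float]]:
        return [
            (int(i), int(j), float(w))
            for (i, j), w in zip(self.edge_index.T, self.edge_weight)
        ]


def build_molecular_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom graph.

    Hydrogens stay implicit (their counts are node features).  Bond edges
    are emitted in both directions and each atom gets a self-loop.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    m = mol.GetNumAtoms()
    if m == 0:
        raise ValueError(f"SMILES {smiles!r} yields an empty molecule")
    feats = np.stack([atom_features(a) for a in mol.GetAtoms()])
    src: list[int] = []
    dst: list[int] = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src += [a, b]
        dst += [b, a]
    src += list(range(m))  # self-loops
    dst += list(range(m))
    edge_index = np.array([src, dst], dtype=np.int64)
    return MolecularGraph(
        node_features=feats,
        edge_index=edge_index,
        edge_weight=np.ones(edge_index.shape[1]),
        smiles=smiles,
    )
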