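"""Weighted graph neural network for affinity and interaction prediction.

Two graph branches — one over the molecular atom graph, one over the
weighted residue graph — each stack three message-passing layers and a
global mean pool, producing fixed-length latent vectors that a
fully-connected head maps to a scalar: an unbounded affinity for the
regression task (DTA) or a logit/sigmoid probability for binary
interaction (CPI).

The graph convolution layer propagates with the symmetrically normalized
weighted adjacency

    H' = sigma( D^{-1/2} A_hat D^{-1/2} H W ),

where A_hat is the weighted adjacency including self-loops and D its
diagonal weighted-degree matrix, so contact probabilities on the edges
modulate the propagation.  The attention layer computes standard
softmax-normalized attention coefficients with a LeakyReLU pairwise
score; because attention coefficients are learned rather than given,
edge weights enter the attention variant through a single leading
convolution layer ("weighted GAT": 1 GCN + 2 GAT layers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from ._autograd import Adam, Parameter, Tensor
from .mol_graph import MolecularGraph
from .protein_graph import WeightedProteinGraph

__all__ = [
    "LayerWeights",
    "ModelConfig",
    "WgnnModel",
    "GraphBatch",
    "gcn_layer",
    "gat_layer",
    "normalized_adjacency",
    "prepare_batch",
]

EdgeList = Sequence[tuple[int, int, float]]


@dataclass
class LayerWeights:
    """Weights of one message-passing layer: the channel map ``W``
    (in_dim, out_dim); for attention layers additionally the pairwise
    score vector ``a`` of length 2*out_dim (first half paired with the
    centre node, second half with the neighbour)."""

    W: np.ndarray
    a: np.ndarray | None = None
    bias: np.ndarray | None = None


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_kind`` selects the branch stack: ``"gcn"`` is three
    convolution layers; ``"gat"`` is one convolution (injecting edge
    weights) followed by two attention layers.  ``task`` selects the
    output: ``"dta"`` leaves the head output unbounded, ``"cpi"``
    applies a sigmoid.
    """

    task: str = "dta"
    encoder_kind: str = "gcn"
    gnn_layers: int = 3
    hidden_dim: int = 128
    head_hidden: tuple[int, ...] = (1024, 512)
    dropout: float = 0.2
    use_edge_weights: bool = True

    def __post_init__(self) -> None:
        if self.task not in ("dta", "cpi"):
            raise ValueError(f"task must be 'dta' or 'cpi', got {self.task!r}")
        if self.encoder_kind not in ("gcn", "gat"):
            raise ValueError(
                f"encoder_kind must be 'gcn' or 'gat', got {self.encoder_kind!r}"
            )
        if self.gnn_layers < 1:
            raise ValueError("gnn_layers must be >= 1")
        self.head_hidden = tuple(self.head_hidden)

    @property
    def output_activation(self) -> str | None:
        return "sigmoid" if self.task == "cpi" else None


# ---------------------------------------------------------------------------
# graph preparation
# ---------------------------------------------------------------------------

def normalized_adjacency(
    num_nodes: int,
    edge_index: np.ndarray,
    edge_weight: np.ndarray,
) -> sp.csr_matrix:
    """Symmetrically normalized weighted adjacency D^{-1/2} A_hat D^{-1/2}.

    Self-loops are added (weight 1) for any node lacking one, so A_hat =
    A + I when the edge list carries none.
    """
    src, dst = np.asarray(edge_index)
    w = np.asarray(edge_weight, dtype=np.float64)
    has_loop = np.zeros(num_nodes, dtype=bool)
    has_loop[src[src == dst]] = True
    if not has_loop.all():
        missing = np.flatnonzero(~has_loop)
        src = np.concatenate([src, missing])
        dst = np.concatenate([dst, missing])
        w = np.concatenate([w, np.ones(missing.size)])
    adj = sp.coo_matrix((w, (dst, src)), shape=(num_nodes, num_nodes)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise ValueError("node with non-positive weighted degree")
    dinv = sp.diags(1.0 / np.sqrt(deg))
    return (dinv @ adj @ dinv).tocsr()


def _edges_to_arrays(edges) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(edges, tuple) and len(edges) == 2:
        return np.asarray(edges[0]), np.asarray(edges[1], dtype=np.float64)
    arr = np.asarray([(i, j) for i, j, _ in edges], dtype=np.int64).T
    w = np.asarray([w for _, _, w in edges], dtype=np.float64)
    return arr, w


_ACTIVATIONS = {
    None: lambda t: t,
    "identity": lambda t: t,
    "relu": lambda t: t.relu(),
    "sigmoid": lambda t: t.sigmoid(),
}


def _gcn_forward(
    H: Tensor, S: sp.csr_matrix, W: Tensor, bias: Tensor | None, activation
) -> Tensor:
    out = H.sparse_matmul(S).matmul(W)
    if bias is not None:
        out = out + bias
    return _ACTIVATIONS[activation](out)


def _segment_max(values: np.ndarray, ids: np.ndarray, n: int) -> np.ndarray:
    out = np.full(n, -np.inf)
    np.maximum.at(out, ids, values)
    return out


def _gat_forward(
    X: Tensor,
    edge_index: np.ndarray,
    W: Tensor,
    a_dst: Tensor,
    a_src: Tensor,
    bias: Tensor | None,
    activation,
    negative_slope: float = 0.2,
    return_attention: bool = False,
):
    src, dst = edge_index
    n = X.shape[0]
    z = X.matmul(W)  # (N, F')
    fp = z.shape[1]
    s_dst = z.matmul(a_dst.reshape(fp, 1))  # (N, 1)
    s_src = z.matmul(a_src.reshape(fp, 1))
    e = (s_dst.gather_rows(dst) + s_src.gather_rows(src)).leaky_relu(
        negative_slope
    )  # (E, 1)
    # softmax over each node's incoming edges; the per-node shift is a
    # constant (softmax is shift-invariant), so it carries no gradient
    shift = _segment_max(e.data.ravel(), dst, n)
    ex = (e - Tensor(shift[dst][:, None])).exp()
    denom = ex.segment_sum(dst, n)  # (N, 1)
    alpha = ex * denom.gather_rows(dst).pow(-1.0)
    h = Tensor.edge_aggregate(alpha, z, src, dst, n)
    if bias is not None:
        h = h + bias
    h = _ACTIVATIONS[activation](h)
    if return_attention:
        return h, alpha
    return h


# -- functional layer ops (NumPy in / NumPy out) ----------------------------

def gcn_layer(
    H: np.ndarray,
    edges: EdgeList | tuple[np.ndarray, np.ndarray],
    weights: LayerWeights | np.ndarray,
    activation: str | None = None,
) -> np.ndarray:
    """One graph-convolution step sigma(D^{-1/2} A_hat D^{-1/2} H W)."""
    H = np.asarray(H, dtype=np.float64)
    if isinstance(weights, np.ndarray):
        weights = LayerWeights(W=weights)
    edge_index, edge_weight = _edges_to_arrays(edges)
    S = normalized_adjacency(H.shape[0], edge_index, edge_weight)
    bias = None if weights.bias is None else Tensor(weights.bias)
    return _gcn_forward(Tensor(H), S, Tensor(weights.W), bias, activation).data


def gat_layer(
    X: np.ndarray,
    edges: EdgeList | tuple[np.ndarray, np.ndarray],
    weights: LayerWeights,
    activation: str | None = None,
    negative_slope: float = 0.2,
    return_attention: bool = False,
):
    """One graph-attention step h_i = sigma(sum_j alpha_ij W x_j).

    The attention coefficients alpha_ij are the softmax over node i's
    neighbourhood (self included) of LeakyReLU(a . [W x_i || W x_j]).
    With ``return_attention=True`` additionally returns the per-edge
    alpha values aligned with the edge list.
    """
    X = np.asarray(X, dtype=np.float64)
    if weights.a is None:
        raise ValueError("gat_layer requires LayerWeights.a")
    edge_index, _ = _edges_to_arrays(edges)
    fp = weights.W.shape[1]
    a_dst, a_src = weights.a[:fp], weights.a[fp:]
    bias = None if weights.bias is None else Tensor(weights.bias)
    out = _gat_forward(
        Tensor(X),
        edge_index,
        Tensor(weights.W),
        Tensor(a_dst),
        Tensor(a_src),
        bias,
        activation,
        negative_slope,
        return_attention,
    )
    if return_attention:
        h, alpha = out
        return h.data, alpha.data.ravel()
    return out.data


# ---------------------------------------------------------------------------
# trainable layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _GCNConv:
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.W = Parameter(_glorot(rng, fin, fout))
        self.b = Parameter(np.zeros(fout))

    def parameters(self):
        return [self.W, self.b]

    def __call__(self, H: Tensor, batch: "GraphBatch") -> Tensor:
        return _gcn_forward(H, batch.S, self.W, self.b, "relu")


class _GATConv:
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.W = Parameter(_glorot(rng, fin, fout))
        self.a_dst = Parameter(_glorot(rng, fout, 1).ravel())
        self.a_src = Parameter(_glorot(rng, fout, 1).ravel())
        self.b = Parameter(np.zeros(fout))

    def parameters(self):
        return [self.W, self.a_dst, self.a_src, self.b]

    def __call__(self, H: Tensor, batch: "GraphBatch") -> Tensor:
        return _gat_forward(
            H, batch.edge_index, self.W, self.a_dst, self.a_src, self.b, "relu"
        )


class _Dense:
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.W = Parameter(_glorot(rng, fin, fout))
        self.b = Parameter(np.zeros(fout))

    def parameters(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.W) + self.b


@dataclass
class GraphBatch:
    """A set of graphs packed into one block-diagonal graph."""

    x: np.ndarray  # (N_total, F) node features
    S: sp.csr_matrix  # normalized weighted adjacency, block-diagonal
    edge_index: np.ndarray  # (2, E_total), node ids offset per graph
    graph_ids: np.ndarray  # (N_total,) which graph each node belongs to
    num_graphs: int
    counts: np.ndarray  # (num_graphs,) nodes per graph


def prepare_batch(
    graphs: Sequence[MolecularGraph | WeightedProteinGraph],
    use_edge_weights: bool = True,
) -> GraphBatch:
    """Pack graphs into one disconnected block graph for batched encoding."""
    if not graphs:
        raise ValueError("empty graph batch")
    xs, blocks, eis, gids = [], [], [], []
    offset = 0
    for gid, g in enumerate(graphs):
        n = g.num_nodes
        if n == 0:
            raise ValueError("graph with no nodes")
        w = g.edge_weight if use_edge_weights else np.ones_like(g.edge_weight)
        xs.append(g.node_features)
        blocks.append(normalized_adjacency(n, g.edge_index, w))
        eis.append(g.edge_index + offset)
        gids.append(np.full(n, gid))
        offset += n
    return GraphBatch(
        x=np.concatenate(xs),
        S=sp.block_diag(blocks, format="csr"),
        edge_index=np.concatenate(eis, axis=1),
        graph_ids=np.concatenate(gids),
        num_graphs=len(graphs),
        counts=np.array([g.num_nodes for g in graphs], dtype=np.float64),
    )


class _GraphEncoder:
    """Stack of message-passing layers plus global mean pooling."""

    def __init__(self, config: ModelConfig, in_dim: int, rng: np.random.Generator):
        h = config.hidden_dim
        dims = [in_dim] + [h] * config.gnn_layers
        self.layers: list[_GCNConv | _GATConv] = []
        for li in range(config.gnn_layers):
            # attention variant: one leading convolution injects the edge
            # weights, the remaining layers attend
            if config.encoder_kind == "gat" and li > 0:
                self.layers.append(_GATConv(dims[li], dims[li + 1], rng))
            else:
                self.layers.append(_GCNConv(dims[li], dims[li + 1], rng))

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def __call__(self, batch: GraphBatch) -> Tensor:
        H = Tensor(batch.x)
        for layer in self.layers:
            H = layer(H, batch)
        pooled = H.segment_sum(batch.graph_ids, batch.num_graphs)
        return pooled * Tensor(1.0 / batch.counts[:, None])


class WgnnModel:
    """Two-branch weighted GNN with a concatenation prediction head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        from .mol_graph import ATOM_FEATURE_DIM
        from .protein_graph import RESIDUE_FEATURE_DIM

        self.config = config
        rng = np.random.default_rng(seed)
        self.mol_encoder = _GraphEncoder(config, ATOM_FEATURE_DIM, rng)
        self.prot_encoder = _GraphEncoder(config, RESIDUE_FEATURE_DIM, rng)
        dims = [2 * config.hidden_dim, *config.head_hidden, 1]
        self.head = [
            _Dense(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)
        ]

    def parameters(self):
        params = self.mol_encoder.parameters() + self.prot_encoder.parameters()
        for layer in self.head:
            params += layer.parameters()
        return params

    # -- forward passes -------------------------------------------------
    def forward_logits(
        self,
        mol_batch: GraphBatch,
        prot_batch: GraphBatch,
        mol_pos: np.ndarray,
        prot_pos: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Per-pair raw head outputs (logits for CPI, affinities for DTA).

        ``mol_pos``/``prot_pos`` map each pair to its graph's position in
        the respective batch, so each distinct graph is encoded once.
        """
        zm = self.mol_encoder(mol_batch).gather_rows(mol_pos)
        zp = self.prot_encoder(prot_batch).gather_rows(prot_pos)
        h = zm.concat(zp, axis=1)
        p = self.config.dropout
        for layer in self.head[:-1]:
            h = layer(h).relu()
            if training and p > 0:
                if dropout_rng is None:
                    raise ValueError("training forward pass needs dropout_rng")
                mask = (dropout_rng.random(h.shape) >= p) / (1.0 - p)
                h = h * Tensor(mask)
        return self.head[-1](h).reshape(-1)

    def predict_pairs(
        self,
        mol_graphs: Sequence[MolecularGraph],
        prot_graphs: Sequence[WeightedProteinGraph],
        mol_pos: np.ndarray,
        prot_pos: np.ndarray,
    ) -> np.ndarray:
        """Deterministic (evaluation-mode) predictions for aligned pairs."""
        uw = self.config.use_edge_weights
        out = self.forward_logits(
            prepare_batch(mol_graphs, use_edge_weights=True),
            prepare_batch(prot_graphs, use_edge_weights=uw),
            np.asarray(mol_pos),
            np.asarray(prot_pos),
            training=False,
        ).data
        if self.config.task == "cpi":
            out = 1.0 / (1.0 + np.exp(-out))
        return out

    def predict(
        self, mol: MolecularGraph, prot: WeightedProteinGraph
    ) -> float:
        """Score one molecule-protein pair (CPI: probability in (0, 1);
        DTA: unbounded affinity)."""
        if not isinstance(mol, MolecularGraph) or not isinstance(
            prot, WeightedProteinGraph
        ):
            raise ValueError(
                "predict expects (MolecularGraph, WeightedProteinGraph)"
            )
        return float(
            self.predict_pairs([mol], [prot], np.array([0]), np.array([0]))[0]
        )

    def encode_molecule(self, mol: MolecularGraph) -> np.ndarray:
        """Latent vector of one molecule (length hidden_dim)."""
        return self.mol_encoder(prepare_batch([mol])).data[0]

    def encode_protein(self, prot: WeightedProteinGraph) -> np.ndarray:
        """Latent vector of one protein (length hidden_dim); honours
        ``config.use_edge_weights``."""
        batch = prepare_batch(
            [prot], use_edge_weights=self.config.use_edge_weights
        )
        return self.prot_encoder(batch).data[0]

    # -- serialization ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write config + weights to a single ``.npz`` checkpoint."""
        arrays = {
            f"param_{i}": p.data for i, p in enumerate(self.parameters())
        }
        arrays["config_json"] = np.array(json.dumps(asdict(self.config)))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "WgnnModel":
        with np.load(path, allow_pickle=False) as data:
            cfg = ModelConfig(**json.loads(str(data["config_json"])))
            model = cls(cfg)
            for i, p in enumerate(model.parameters()):
                arr = data[f"param_{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError(
                        f"checkpoint shape mismatch at parameter {i}"
                    )
                p.data = arr.astype(np.float64)
        return model
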