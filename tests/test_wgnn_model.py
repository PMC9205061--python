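import numpy as np
import pytest

from wgnn_dta import (
    LayerWeights,
    ModelConfig,
    WgnnModel,
    build_molecular_graph,
    build_weighted_protein_graph,
    gat_layer,
    gcn_layer,
)
from wgnn_dta.protein_graph import WeightedProteinGraph

from conftest import make_cmap, random_weighted_graph


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def dense_gcn_oracle(H, edges, W):
    """Brute-force sigma-less convolution via the dense normalized
    adjacency: out_i = sum_j A_ij / sqrt(d_i d_j) H_j W."""
    n = H.shape[0]
    A = np.zeros((n, n))
    for i, j, w in edges:
        A[j, i] = w  # messages j <- i stored row-wise per receiver
    d = A.sum(axis=1)
    out = np.zeros((n, H.shape[1]))
    for i in range(n):
        for j in range(n):
            if A[i, j]:
                out[i] += A[i, j] / np.sqrt(d[i] * d[j]) * H[j]
    return out @ W


def gat_enumeration_oracle(X, edges, W, a, slope=0.2):
    """Per-node enumeration of attention scores, softmax and weighted sums."""
    n = X.shape[0]
    z = X @ W
    fp = W.shape[1]
    neighbors = {i: [] for i in range(n)}
    for src, dst, _ in edges:
        neighbors[dst].append(src)
    out = np.zeros((n, fp))
    alphas = {}
    for i in range(n):
        scores = []
        for j in neighbors[i]:
            s = a[:fp] @ z[i] + a[fp:] @ z[j]
            scores.append(s if s > 0 else slope * s)
        scores = np.array(scores)
        e = np.exp(scores - scores.max())
        alpha = e / e.sum()
        for al, j in zip(alpha, neighbors[i]):
            out[i] += al * z[j]
            alphas[(j, i)] = al
    return out, alphas


class TestGcnLayer:
    def test_single_node_self_loop_identity(self):
        out = gcn_layer(np.array([[1.0]]), [(0, 0, 1.0)], np.array([[1.0]]))
        assert out == pytest.approx(np.array([[1.0]]))

    def test_weighted_path_graph_matches_brute_force(self, rng):
        edges = [(0, 0, 1.0), (1, 1, 1.0), (2, 2, 1.0),
                 (0, 1, 0.7), (1, 0, 0.7), (1, 2, 0.3), (2, 1, 0.3)]
        H = rng.normal(size=(3, 5))
        W = rng.normal(size=(5, 2))
        np.testing.assert_allclose(
            gcn_layer(H, edges, W), dense_gcn_oracle(H, edges, W), atol=1e-6
        )

    def test_uniform_weight_scaling_cancels(self, rng):
        edges = random_weighted_graph(rng, 5)
        doubled = [(i, j, 2 * w) for i, j, w in edges]
        H = rng.normal(size=(5, 4))
        W = rng.normal(size=(4, 3))
        np.testing.assert_allclose(
            gcn_layer(H, edges, W), gcn_layer(H, doubled, W), atol=1e-10
        )

    def test_adds_identity_when_self_loops_missing(self, rng):
        # A_hat = A + I: an edge list without self-loops must behave as if
        # unit self-loops were present
        bare = [(0, 1, 0.5), (1, 0, 0.5)]
        with_loops = bare + [(0, 0, 1.0), (1, 1, 1.0)]
        H = rng.normal(size=(2, 3))
        W = rng.normal(size=(3, 3))
        np.testing.assert_allclose(
            gcn_layer(H, bare, W), gcn_layer(H, with_loops, W), atol=1e-10
        )

    def test_activation_applied(self, rng):
        edges = [(0, 0, 1.0)]
        H = np.array([[-3.0]])
        W = np.array([[1.0]])
        assert gcn_layer(H, edges, W, activation="relu") == pytest.approx(0.0)


class TestGatLayer:
    def _weights(self, rng, fin, fout):
        return LayerWeights(
            W=rng.normal(size=(fin, fout)), a=rng.normal(size=2 * fout)
        )

    def test_single_node_softmax_over_one_element(self, rng):
        w = self._weights(rng, 3, 2)
        X = rng.normal(size=(1, 3))
        out, alpha = gat_layer(X, [(0, 0, 1.0)], w, return_attention=True)
        assert alpha == pytest.approx([1.0])
        np.testing.assert_allclose(out, X @ w.W, atol=1e-10)

    def test_attention_rows_sum_to_one(self, rng):
        edges = random_weighted_graph(rng, 6)
        w = self._weights(rng, 4, 3)
        X = rng.normal(size=(6, 4))
        _, alpha = gat_layer(X, edges, w, return_attention=True)
        sums = np.zeros(6)
        for (src, dst, _), al in zip(edges, alpha):
            sums[dst] += al
        np.testing.assert_allclose(sums, np.ones(6), atol=1e-6)

    def test_star_graph_matches_enumeration_oracle(self, rng):
        # hub 0 connected to 1..3, self-loops everywhere
        edges = [(i, i, 1.0) for i in range(4)]
        for leaf in (1, 2, 3):
            edges += [(0, leaf, 1.0), (leaf, 0, 1.0)]
        w = self._weights(rng, 5, 4)
        X = rng.normal(size=(4, 5))
        out = gat_layer(X, edges, w)
        expect, _ = gat_enumeration_oracle(X, edges, w.W, w.a)
        np.testing.assert_allclose(out, expect, atol=1e-6)

    def test_missing_attention_vector_rejected(self, rng):
        with pytest.raises(ValueError, match="a"):
            gat_layer(
                rng.normal(size=(2, 3)),
                [(0, 0, 1.0), (1, 1, 1.0)],
                LayerWeights(W=rng.normal(size=(3, 2))),
            )


# ---------------------------------------------------------------------------
# encoders and head
# ---------------------------------------------------------------------------

def _toy_protein(weight=0.8):
    return build_weighted_protein_graph(
        "ACDEFG", make_cmap(6, {(0, 4): weight})
    )


def _permute_graph(g: WeightedProteinGraph, perm: np.ndarray):
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    return WeightedProteinGraph(
        node_features=g.node_features[perm],
        edge_index=inv[g.edge_index],
        edge_weight=g.edge_weight,
        sequence="".join(g.sequence[i] for i in perm),
    )


@pytest.fixture(params=["gcn", "gat"])
def model(request):
    return WgnnModel(
        ModelConfig(task="dta", encoder_kind=request.param), seed=5
    )


class TestEncoders:
    def test_single_residue_pooling_is_identity(self):
        m = WgnnModel(ModelConfig(task="dta"), seed=0)
        g = build_weighted_protein_graph("A", make_cmap(1, {}))
        latent = m.encode_protein(g)
        assert latent.shape == (m.config.hidden_dim,)

    def test_node_permutation_invariance(self, model):
        g = _toy_protein()
        perm = np.random.default_rng(3).permutation(g.num_nodes)
        z0 = model.encode_protein(g)
        z1 = model.encode_protein(_permute_graph(g, perm))
        np.testing.assert_allclose(z0, z1, atol=1e-5)

    def test_molecule_permutation_invariance_via_smiles_relabel(self, model):
        # the same molecule parsed from two SMILES spellings has permuted
        # atom order; mean pooling must give the same latent
        z0 = model.encode_molecule(build_molecular_graph("OCC"))
        z1 = model.encode_molecule(build_molecular_graph("CCO"))
        np.testing.assert_allclose(z0, z1, atol=1e-5)

    def test_latent_size_independent_of_graph_size(self, model):
        za = model.encode_molecule(build_molecular_graph("CC"))
        zb = model.encode_molecule(build_molecular_graph("C" * 15))
        assert za.shape == zb.shape

    def test_edge_weights_are_live(self):
        # a sub-unit contact edge must change the latent when weights are on
        g = _toy_protein(weight=0.6)
        m_w = WgnnModel(
            ModelConfig(task="dta", use_edge_weights=True), seed=5
        )
        m_u = WgnnModel(
            ModelConfig(task="dta", use_edge_weights=False), seed=5
        )
        z_w = m_w.encode_protein(g)
        z_u = m_u.encode_protein(g)
        assert np.abs(z_w - z_u).max() > 1e-8


class TestPredict:
    def test_cpi_outputs_in_unit_interval(self):
        m = WgnnModel(ModelConfig(task="cpi"), seed=2)
        rng = np.random.default_rng(4)
        prot = _toy_protein()
        smiles = ["C" * n for n in range(2, 12)] + ["c1ccccc1", "CCO"]
        for _ in range(100):
            mol = build_molecular_graph(str(rng.choice(smiles)))
            assert 0.0 < m.predict(mol, prot) < 1.0

    def test_inference_determinism(self, model):
        mol = build_molecular_graph("CCO")
        prot = _toy_protein()
        assert model.predict(mol, prot) == model.predict(mol, prot)

    def test_zeroed_final_layer_outputs_bias(self, model):
        b = 3.25
        model.head[-1].W.data[:] = 0.0
        model.head[-1].b.data[:] = b
        out = model.predict(build_molecular_graph("CCC"), _toy_protein())
        assert out == pytest.approx(b)

    def test_type_mismatch_rejected(self, model):
        mol = build_molecular_graph("CC")
        with pytest.raises(ValueError):
            model.predict(mol, mol)

    def test_save_load_round_trip(self, tmp_path, model):
        mol = build_molecular_graph("CCO")
        prot = _toy_protein()
        before = model.predict(mol, prot)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = WgnnModel.load(path)
        assert back.config == model.config
        assert back.predict(mol, prot) == pytest.approx(before, abs=1e-12)
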