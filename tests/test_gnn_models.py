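"""Architecture contracts of the three GNN regressors and the trainer."""

import numpy as np
import pytest

import xasgnn as x
from xasgnn.gnn_models import GraphBatch, build_model
from xasgnn.molgraph import EDGE_FEATURE_DIM, NODE_FEATURE_DIM

from conftest import random_graph

ARCHS = ("gcn", "graphnet", "gatv2")


def small_config(arch, **kw):
    defaults = dict(architecture=arch, hidden_sizes=(16, 32), n_out=100,
                    seed=3)
    defaults.update(kw)
    return x.ModelConfig(**defaults)


def permute_graph(g, perm):
    inv = np.argsort(perm)
    return x.MolecularGraph(
        molecule_id=g.molecule_id,
        elements=[g.elements[i] for i in perm],
        node_features=g.node_features[perm],
        edges=[tuple(sorted((int(inv[v]), int(inv[w])))) for v, w in g.edges],
        edge_features=g.edge_features,
        hydrogen_counts=[g.hydrogen_counts[i] for i in perm])


class TestForwardContract:
    @pytest.mark.parametrize("arch", ARCHS)
    def test_output_length_100(self, arch, ethanol_graph):
        model = build_model(small_config(arch))
        y, acts = model.forward(ethanol_graph)
        assert y.shape == (100,)
        assert acts.shape == (ethanol_graph.n_atoms, 32)

    @pytest.mark.parametrize("arch", ARCHS)
    def test_permutation_invariant_output(self, arch):
        rng = np.random.default_rng(17)
        model = build_model(small_config(arch))
        for _ in range(3):
            g = random_graph(rng)
            perm = rng.permutation(g.n_atoms)
            y1, acts1 = model.forward(g)
            y2, acts2 = model.forward(permute_graph(g, perm))
            np.testing.assert_allclose(y1, y2, atol=1e-10)
            # activations are permutation-equivariant
            np.testing.assert_allclose(acts1[perm], acts2, atol=1e-10)

    @pytest.mark.parametrize("arch", ARCHS)
    def test_zero_weights_output_equals_bias(self, arch):
        model = build_model(small_config(arch))
        for p in model.parameters():
            p.data = np.zeros_like(p.data)
        bias = np.linspace(-1, 1, 100)
        model.output_layer.bias.data = bias.copy()
        g = x.MolecularGraph(
            molecule_id="z", elements=["C"],
            node_features=np.zeros((1, NODE_FEATURE_DIM)),
            edges=[], edge_features=np.zeros((0, EDGE_FEATURE_DIM)),
            hydrogen_counts=[0])
        y, _ = model.forward(g)
        np.testing.assert_allclose(y, bias, atol=1e-12)

    def test_batched_equals_single(self, dataset):
        model = build_model(small_config("graphnet"))
        graphs = [r.graph for r in dataset[:5]]
        out, _ = model.forward_batch(GraphBatch(graphs))
        for i, g in enumerate(graphs):
            y, _ = model.forward(g)
            np.testing.assert_allclose(out.data[i], y, atol=1e-10)


class TestGCNMessagePassing:
    def test_single_layer_matches_hand_unrolled_star(self):
        """One propagation step on a 4-node star, against a numpy loop."""
        model = build_model(small_config("gcn", hidden_sizes=(8,)))
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(4, NODE_FEATURE_DIM))
        g = x.MolecularGraph(
            molecule_id="star", elements=["C", "C", "C", "C"],
            node_features=feats,
            edges=[(0, 1), (0, 2), (0, 3)],
            edge_features=np.zeros((3, EDGE_FEATURE_DIM)),
            hydrogen_counts=[0, 0, 0, 0])
        _, acts = model.forward(g)
        W = model.layers[0].weight.data
        b = model.layers[0].bias.data
        neighbors = {0: [0, 1, 2, 3], 1: [0, 1], 2: [0, 2], 3: [0, 3]}
        for i in range(4):
            agg = np.mean([feats[j] for j in neighbors[i]], axis=0)
            pre = agg @ W + b
            expected = np.where(pre > 0, pre, 0.01 * pre)
            np.testing.assert_allclose(acts[i], expected, atol=1e-12)

    def test_edgeless_graph_nodes_independent(self):
        model = build_model(small_config("gcn", hidden_sizes=(8,)))
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(2, NODE_FEATURE_DIM))
        for i in range(2):
            g = x.MolecularGraph(
                molecule_id="lone", elements=["C"],
                node_features=feats[i:i + 1], edges=[],
                edge_features=np.zeros((0, EDGE_FEATURE_DIM)),
                hydrogen_counts=[0])
            g2 = x.MolecularGraph(
                molecule_id="pair", elements=["C", "C"],
                node_features=feats, edges=[],
                edge_features=np.zeros((0, EDGE_FEATURE_DIM)),
                hydrogen_counts=[0, 0])
            _, a1 = model.forward(g)
            _, a2 = model.forward(g2)
            np.testing.assert_allclose(a1[0], a2[i], atol=1e-12)


class TestGraphNetBlock:
    def test_single_block_matches_hand_unrolled_edge(self):
        """One block on a 2-node, 1-edge graph against independent numpy."""
        model = build_model(small_config("graphnet", hidden_sizes=(8,)))
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(2, NODE_FEATURE_DIM))
        ef = rng.normal(size=(1, EDGE_FEATURE_DIM))
        g = x.MolecularGraph(
            molecule_id="pair", elements=["C", "O"], node_features=feats,
            edges=[(0, 1)], edge_features=ef, hydrogen_counts=[0, 0])
        _, acts = model.forward(g)

        def lrelu(v):
            return np.where(v > 0, v, 0.01 * v)

        u0 = feats.mean(axis=0)
        We, be = model.edge_layers[0].weight.data, model.edge_layers[0].bias.data
        Wn, bn = model.node_layers[0].weight.data, model.node_layers[0].bias.data
        e1 = lrelu(np.concatenate([ef[0], feats[0] + feats[1], u0]) @ We + be)
        for i in range(2):
            h1 = lrelu(np.concatenate([feats[i], e1, u0]) @ Wn + bn)
            np.testing.assert_allclose(acts[i], h1, atol=1e-12)

    def test_disconnected_components_couple_only_via_global(self):
        """With the global-update weights zeroed, one component's features
        cannot influence the other's activations."""
        model = build_model(small_config("graphnet", hidden_sizes=(8, 8)))
        for lay in model.global_layers:
            lay.weight.data = np.zeros_like(lay.weight.data)
            lay.bias.data = np.zeros_like(lay.bias.data)
        # also sever the initial global state (mean of raw node features)
        # from the first block's edge and node updates
        nd = NODE_FEATURE_DIM
        model.edge_layers[0].weight.data[EDGE_FEATURE_DIM + nd:] = 0.0
        model.node_layers[0].weight.data[-nd:] = 0.0
        rng = np.random.default_rng(3)
        feats = rng.normal(size=(4, NODE_FEATURE_DIM))
        ef = rng.normal(size=(2, EDGE_FEATURE_DIM))

        def two_comp(second_feats):
            nf = feats.copy()
            nf[2:] = second_feats
            return x.MolecularGraph(
                molecule_id="cc", elements=["C", "C", "O", "O"],
                node_features=nf, edges=[(0, 1), (2, 3)],
                edge_features=ef, hydrogen_counts=[0] * 4)

        _, a1 = model.forward(two_comp(feats[2:]))
        _, a2 = model.forward(two_comp(feats[2:] + 5.0))
        np.testing.assert_allclose(a1[:2], a2[:2], atol=1e-12)
        assert not np.allclose(a1[2:], a2[2:])

        # with nonzero global updates the coupling reappears
        model2 = build_model(small_config("graphnet", hidden_sizes=(8, 8)))
        _, b1 = model2.forward(two_comp(feats[2:]))
        _, b2 = model2.forward(two_comp(feats[2:] + 5.0))
        assert not np.allclose(b1[:2], b2[:2])


class TestGATv2Attention:
    def test_zero_attention_vector_reduces_to_uniform_average(self):
        """All logits equal -> softmax uniform -> plain neighborhood mean."""
        model = build_model(small_config("gatv2", hidden_sizes=(8,),
                                         n_heads=2))
        model.att[0].data = np.zeros_like(model.att[0].data)
        rng = np.random.default_rng(4)
        feats = rng.normal(size=(3, NODE_FEATURE_DIM))
        g = x.MolecularGraph(
            molecule_id="path", elements=["C", "C", "C"],
            node_features=feats, edges=[(0, 1), (1, 2)],
            edge_features=np.zeros((2, EDGE_FEATURE_DIM)),
            hydrogen_counts=[0] * 3)
        _, acts = model.forward(g)
        Wr = model.w_right[0].weight.data
        br = model.w_right[0].bias.data
        right = feats @ Wr + br  # (3, 2*8)
        neighbors = {0: [0, 1], 1: [0, 1, 2], 2: [1, 2]}
        for i in range(3):
            per_head = np.mean([right[j] for j in neighbors[i]],
                               axis=0).reshape(2, 8)
            pre = per_head.mean(axis=0)  # heads averaged on the final layer
            expected = np.where(pre > 0, pre, 0.01 * pre)
            np.testing.assert_allclose(acts[i], expected, atol=1e-12)

    def test_attention_coefficients_match_manual_softmax(self):
        """3-node path: recompute the GATv2 logits and softmax by hand."""
        from xasgnn.autodiff import Tensor, segment_softmax
        model = build_model(small_config("gatv2", hidden_sizes=(8,),
                                         n_heads=1))
        rng = np.random.default_rng(5)
        feats = rng.normal(size=(3, NODE_FEATURE_DIM))
        g = x.MolecularGraph(
            molecule_id="path", elements=["C", "C", "C"],
            node_features=feats, edges=[(0, 1), (1, 2)],
            edge_features=np.zeros((2, EDGE_FEATURE_DIM)),
            hydrogen_counts=[0] * 3)
        batch = GraphBatch([g])
        src = np.concatenate([batch.src, batch.loop])
        dst = np.concatenate([batch.dst, batch.loop])
        Wl, bl = model.w_left[0].weight.data, model.w_left[0].bias.data
        Wr, br = model.w_right[0].weight.data, model.w_right[0].bias.data
        a = model.att[0].data[0, 0]
        left, right = feats @ Wl + bl, feats @ Wr + br
        logits = np.empty(len(src))
        for k, (s, d) in enumerate(zip(src, dst)):
            pair = left[d] + right[s]
            logits[k] = np.where(pair > 0, pair, 0.01 * pair) @ a
        # manual per-target softmax
        alpha_manual = np.empty_like(logits)
        for d in np.unique(dst):
            mask = dst == d
            ex = np.exp(logits[mask] - logits[mask].max())
            alpha_manual[mask] = ex / ex.sum()
        alpha_model = segment_softmax(
            Tensor(logits[:, None]), dst, 3).data[:, 0]
        np.testing.assert_allclose(alpha_model, alpha_manual, atol=1e-12)


class TestTraining:
    def test_memorizes_single_molecule(self, dataset):
        rec = dataset[0]
        pairs = [(rec.graph, rec.spectrum)] * 2
        model = build_model(small_config("gatv2", hidden_sizes=(16, 32)))
        model, hist = x.train(model, pairs, x.TrainConfig(
            epochs=400, val_fraction=0.5, val_check_every=100, seed=0))
        assert hist["train_rmse"][-1] < 1e-2 * rec.spectrum.intensities.max()

    def test_lr_schedule(self, dataset):
        rec = dataset[0]
        pairs = [(rec.graph, rec.spectrum)] * 2
        model = build_model(small_config("gcn", hidden_sizes=(4,)))
        _, hist = x.train(model, pairs, x.TrainConfig(
            epochs=250, val_fraction=0.5, val_check_every=250, seed=0))
        assert hist["lr"][0] == pytest.approx(1e-3)
        assert hist["lr"][150] == pytest.approx(1e-3 * 0.8)   # epoch 151
        assert hist["lr"][249] == pytest.approx(1e-3 * 0.8 ** 2)

    def test_reproducible_history(self, dataset):
        pairs = x.training_pairs(dataset[:20])
        hists = []
        for _ in range(2):
            model = build_model(small_config("gcn", hidden_sizes=(8,)))
            _, h = x.train(model, pairs, x.TrainConfig(
                epochs=10, val_check_every=5, seed=4))
            hists.append(h)
        assert hists[0]["train_rmse"] == hists[1]["train_rmse"]
        assert hists[0]["val_rmse"] == hists[1]["val_rmse"]

    def test_empty_dataset_rejected(self):
        model = build_model(small_config("gcn"))
        with pytest.raises(ValueError):
            x.train(model, [], x.TrainConfig())

    def test_validation_never_trained_on(self, dataset):
        pairs = x.training_pairs(dataset[:20])
        model = build_model(small_config("gcn", hidden_sizes=(8,)))
        _, h = x.train(model, pairs, x.TrainConfig(
            epochs=2, val_check_every=1, seed=4))
        val_idx = set(h["val_indices"])
        assert len(val_idx) == 4  # 20% of 20
        assert all(0 <= i < 20 for i in val_idx)
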