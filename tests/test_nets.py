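"""Basis expansions, message-passing primitives and classifier invariances."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pocketec.autodiff import Tensor, constant, parameter, ssp
from pocketec.eclabel import ECLabel
from pocketec.graph_build import GraphBatch, ProteinGraph, build_edges
from pocketec.nets import (
    ModelConfig,
    RBFConfig,
    SBFConfig,
    atomwise,
    build_model,
    cfconv,
    dimenet_message_update,
    featurize,
    load_checkpoint,
    predict_ec,
    rbf_expand,
    save_checkpoint,
    sbf_expand,
    softmax,
    _spherical_bessel_zeros,
)


def _random_graph(rng, n=8, n_types=21, radius=8.0, max_neighbors=6, spread=6.0):
    positions = rng.uniform(-spread, spread, size=(n, 3))
    return ProteinGraph(
        positions=positions,
        node_types=rng.integers(0, n_types, size=n).astype(np.intp),
        edge_index=build_edges(positions, radius, max_neighbors),
        resolution="residue",
        neighbor_radius=radius,
    )


def _cfg(arch, **kw):
    base = dict(
        architecture=arch, n_classes=4, n_node_types=21, embedding_dim=16,
        hidden_dim=16, n_filters=16, n_interactions=2, n_blocks=3, n_rbf=12,
        interaction_embedding=8, output_embedding=16, cutoff=10.0,
    )
    base.update(kw)
    return ModelConfig(**base)


class TestRBF:
    def test_unity_at_center(self):
        cfg = RBFConfig.uniform(count=10, cutoff=10.0, gamma=10.0)
        for k in (0, 4, 9):
            assert rbf_expand(cfg.centers[k], cfg)[k] == 1.0

    def test_known_offset_value(self):
        cfg = RBFConfig(centers=np.array([0.0, 1.0]), gamma=10.0)
        val = rbf_expand(1.1, cfg)[1]  # offset 0.1, gamma 10 -> exp(-0.1)
        assert val == pytest.approx(np.exp(-0.1), rel=1e-12)

    def test_gaussian_tail_vanishes(self):
        cfg = RBFConfig(centers=np.array([0.0]), gamma=10.0)
        assert rbf_expand(3.0, cfg)[0] < 1e-39

    def test_grid_mode_has_301_centers(self):
        assert RBFConfig.grid().count == 301

    def test_rejects_bad_config(self):
        with pytest.raises(ValueError):
            RBFConfig(centers=np.array([1.0, 0.5]), gamma=10.0)
        with pytest.raises(ValueError):
            RBFConfig(centers=np.array([0.0, 1.0]), gamma=-1.0)


class TestSBF:
    def test_spherical_bessel_zeros_are_roots(self):
        from scipy.special import spherical_jn

        for l in range(4):
            zeros = _spherical_bessel_zeros(l, 4)
            assert np.all(np.diff(zeros) > 0)
            np.testing.assert_allclose(spherical_jn(l, zeros), 0.0, atol=1e-10)

    def test_shape_and_finiteness(self):
        cfg = SBFConfig(num_spherical=7, num_radial=6, cutoff=10.0)
        out = sbf_expand(np.array([1.0, 5.0]), np.array([0.3, 2.0]), cfg)
        assert out.shape == (2, 42)
        assert np.all(np.isfinite(out))


class TestCfconv:
    def test_isolated_node_gets_zero_row(self):
        x = constant(np.ones((3, 4)))
        filt = constant(np.ones((1, 4)))
        edge_index = np.array([[0], [1]])  # only node 1 receives
        out = cfconv(x, filt, edge_index, 3)
        np.testing.assert_array_equal(out.data[0], 0.0)
        np.testing.assert_array_equal(out.data[2], 0.0)
        np.testing.assert_array_equal(out.data[1], 1.0)

    def test_matches_dense_double_loop(self):
        rng = np.random.default_rng(0)
        n, F = 6, 5
        x = rng.normal(size=(n, F))
        edge_index = np.array([[j, i] for i in range(n) for j in range(n) if i != j]).T
        filters = rng.normal(size=(edge_index.shape[1], F))
        out = cfconv(constant(x), constant(filters), edge_index, n).data
        expected = np.zeros((n, F))
        for e, (j, i) in enumerate(edge_index.T):
            expected[i] += x[j] * filters[e]
        np.testing.assert_allclose(out, expected, atol=1e-6)


class TestAtomwise:
    def test_identity_weights(self):
        x = np.random.default_rng(1).normal(size=(4, 3))
        out = atomwise(constant(x), constant(np.eye(3)), constant(np.zeros(3)))
        np.testing.assert_array_equal(out.data, x)

    def test_permutation_equivariance_and_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 3))
        W = rng.normal(size=(3, 4))
        b = rng.normal(size=4)
        out = atomwise(constant(x), constant(W), constant(b)).data
        np.testing.assert_allclose(out, x @ W + b, atol=1e-12)
        perm = rng.permutation(5)
        out_p = atomwise(constant(x[perm]), constant(W), constant(b)).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)


class TestDirectionalUpdate:
    def _params(self, rng, H=6, K=5, S=4, B=3, I=4):
        mk = lambda *shape: parameter(rng.normal(size=shape) * 0.3)
        return {
            "W_src": mk(H, H), "b_src": mk(H), "W_kj": mk(H, H), "b_kj": mk(H),
            "W_rb1": mk(K, B), "W_rb2": mk(B, H), "W_sb1": mk(S, B), "W_sb2": mk(B, I),
            "W_down": mk(H, I), "W_up": mk(I, H), "W_res": mk(H, H), "b_res": mk(H),
        }

    def test_no_triplets_reduces_to_self_path(self):
        rng = np.random.default_rng(3)
        params = self._params(rng)
        m = constant(rng.normal(size=(2, 6)))
        rbf = rng.normal(size=(2, 5))
        out = dimenet_message_update(m, rbf, np.zeros((0, 4)), np.zeros(0, dtype=int),
                                     np.zeros(0, dtype=int), params)
        # directional sum empty -> x_ji + residual layer only
        from pocketec.autodiff import matmul

        x_ji = ssp(atomwise(m, params["W_src"], params["b_src"]))
        up = ssp(matmul(segment_sum_zero(2, 4), params["W_up"]))
        expected = x_ji + up
        expected = expected + ssp(atomwise(expected, params["W_res"], params["b_res"]))
        np.testing.assert_allclose(out.data, expected.data, atol=1e-12)

    def test_incoming_message_order_irrelevant(self):
        rng = np.random.default_rng(4)
        params = self._params(rng)
        E, T = 5, 6
        m = constant(rng.normal(size=(E, 6)))
        rbf = rng.normal(size=(E, 5))
        sbf = rng.normal(size=(T, 4))
        kj = rng.integers(0, E, size=T)
        ji = rng.integers(0, E, size=T)
        out = dimenet_message_update(m, rbf, sbf, kj, ji, params).data
        perm = rng.permutation(T)
        out_p = dimenet_message_update(m, rbf, sbf[perm], kj[perm], ji[perm], params).data
        np.testing.assert_allclose(out, out_p, atol=1e-9)

    def test_matches_naive_triplet_loop(self):
        rng = np.random.default_rng(5)
        params = self._params(rng)
        E, T, H, I = 4, 7, 6, 4
        m_np = rng.normal(size=(E, H))
        rbf = rng.normal(size=(E, 5))
        sbf = rng.normal(size=(T, 4))
        kj = rng.integers(0, E, size=T)
        ji = rng.integers(0, E, size=T)
        out = dimenet_message_update(constant(m_np), rbf, sbf, kj, ji, params).data

        def np_ssp(x):
            return np.logaddexp(x, 0.0) - np.log(2.0)

        P = {k: v.data for k, v in params.items()}
        x_ji = np_ssp(m_np @ P["W_src"] + P["b_src"])
        rbf_emb = rbf @ P["W_rb1"] @ P["W_rb2"]
        x_kj = np_ssp(np_ssp(m_np @ P["W_kj"] + P["b_kj"]) * rbf_emb @ P["W_down"])
        sbf_emb = sbf @ P["W_sb1"] @ P["W_sb2"]
        agg = np.zeros((E, I))
        for t in range(T):  # literal triplet loop
            agg[ji[t]] += x_kj[kj[t]] * sbf_emb[t]
        expected = x_ji + np_ssp(agg @ P["W_up"])
        expected = expected + np_ssp(expected @ P["W_res"] + P["b_res"])
        np.testing.assert_allclose(out, expected, atol=1e-6)


def segment_sum_zero(n_rows, width):
    from pocketec.autodiff import segment_sum

    return segment_sum(constant(np.zeros((0, width))), np.zeros(0, dtype=int), n_rows)


@pytest.mark.parametrize("arch", ["distances", "distances_angles"])
class TestForwardInvariances:
    def test_rigid_motion_invariance(self, arch):
        rng = np.random.default_rng(6)
        model = build_model(_cfg(arch), seed=1)
        for trial in range(5):
            g = _random_graph(rng)
            base = model.logits([g])
            R = Rotation.random(random_state=trial).as_matrix()
            g2 = dataclasses.replace(g, positions=g.positions @ R.T + rng.normal(size=3))
            moved = model.logits([g2])
            rel = np.max(np.abs(moved - base) / np.maximum(np.abs(base), 1e-9))
            assert rel < 1e-4

    def test_node_permutation_invariance(self, arch):
        rng = np.random.default_rng(7)
        model = build_model(_cfg(arch), seed=2)
        g = _random_graph(rng, n=10)
        base = model.logits([g])
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        g2 = ProteinGraph(
            positions=g.positions[perm],
            node_types=g.node_types[perm],
            edge_index=inv[g.edge_index],
            resolution="residue",
        )
        permuted = model.logits([g2])
        np.testing.assert_allclose(permuted, base, rtol=1e-9, atol=1e-9)

    def test_batch_locality(self, arch):
        """Changing one graph of a batch cannot change another graph's logits."""
        rng = np.random.default_rng(8)
        model = build_model(_cfg(arch), seed=3)
        ga, gb = _random_graph(rng), _random_graph(rng)
        base = model.forward(featurize(GraphBatch.from_graphs([ga, gb]), model.cfg)).data
        gb2 = dataclasses.replace(gb, node_types=(gb.node_types + 1) % 21)
        mod = model.forward(featurize(GraphBatch.from_graphs([ga, gb2]), model.cfg)).data
        np.testing.assert_allclose(mod[0], base[0], atol=1e-12)
        assert not np.allclose(mod[1], base[1])


def test_single_node_graph_is_readout_of_embedding():
    cfg = _cfg("distances")
    model = build_model(cfg, seed=4)
    g = ProteinGraph(
        positions=np.zeros((1, 3)),
        node_types=np.array([7], dtype=np.intp),
        edge_index=np.zeros((2, 0), dtype=np.intp),
        resolution="residue",
    )
    logits = model.logits([g])[0]
    # hand-trace: empty conv sums leave x at its embedding + per-block biases
    p = {k: v.data for k, v in model.params.items()}

    def np_ssp(x):
        return np.logaddexp(x, 0.0) - np.log(2.0)

    x = p["type_embedding"][7:8]
    for l in range(cfg.n_interactions):
        agg = np.zeros((1, cfg.n_filters))
        y = np_ssp(agg @ p[f"b{l}.W_o1"] + p[f"b{l}.b_o1"]) @ p[f"b{l}.W_o2"] + p[f"b{l}.b_o2"]
        x = x + y
    expected = (np_ssp(x @ p["W_r1"] + p["b_r1"]) @ p["W_r2"] + p["b_r2"])[0]
    np.testing.assert_allclose(logits, expected, atol=1e-10)


def test_gradient_reaches_every_node_embedding():
    rng = np.random.default_rng(9)
    model = build_model(_cfg("distances"), seed=5)
    g = _random_graph(rng, n=6, radius=30.0, max_neighbors=8)  # connected
    feats = featurize(GraphBatch.from_graphs([g]), model.cfg)
    logits = model.forward(feats)
    logits.sum().backward()
    emb_grad = model.params["type_embedding"].grad
    touched = np.unique(g.node_types)
    for t in touched:
        assert np.any(emb_grad[t] != 0)


class TestPredictEC:
    def test_hierarchy_truncation_worked_example(self):
        vocab = [ECLabel.parse(v) for v in ["1.1.1.1", "2.7.10.1", "3.4.21.4"]]
        label, conf = predict_ec(np.array([0.0, 9.0, 1.0]), vocab)
        assert str(label) == "2.7.10.1"
        assert str(label.truncate(1)) == "2"
        assert str(label.truncate(2)) == "2.7"
        assert str(label.truncate(3)) == "2.7.10"

    def test_confident_and_uniform_cases(self):
        vocab = [ECLabel.parse(str(i)) for i in range(4)]
        _, conf = predict_ec(np.array([100.0, 0, 0, 0]), vocab)
        assert conf == pytest.approx(1.0, abs=1e-10)
        _, conf = predict_ec(np.zeros(4), vocab)
        assert conf == pytest.approx(0.25)

    def test_tie_goes_to_lowest_index_with_warning(self):
        vocab = [ECLabel.parse(str(i)) for i in range(3)]
        with pytest.warns(UserWarning, match="tie"):
            label, _ = predict_ec(np.array([1.0, 1.0, 0.0]), vocab)
        assert str(label) == "0"

    def test_vocabulary_size_mismatch(self):
        with pytest.raises(ValueError, match="config error"):
            predict_ec(np.zeros(3), [ECLabel.parse("1")])


def test_checkpoint_round_trip_and_vocab_guard(tmp_path):
    rng = np.random.default_rng(10)
    model = build_model(_cfg("distances"), seed=6)
    g = _random_graph(rng)
    vocab = [ECLabel.parse(v) for v in ["1.1.1.1", "2.7.10.1", "3.4.21.4", "4.2.1.11"]]
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model, vocab, scheme_version="test-1")
    loaded, vocab2, sv = load_checkpoint(path, expected_vocab=vocab)
    assert sv == "test-1"
    np.testing.assert_allclose(loaded.logits([g]), model.logits([g]), atol=1e-12)
    with pytest.raises(ValueError, match="vocabulary"):
        load_checkpoint(path, expected_vocab=vocab[:2] + vocab[:2])


def test_softmax_rows_sum_to_one():
    rng = np.random.default_rng(11)
    p = softmax(rng.normal(size=(5, 4)) * 10, axis=1)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
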