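"""Loss, sampling, metrics and the training loop contracts."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, f1_score

from pocketec.autodiff import constant
from pocketec.nets import ModelConfig, build_model
from pocketec.train_eval import (
    LossSpec,
    TrainConfig,
    augment_translate,
    class_weights,
    oversample_indices,
    per_class_aupr,
    protein_centric_f1,
    train_model,
    weighted_cross_entropy,
)


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        w = class_weights({"a": 10, "b": 10})
        assert w == {"a": pytest.approx(1.0), "b": pytest.approx(1.0)}

    def test_rarer_class_weighs_more(self):
        w = class_weights({"a": 1, "b": 9})
        assert w["a"] > w["b"]
        assert w["a"] == pytest.approx(1.8)
        assert w["b"] == pytest.approx(0.2)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="unseen"):
            class_weights({"a": 0, "b": 5})


class TestWeightedCrossEntropy:
    def test_confident_correct_prediction_has_near_zero_loss(self):
        logits = np.array([[30.0, 0.0, 0.0, 0.0]])
        spec = LossSpec(weights=np.ones(4))
        loss = weighted_cross_entropy(logits, np.array([0]), spec)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_logits_give_log_c(self):
        spec = LossSpec(weights=np.ones(4))
        loss = weighted_cross_entropy(np.zeros((3, 4)), np.array([0, 1, 2]), spec)
        assert float(loss.data) == pytest.approx(np.log(4.0), rel=1e-12)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(5, 4))
        y = rng.integers(0, 4, size=5)
        w = rng.uniform(0.5, 2.0, size=4)
        l1 = float(weighted_cross_entropy(logits, y, LossSpec(weights=w)).data)
        l2 = float(weighted_cross_entropy(logits, y, LossSpec(weights=2 * w)).data)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_uniform_weights_equal_standard_cross_entropy(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(6, 5))
        y = rng.integers(0, 5, size=6)
        loss = float(weighted_cross_entropy(logits, y, LossSpec(weights=np.ones(5))).data)
        # reference: plain softmax cross-entropy
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        expected = -logp[np.arange(6), y].mean()
        assert loss == pytest.approx(expected, abs=1e-12)

    def test_non_finite_logits_rejected(self):
        with pytest.raises(FloatingPointError):
            weighted_cross_entropy(np.array([[np.nan, 0.0]]), np.array([0]),
                                   LossSpec(weights=np.ones(2)))


class TestOversampling:
    def test_balanced_labels_stay_balanced(self):
        labels = ["a"] * 50 + ["b"] * 50
        idx = oversample_indices(labels, seed=0, n_draws=10_000)
        freq_b = np.mean([labels[i] == "b" for i in idx])
        assert freq_b == pytest.approx(0.5, abs=0.02)

    def test_minority_class_upweighted_to_half(self):
        labels = ["a"] * 90 + ["b"] * 10
        idx = oversample_indices(labels, seed=1, n_draws=10_000)
        freq_b = np.mean([labels[i] == "b" for i in idx])
        assert freq_b == pytest.approx(0.5, abs=0.02)

    def test_deterministic_under_seed(self):
        labels = ["a"] * 5 + ["b"] * 15
        np.testing.assert_array_equal(
            oversample_indices(labels, seed=7), oversample_indices(labels, seed=7)
        )


class TestAugmentation:
    def test_zero_amplitude_is_identity(self, small_graphs):
        g = small_graphs[0]
        assert augment_translate(g, 0.0, seed=0) is g

    def test_displacement_bounded(self, small_graphs):
        g = small_graphs[0]
        g2 = augment_translate(g, 0.05, seed=3)
        disp = np.linalg.norm(g2.positions - g.positions, axis=1)
        assert disp.max() <= 0.05 + 1e-12
        np.testing.assert_array_equal(g2.edge_index, g.edge_index)  # edges kept


def _tiny_model(n_classes=2):
    cfg = ModelConfig(
        architecture="distances", n_classes=n_classes, n_node_types=21,
        embedding_dim=8, n_filters=8, n_interactions=1, n_rbf=8, cutoff=15.0,
        dropout=0.0,
    )
    return build_model(cfg, seed=0)


class TestTrainLoop:
    def test_patience_contract_on_frozen_validation(self, small_graphs):
        """Constant labels freeze accuracy at 1 -> stop after patience+1 stale epochs."""
        import dataclasses

        graphs = [dataclasses.replace(g, label=0) for g in small_graphs[:8]]
        val = [dataclasses.replace(g, label=0) for g in small_graphs[8:12]]
        model = _tiny_model()
        hist = train_model(model, graphs, val, TrainConfig(patience=2, max_epochs=50, seed=0))
        assert len(hist) == 2 + 2  # first epoch improves; then patience+1 stale

    def test_reproducible_history_under_seed(self, small_graphs):
        import dataclasses

        graphs = [dataclasses.replace(g, label=g.label) for g in small_graphs[:12]]
        h1 = train_model(_tiny_model(4), graphs, None, TrainConfig(max_epochs=3, seed=5))
        h2 = train_model(_tiny_model(4), graphs, None, TrainConfig(max_epochs=3, seed=5))
        assert h1 == h2

    def test_requires_labels_and_disjoint_validation(self, small_graphs):
        import dataclasses

        unlabeled = [dataclasses.replace(small_graphs[0], label=None)]
        with pytest.raises(ValueError, match="label"):
            train_model(_tiny_model(), unlabeled, None, TrainConfig(max_epochs=1))
        labeled = [dataclasses.replace(g, label=0) for g in small_graphs[:4]]
        with pytest.raises(ValueError, match="disjoint"):
            train_model(_tiny_model(), labeled, labeled, TrainConfig(max_epochs=1))


class TestProteinCentricF1:
    def test_all_correct_is_one(self):
        out = protein_centric_f1([("1.1", 1.0)] * 4, ["1.1"] * 4)
        assert out["fmax"] == 1.0
        assert out["f1"] == 1.0

    def test_all_wrong_is_zero(self):
        out = protein_centric_f1([("1.1", 1.0)] * 4, ["2.2"] * 4)
        assert out["fmax"] == 0.0
        assert out["f1"] == 0.0

    def test_threshold_sweep_hand_example(self):
        """2 correct at conf .9/.8, 1 wrong at .99; grid {0, .85, .95}."""
        preds = [("A", 0.9), ("B", 0.8), ("C", 0.99)]
        truths = ["A", "B", "X"]
        out = protein_centric_f1(preds, truths, thresholds=np.array([0.0, 0.85, 0.95]))
        # t=0: P=2/3, R=2/3 -> F=2/3;  t=.85: P=1/2, R=1/3 -> F=0.4;  t=.95: P=0 -> F=0
        assert out["fmax"] == pytest.approx(2 / 3)
        assert out["threshold"] == 0.0
        assert out["f1"] == pytest.approx(2 / 3)


class TestAUPR:
    def test_perfect_separation(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        aupr, macro = per_class_aupr(scores, [0, 0, 1, 1])
        assert aupr[0] == pytest.approx(1.0)
        assert aupr[1] == pytest.approx(1.0)
        assert macro == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(2)
        n = 4000
        truths = (rng.random(n) < 0.2).astype(int)
        scores = rng.random((n, 2))
        aupr, _ = per_class_aupr(scores, truths)
        assert aupr[1] == pytest.approx(0.2, abs=0.03)

    def test_six_sample_hand_example(self):
        # class-1 scores .9 .8 .6 .4 .3 .1 with positives at ranks 1,2,5
        scores = np.array([.9, .8, .6, .4, .3, .1])
        truths = np.array([1, 1, 0, 0, 1, 0])
        expected = (1 / 3) * 1.0 + (1 / 3) * 1.0 + (1 / 3) * (3 / 5)
        aupr, _ = per_class_aupr(np.stack([1 - scores, scores], axis=1), truths)
        assert aupr[1] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_reference_implementation(self, seed):
        """Step-interpolated AUPR equals sklearn average precision."""
        rng = np.random.default_rng(seed)
        n, c = 30, 3
        scores = rng.random((n, c))
        truths = rng.integers(0, c, size=n)
        aupr, _ = per_class_aupr(scores, truths)
        for cls, val in aupr.items():
            ref = average_precision_score((truths == cls).astype(int), scores[:, cls])
            assert val == pytest.approx(ref, abs=1e-12)

    def test_absent_class_excluded(self):
        scores = np.random.default_rng(3).random((5, 3))
        aupr, _ = per_class_aupr(scores, [0, 0, 1, 1, 0])
        assert 2 not in aupr


@pytest.mark.parametrize("seed", range(10))
def test_hard_label_f1_agrees_with_reference(seed):
    rng = np.random.default_rng(seed)
    truths = rng.integers(0, 3, size=40)
    preds = rng.integers(0, 3, size=40)
    out = protein_centric_f1([(str(p), 1.0) for p in preds], [str(t) for t in truths])
    ref = f1_score(truths, preds, average="micro")
    assert out["f1"] == pytest.approx(ref, abs=1e-12)
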