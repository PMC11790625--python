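"""GNN architectures, autodiff gradients, training loop, and metrics."""

import numpy as np
import pytest

from variantkg.gnn import (
    ARCHITECTURES,
    TrainConfig,
    confusion_matrix,
    evaluate,
    init_model,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)
from variantkg.gnn._autodiff import Tensor
from variantkg.graph_build import GraphConfig, LearningGraph, build_edges, split_masks

from ._oracles import oracle_metrics


def toy_graph(n=60, d=6, num_classes=3, seed=0, informative=True, clique_by_label=True):
    """Small graph whose first feature column carries the label signal.

    With ``clique_by_label`` the gene cliques are label-pure (structure
    alone solves the task); without it cliques are label-mixed, so a
    model must rely on the informative feature column.
    """
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, num_classes, size=n)
    X = rng.normal(size=(n, d)).astype(np.float32)
    if informative:
        X[:, 0] = labels * 2.0 + rng.normal(scale=0.3, size=n)
    if clique_by_label:
        genes = [f"G{labels[i]}_{i % 4}" for i in range(n)]
    else:
        genes = [f"G{i % 10}" for i in range(n)]
    edges, weights = build_edges(genes, GraphConfig(seed=seed))
    train_m, val_m, test_m = split_masks(n, 0.6, 0.2, seed)
    return LearningGraph(
        num_nodes=n,
        node_features=X,
        labels=labels,
        edges=edges,
        weights=weights,
        train_mask=train_m,
        val_mask=val_m,
        test_mask=test_m,
        encoders={},
        scalers={},
        label_names=[str(c) for c in range(num_classes)],
        feature_names=[f"f{j}" for j in range(d)],
    )


class TestModels:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_logit_shape_contract(self, arch):
        g = toy_graph(n=5)
        model = init_model(arch, 6, 4, TrainConfig(arch=arch, seed=0))
        logits = model.forward(g.node_features, g.edges, g.weights)
        assert logits.value.shape == (5, 4)

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_same_seed_identical_initial_parameters(self, arch):
        config = TrainConfig(arch=arch, seed=3)
        a = init_model(arch, 6, 4, config)
        b = init_model(arch, 6, 4, config)
        assert all(np.array_equal(p.value, q.value) for p, q in zip(a.params, b.params))

    def test_gcn_without_edges_reduces_to_per_node_network(self):
        """With only self-loops, graph convolution must equal a plain
        feed-forward network sharing the same weights."""
        n, d, c = 7, 5, 3
        rng = np.random.default_rng(1)
        X = rng.normal(size=(n, d)).astype(np.float32)
        loops = np.stack([np.arange(n), np.arange(n)], axis=1)
        model = init_model("gcn", d, c, TrainConfig(arch="gcn", seed=2))
        logits = model.forward(X, loops, np.ones(n)).value
        h = X
        for i, (w, b) in enumerate(model.layers):
            h = h @ w.value + b.value
            if i < len(model.layers) - 1:
                h = np.maximum(h, 0)
        assert logits == pytest.approx(h, abs=1e-5)

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_autodiff_gradients_match_finite_differences(self, arch):
        g = toy_graph(n=12, d=4)
        model = init_model(arch, 4, 3, TrainConfig(arch=arch, seed=0, hidden_dim=4, num_heads=2))
        idx = np.arange(6)

        def loss_value():
            from variantkg.gnn.train import cross_entropy

            logits = model.forward(g.node_features, g.edges, g.weights)
            return cross_entropy(logits, g.labels, idx)

        loss = loss_value()
        for p in model.params:
            p.grad = None
        loss.backward()
        rng = np.random.default_rng(0)
        for p in model.params[:4]:
            flat = p.value.ravel()
            for _ in range(3):
                j = rng.integers(flat.size)
                eps = 1e-2
                orig = flat[j]
                flat[j] = orig + eps
                up = float(loss_value().value)
                flat[j] = orig - eps
                down = float(loss_value().value)
                flat[j] = orig
                numeric = (up - down) / (2 * eps)
                analytic = float(p.grad.ravel()[j]) if p.grad is not None else 0.0
                assert analytic == pytest.approx(numeric, abs=5e-2, rel=0.1)

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_forward_is_permutation_equivariant(self, arch):
        g = toy_graph(n=20)
        model = init_model(arch, 6, 3, TrainConfig(arch=arch, seed=0))
        logits = model.forward(g.node_features, g.edges, g.weights).value
        perm = np.random.default_rng(9).permutation(g.num_nodes)
        inv = np.argsort(perm)
        perm_edges = inv[g.edges]
        perm_logits = model.forward(
            g.node_features[perm], perm_edges, g.weights
        ).value
        assert perm_logits == pytest.approx(logits[perm], abs=1e-4)


class TestTraining:
    def test_single_epoch_history_length(self):
        g = toy_graph()
        config = TrainConfig(arch="gcn", epochs=1, seed=0)
        _, history = train(init_model("gcn", 6, 3, config), g, config)
        assert len(history.train_loss) == len(history.val_loss) == len(history.val_accuracy) == 1

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        g = toy_graph()
        config = TrainConfig(arch="graphsage", epochs=1, learning_rate=0.0, dropout=0.0, seed=0)
        model = init_model("graphsage", 6, 3, config)
        before = [p.value.copy() for p in model.params]
        train(model, g, config)
        assert all(np.array_equal(b, p.value) for b, p in zip(before, model.params))

    def test_training_loss_finite_every_epoch(self):
        g = toy_graph()
        config = TrainConfig(arch="gcn", epochs=30, seed=0)
        _, history = train(init_model("gcn", 6, 3, config), g, config)
        assert np.isfinite(history.train_loss).all()

    def test_same_seed_reproduces_trajectory(self):
        g = toy_graph()
        config = TrainConfig(arch="gcn", epochs=10, seed=5)
        _, h1 = train(init_model("gcn", 6, 3, config), g, config)
        _, h2 = train(init_model("gcn", 6, 3, config), g, config)
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_learns_planted_signal_above_majority(self, arch):
        g = toy_graph(n=120, seed=2)
        majority = np.bincount(g.labels).max() / g.num_nodes
        config = TrainConfig(arch=arch, epochs=150, seed=0)
        _, history = train(init_model(arch, 6, 3, config), g, config)
        assert history.val_accuracy[-1] >= majority + 0.2

    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path):
        g = toy_graph()
        config = TrainConfig(arch="graphsage", epochs=20, seed=0)
        model, _ = train(init_model("graphsage", 6, 3, config), g, config)
        save_checkpoint(model, config, tmp_path / "ckpt.pkl")
        loaded, _ = load_checkpoint(tmp_path / "ckpt.pkl", 6, 3)
        assert np.array_equal(predict(model, g), predict(loaded, g))


class TestMetrics:
    def test_perfect_predictions(self):
        g = toy_graph()
        labels = g.labels

        class Oracle:
            def forward(self, x, e, w, **kw):
                onehot = np.zeros((len(labels), 3))
                onehot[np.arange(len(labels)), labels] = 10.0
                return Tensor(onehot)

        metrics = evaluate(Oracle(), g, g.test_mask)
        assert metrics.accuracy == 1.0
        assert metrics.macro_f1 == pytest.approx(1.0)

    def test_matches_counting_oracle_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            num_classes = int(rng.integers(2, 5))
            n = int(rng.integers(5, 60))
            y_true = rng.integers(0, num_classes, n)
            y_pred = rng.integers(0, num_classes, n)
            expected = oracle_metrics(y_true, y_pred, num_classes)
            cm = confusion_matrix(y_true, y_pred, num_classes)
            assert np.array_equal(cm, expected["confusion"])
            from sklearn.metrics import precision_recall_fscore_support

            prec, rec, f1, support = precision_recall_fscore_support(
                y_true, y_pred, labels=np.arange(num_classes), zero_division=0
            )
            assert prec == pytest.approx(expected["precision"])
            assert rec == pytest.approx(expected["recall"])
            assert f1 == pytest.approx(expected["f1"])
            assert np.array_equal(support, expected["support"])

    def test_confusion_matrix_hand_counted(self):
        cm = confusion_matrix([0, 0, 1], [1, 0, 1], 2)
        assert cm.tolist() == [[1, 1], [0, 1]]

    def test_confusion_matrix_identity_and_empty(self):
        assert confusion_matrix([0, 1], [0, 1], 2).tolist() == [[1, 0], [0, 1]]
        assert confusion_matrix([], [], 3).tolist() == np.zeros((3, 3)).tolist()

    def test_confusion_matrix_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            confusion_matrix([0, 5], [0, 1], 2)

    def test_confusion_row_sums_equal_support(self):
        g = toy_graph()
        config = TrainConfig(arch="gcn", epochs=5, seed=0)
        model, _ = train(init_model("gcn", 6, 3, config), g, config)
        metrics = evaluate(model, g, g.test_mask)
        assert metrics.confusion.sum(axis=1).tolist() == metrics.support.tolist()
        assert metrics.accuracy == pytest.approx(
            metrics.confusion.trace() / metrics.confusion.sum()
        )
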