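"""Network construction, training behavior, metrics and Hand-Till AUC."""

import numpy as np
import pytest

import spotgin as sg
from spotgin.gnn import GinConfig, HeadSpec, _pairwise_rank_auc
from spotgin.graphs import Subgraph
from spotgin.nn import cross_entropy, mse_l1, softmax


def make_subgraph(features, label, edges=None, participant="p0"):
    n = len(features)
    if edges is None:
        rows = list(range(n)) + [i for i in range(n - 1)] + \
            [i + 1 for i in range(n - 1)]
        cols = list(range(n)) + [i + 1 for i in range(n - 1)] + \
            [i for i in range(n - 1)]
        edges = np.array([rows, cols])
    return Subgraph(center="c", k=1, nodes=[f"n{i}" for i in range(n)],
                    edge_index=edges, features=np.asarray(features, float),
                    labels={"task": label}, participant=participant)


def toy_task(rng, n=60, n_nodes=5, separation=3.0):
    """Binary task: class decided by the mean node feature level."""
    subs = []
    for i in range(n):
        label = "A" if i % 2 == 0 else "B"
        shift = 0.0 if label == "A" else separation
        feats = rng.normal(shift, 1.0, size=(n_nodes, 4))
        subs.append(make_subgraph(feats, label))
    return subs


HEAD = HeadSpec("task", classes=["A", "B"])


class TestModelConstruction:
    def test_same_seed_identical_parameters(self):
        cfg = GinConfig(hidden_dim=16, heads=[HEAD], seed=5, epochs=1)
        m1 = sg.init_model(cfg, 4)
        m2 = sg.init_model(cfg, 4)
        for p1, p2 in zip(m1.params(), m2.params()):
            assert np.array_equal(p1.value, p2.value)

    def test_head_count_matches_config(self):
        heads = [HEAD, HeadSpec("other", classes=["x", "y", "z"])]
        model = sg.init_model(GinConfig(hidden_dim=8, heads=heads), 4)
        assert set(model.heads) == {"task", "other"}

    def test_forward_returns_logits_per_task(self, rng):
        model = sg.init_model(GinConfig(hidden_dim=8, heads=[HEAD]), 4)
        out = model.forward([make_subgraph(rng.normal(size=(37, 4)), "A")])
        assert out["task"].shape == (1, 2)

    def test_k0_builds_linear_baseline(self):
        model = sg.init_model(GinConfig(hidden_dim=8, heads=[HEAD], k=0), 4)
        assert model.is_linear and not model.gin_layers

    def test_permutation_equivariance(self, rng):
        model = sg.init_model(GinConfig(hidden_dim=16, heads=[HEAD],
                                        dropout_p=0.0, seed=1), 4)
        sub = make_subgraph(rng.normal(size=(9, 4)), "A")
        out1 = model.forward([sub])["task"]
        perm = rng.permutation(9)
        inv = np.argsort(perm)
        permuted = Subgraph(center=sub.center, k=1,
                            nodes=[sub.nodes[i] for i in perm],
                            edge_index=np.vectorize(lambda v: inv[v])(
                                sub.edge_index),
                            features=sub.features[perm], labels=sub.labels)
        out2 = model.forward([permuted])["task"]
        assert np.allclose(out1, out2, atol=1e-5)


class TestTraining:
    def test_overfits_small_batch(self, rng):
        subs = toy_task(rng, n=32, separation=1.5)
        cfg = GinConfig(hidden_dim=16, dropout_p=0.0, epochs=200, lr=1e-2,
                        batch_size=32, seed=0, heads=[HEAD])
        model = sg.init_model(cfg, 4)
        sg.train(model, subs, cfg)
        pred = sg.predicted_classes(sg.predict(model, subs)["task"],
                                    HEAD.classes)
        truth = [s.labels["task"] for s in subs]
        assert (pred == np.array(truth, dtype=object)).mean() == 1.0

    def test_loss_history_decreases_smoothed(self, rng):
        subs = toy_task(rng, n=64)
        cfg = GinConfig(hidden_dim=16, dropout_p=0.1, epochs=30, lr=1e-3,
                        batch_size=16, seed=0, heads=[HEAD])
        model = sg.init_model(cfg, 4)
        history = np.array(sg.train(model, subs, cfg))
        smoothed = np.convolve(history, np.ones(10) / 10, mode="valid")
        assert (np.diff(smoothed) <= 1e-6).all()

    def test_seeded_training_reproducible(self, rng):
        subs = toy_task(rng, n=24)
        cfg = GinConfig(hidden_dim=8, epochs=5, seed=9, batch_size=8,
                        heads=[HEAD])
        runs = []
        for _ in range(2):
            model = sg.init_model(cfg, 4)
            sg.train(model, subs, cfg)
            runs.append(sg.predict(model, subs)["task"])
        assert np.array_equal(runs[0], runs[1])

    def test_single_class_task_rejected(self, rng):
        subs = [make_subgraph(rng.normal(size=(3, 4)), "A")] * 8
        cfg = GinConfig(hidden_dim=8, epochs=1, heads=[HEAD])
        model = sg.init_model(cfg, 4)
        with pytest.raises(ValueError, match="fewer than two classes"):
            sg.train(model, subs, cfg)

    def test_unknown_labels_masked_not_crashing(self, rng):
        subs = toy_task(rng, n=16)
        for s in subs[:4]:
            s.labels["task"] = "unknown"
        cfg = GinConfig(hidden_dim=8, epochs=3, heads=[HEAD], batch_size=8)
        model = sg.init_model(cfg, 4)
        history = sg.train(model, subs, cfg)
        assert np.isfinite(history).all()

    def test_uncertainty_weighting_trains_and_balances(self, rng):
        subs = toy_task(rng, n=48, separation=2.0)
        cfg = GinConfig(hidden_dim=16, dropout_p=0.0, epochs=60, lr=1e-2,
                        batch_size=16, seed=2, heads=[HEAD],
                        uncertainty_weighting=True)
        model = sg.init_model(cfg, 4)
        history = sg.train(model, subs, cfg)
        assert np.isfinite(history).all()
        pred = sg.predicted_classes(sg.predict(model, subs)["task"],
                                    HEAD.classes)
        truth = np.array([s.labels["task"] for s in subs], dtype=object)
        assert (pred == truth).mean() >= 0.95

    def test_continuous_head_trains(self, rng):
        head = HeadSpec("task", kind="continuous", dim=1)
        subs = []
        for i in range(32):
            level = rng.normal()
            feats = np.full((4, 3), level) + rng.normal(0, 0.05, size=(4, 3))
            subs.append(make_subgraph(feats, None))
            subs[-1].labels = {"task": level}
        cfg = GinConfig(hidden_dim=16, dropout_p=0.0, epochs=150, lr=1e-2,
                        batch_size=32, seed=0, heads=[head])
        model = sg.init_model(cfg, 3)
        history = sg.train(model, subs, cfg)
        assert history[-1] < 0.25 * history[0]


class TestLossFunctions:
    def test_cross_entropy_gradient_direction(self):
        logits = np.array([[2.0, -2.0]])
        loss, grad = cross_entropy(logits, np.array([1]))
        assert loss > 1.0
        assert grad[0, 1] < 0 < grad[0, 0]

    def test_mse_l1_zero_at_target(self):
        loss, grad = mse_l1(np.array([[1.0]]), np.array([[1.0]]))
        assert loss == 0.0 and np.allclose(grad, 0.0)

    def test_masked_items_get_zero_gradient(self):
        logits = np.array([[1.0, 0.0], [0.0, 1.0]])
        mask = np.array([True, False])
        _, grad = cross_entropy(logits, np.array([0, 0]), mask)
        assert np.allclose(grad[1], 0.0)


class TestParticipantVote:
    def test_majority_vote_fraction(self):
        logits = np.zeros((10, 2))
        logits[:7, 0] = 5.0
        logits[7:, 1] = 5.0
        table = sg.predict_participant(logits, ["A", "B"], ["p"] * 10)
        assert table.loc["p", "predicted"] == "A"
        assert table.loc["p", "vote_fraction"] == pytest.approx(0.7)

    def test_tie_broken_by_mean_softmax(self):
        logits = np.zeros((10, 2))
        logits[:5, 0] = 1.0   # five modest votes for A
        logits[5:, 1] = 4.0   # five confident votes for B
        table = sg.predict_participant(logits, ["A", "B"], ["p"] * 10)
        assert table.loc["p", "predicted"] == "B"

    def test_vote_fractions_sum_to_one(self, rng):
        logits = rng.normal(size=(30, 3))
        parts = list(rng.choice(["p1", "p2"], size=30))
        table = sg.predict_participant(logits, ["A", "B", "C"], parts)
        for fracs in table["fractions"]:
            assert np.isclose(sum(fracs), 1.0)


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = ["A", "B", "A", "B"]
        rep = sg.evaluate(truth, truth, ["A", "B"])
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0
        assert np.array_equal(np.diag(rep.confusion), [2, 2])

    def test_all_one_class_on_balanced_truth(self):
        truth = ["A", "B"] * 10
        pred = ["A"] * 20
        rep = sg.evaluate(pred, truth, ["A", "B"])
        assert rep.accuracy == 0.5
        assert rep.f1 == pytest.approx(1 / 3)

    def test_matches_counting_oracle(self, rng):
        classes = ["A", "B", "C"]
        truth = rng.choice(classes, size=200)
        pred = rng.choice(classes, size=200)
        rep = sg.evaluate(pred, truth, classes)
        precisions, recalls = [], []
        for c in classes:
            tp = ((pred == c) & (truth == c)).sum()
            fp = ((pred == c) & (truth != c)).sum()
            fn = ((pred != c) & (truth == c)).sum()
            precisions.append(tp / (tp + fp) if tp + fp else 0.0)
            recalls.append(tp / (tp + fn) if tp + fn else 0.0)
        assert rep.precision == pytest.approx(np.mean(precisions))
        assert rep.recall == pytest.approx(np.mean(recalls))
        assert rep.confusion.to_numpy().sum(axis=1).tolist() == \
            [(truth == c).sum() for c in classes]


class TestHandTill:
    def test_separable_three_class(self):
        scores = np.eye(3).repeat(4, axis=0) * 10
        truth = np.repeat([0, 1, 2], 4)
        assert sg.hand_till_auc(scores, truth, classes=[0, 1, 2]) == 1.0

    def test_identical_scores_give_half(self):
        scores = np.ones((12, 3))
        truth = np.repeat([0, 1, 2], 4)
        assert sg.hand_till_auc(scores, truth, classes=[0, 1, 2]) == 0.5

    def test_two_class_matches_all_pairs_oracle(self, rng):
        scores = rng.normal(size=(200, 2))
        truth = rng.choice([0, 1], size=200)
        m = sg.hand_till_auc(scores, truth, classes=[0, 1])
        pos = scores[truth == 1]
        neg = scores[truth == 0]
        a_1_0 = np.mean((pos[:, None, 1] > neg[None, :, 1])
                        + 0.5 * (pos[:, None, 1] == neg[None, :, 1]))
        a_0_1 = np.mean((neg[:, None, 0] > pos[None, :, 0])
                        + 0.5 * (neg[:, None, 0] == pos[None, :, 0]))
        assert m == pytest.approx((a_1_0 + a_0_1) / 2, abs=1e-12)

    def test_matches_sklearn_ovo(self, rng):
        from sklearn.metrics import roc_auc_score
        logits = rng.normal(size=(300, 3))
        probs = softmax(logits)
        truth = rng.choice([0, 1, 2], size=300, p=[0.5, 0.3, 0.2])
        ours = sg.hand_till_auc(probs, truth, classes=[0, 1, 2])
        theirs = roc_auc_score(truth, probs, multi_class="ovo")
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_empty_class_excluded(self):
        scores = np.array([[0.9, 0.1, 0.0], [0.2, 0.8, 0.0],
                           [0.8, 0.2, 0.0], [0.1, 0.9, 0.0]])
        truth = np.array([0, 1, 0, 1])
        assert sg.hand_till_auc(scores, truth, classes=[0, 1, 2]) == 1.0

    def test_pairwise_rank_auc_midranks(self):
        assert _pairwise_rank_auc(np.array([1.0, 1.0]),
                                  np.array([1.0])) == 0.5
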