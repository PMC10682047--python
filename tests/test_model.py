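"""2D-SFE architecture, schedule, optimizer, losses and training behavior."""

import math

import numpy as np
import pytest

import larynet as ln
from larynet import model as M
from larynet.preprocess import assemble_dataset, default_split


class TestArchitecture:
    def test_layer_census_default(self):
        net = M.build_model(M.ModelConfig(n_classes=13), seed=0)
        census = net.layer_census()
        assert census["processing"] == 62
        assert census["classifying"] == 2
        assert census["weight_blocks"] == 8

    def test_inconsistent_layer_accounting_rejected(self):
        with pytest.raises(ValueError, match="layer accounting"):
            M.ModelConfig(n_classes=13, block_convs=(1,) * 8)

    def test_block_channel_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="one width per block"):
            M.ModelConfig(n_classes=13, channels_per_block=(8, 8))

    def test_probabilities_normalized_on_zero_input(self):
        net = M.build_model(M.ModelConfig(n_classes=13), seed=0)
        _, probs = net.forward(np.zeros((3, 4, 1000), dtype=np.float32))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_initialization_reproducible(self):
        a = M.build_model(M.ModelConfig(n_classes=13), seed=5)
        b = M.build_model(M.ModelConfig(n_classes=13), seed=5)
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.all_params, b.all_params))
        c = M.build_model(M.ModelConfig(n_classes=13), seed=6)
        assert not all(np.array_equal(x, y)
                       for x, y in zip(a.all_params, c.all_params))

    def test_feature_vectors_unit_norm(self, rng):
        net = M.build_model(M.ModelConfig(n_classes=13), seed=0)
        emb = net.embed(rng.standard_normal((4, 4, 1000)).astype(np.float32))
        assert np.allclose(np.linalg.norm(emb, axis=1), 1.0, atol=1e-5)

    def test_wrong_window_shape_rejected(self):
        net = M.build_model(M.ModelConfig(n_classes=13), seed=0)
        with pytest.raises(ValueError, match="expected windows"):
            net.embed(np.zeros((2, 4, 999), dtype=np.float32))


class TestLrSchedule:
    def test_printed_form_matches_direct_evaluation(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            x = float(rng.uniform(0, 200))
            epochs = int(rng.integers(1, 300))
            ilr = float(10 ** rng.uniform(-6, -1))
            cfg = M.LRScheduleConfig(iLR=ilr, epochs=epochs, mode="as_printed")
            expected = (1.0 + 0.5 * math.cos(x + math.pi / epochs)) * (1.0 - ilr)
            assert M.lr_schedule(x, cfg) == pytest.approx(expected, abs=0, rel=1e-15)

    def test_printed_form_reference_point(self):
        cfg = M.LRScheduleConfig(iLR=1e-4, epochs=100, mode="as_printed")
        assert M.lr_schedule(0.0, cfg) == pytest.approx(1.4996, abs=2e-4)
        x = math.pi / 2 - math.pi / 100
        assert M.lr_schedule(x, cfg) == pytest.approx(1.0 - 1e-4, rel=1e-12)

    def test_cosine_annealing_endpoints(self):
        cfg = M.LRScheduleConfig(iLR=1e-4, epochs=100, mode="cosine_annealing")
        assert M.lr_schedule(0, cfg) == pytest.approx(1e-4)
        assert M.lr_schedule(100, cfg) == pytest.approx(0.0, abs=1e-20)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            M.LRScheduleConfig(iLR=0.0)
        with pytest.raises(ValueError):
            M.LRScheduleConfig(mode="linear")
        with pytest.raises(ValueError):
            M.lr_schedule(-1, M.LRScheduleConfig())


class TestOptimizer:
    def test_zero_gradient_is_a_no_op(self):
        state = M.OptimizerState()
        p = np.array([1.0, -2.0])
        M.optimizer_step(state, [p], [np.zeros(2)], lr=0.1)
        assert np.array_equal(p, [1.0, -2.0])
        assert state.ar == 0.9
        assert np.all(state.m[0] == 0) and np.all(state.v[0] == 0)

    def test_first_step_unit_gradient_moves_by_lr(self):
        # symbolic substitution: m_hat = v_hat = 1, delta = lr / (eps + 1)
        state = M.OptimizerState(beta1=0.9, beta2=0.999, eps=1e-8)
        p = np.array([0.0])
        M.optimizer_step(state, [p], [np.array([1.0])], lr=1e-3)
        assert p[0] == pytest.approx(-1e-3 / (1e-8 + 1.0), rel=1e-12)
        assert state.ar == pytest.approx(0.9 - 1e-3 / (1e-8 + 1.0), rel=1e-9)

    def test_moment_approaches_gradient_geometrically(self):
        state = M.OptimizerState(beta1=0.9)
        p = np.array([0.0])
        g = np.array([2.0])
        prev = 0.0
        for t in range(1, 6):
            M.optimizer_step(state, [p], [g.copy()], lr=0.0)
            m = state.m[0][0]
            assert m == pytest.approx(2.0 * (1 - 0.9**t), rel=1e-12)
            assert prev < m < 2.0
            prev = m

    def test_non_finite_gradient_rejected(self):
        state = M.OptimizerState()
        with pytest.raises(ValueError, match="non-finite"):
            M.optimizer_step(state, [np.zeros(1)], [np.array([np.nan])], lr=0.1)

    def test_quadratic_convergence(self):
        # minimize 0.5 * ||p - target||^2
        state = M.OptimizerState()
        target = np.array([3.0, -1.5, 0.25])
        p = np.zeros(3)
        for _ in range(500):
            M.optimizer_step(state, [p], [p - target], lr=0.05)
        assert np.abs(p - target).max() < 1e-3


class TestLosses:
    def test_triplet_zero_when_negative_far(self):
        a = np.array([[0.0, 0.0]])
        n = np.array([[5.0, 0.0]])
        assert M.triplet_loss(a, a, n, margin=1.0) == 0.0

    def test_triplet_equals_margin_when_degenerate(self):
        a = np.array([[1.0, 2.0]])
        assert M.triplet_loss(a, a, a, margin=0.7) == pytest.approx(0.7)

    def test_triplet_hand_example(self):
        a, p, n = np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]]), np.array(
            [[0.0, 3.0]])
        assert M.triplet_loss(a, p, n, margin=1.0) == 0.0
        assert M.triplet_loss(a, p, n, margin=3.0) == pytest.approx(1.0)

    def test_triplet_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share a shape"):
            M.triplet_loss(np.zeros((1, 2)), np.zeros((1, 3)), np.zeros((1, 2)))

    def test_cross_entropy_uniform_closed_forms(self):
        u13 = np.full((1, 13), 1 / 13)
        t13 = M.one_hot([4], 13)
        assert M.cross_entropy_loss(u13, t13) == pytest.approx(np.log(13),
                                                               rel=1e-12)
        u4 = np.full((1, 4), 0.25)
        t4 = M.one_hot([0], 4)
        assert M.cross_entropy_loss(u4, t4) == pytest.approx(np.log(4), rel=1e-12)

    def test_cross_entropy_perfect_prediction_near_zero(self):
        t = M.one_hot([1, 0], 2)
        assert M.cross_entropy_loss(t, t) < 1e-9

    def test_cross_entropy_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            M.cross_entropy_loss(np.full((1, 3), 1 / 3), M.one_hot([0], 4))


@pytest.fixture(scope="module")
def small4_dataset():
    kinds = ("pinyin1", "vowel3", "swallow", "cough")
    cohort = ln.synthesize_cohort(5, classes=kinds, reps_per_class=2, seed=7,
                                  jitter_range=(0.0, 0.0))
    split = default_split(cohort, n_test=1)
    return assemble_dataset(cohort, {k: k for k in kinds}, split,
                            n_sequences=10, seed=7)


class TestTraining:
    def test_separable_four_class_accuracy(self, small4_dataset):
        res = ln.SFEClassifier(small4_dataset).fit(epochs=30, seed=7)
        assert res.test_accuracy >= 0.95
        assert len(res.history["lr"]) == 30
        # triplet geometry: intra-class < inter-class embedding distance
        X, y, _ = small4_dataset.tensors("heldout")
        emb = res.embed(X)
        d = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        same = y[:, None] == y[None, :]
        off = ~np.eye(len(y), dtype=bool)
        assert d[same & off].mean() < d[~same].mean()

    def test_training_loss_decreases(self, small4_dataset):
        res = ln.SFEClassifier(small4_dataset).fit(epochs=12, seed=3)
        h = res.history
        mix = 0.5 * h["triplet_loss"] + 0.5 * h["cross_entropy_loss"]
        assert mix[-1] <= mix[0]

    def test_deterministic_trajectories(self, small4_dataset):
        r1 = ln.SFEClassifier(small4_dataset).fit(epochs=3, seed=11)
        r2 = ln.SFEClassifier(small4_dataset).fit(epochs=3, seed=11)
        assert np.array_equal(r1.history["cross_entropy_loss"],
                              r2.history["cross_entropy_loss"])
        assert all(np.array_equal(a, b) for a, b in
                   zip(r1.network.state_arrays(), r2.network.state_arrays()))

    def test_single_class_dataset_rejected(self):
        cohort = ln.synthesize_cohort(2, classes=("swallow",), reps_per_class=2,
                                      seed=0)
        ds = assemble_dataset(cohort, {"swallow": "swallow"},
                              default_split(cohort, 1), n_sequences=3, seed=0)
        with pytest.raises(ValueError, match="single class"):
            ln.SFEClassifier(ds).fit(epochs=1, seed=0)

    def test_summary_reports_census_and_accuracy(self, small4_dataset):
        res = ln.SFEClassifier(small4_dataset).fit(epochs=2, seed=0)
        text = res.summary()
        assert "processing layers:   62" in text
        assert "classifying layers:  2" in text
        assert "eval accuracy" in text


class TestPredictAdapt:
    def test_predict_shapes_and_normalization(self, small4_dataset, rng):
        res = ln.SFEClassifier(small4_dataset).fit(epochs=2, seed=0)
        X = rng.standard_normal((7, 4, 1000)).astype(np.float32)
        emb, probs, classes = res.predict(X)
        assert emb.shape == (7, 16) and probs.shape == (7, 4)
        assert classes.shape == (7,)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_prediction_order_preserved(self, small4_dataset):
        res = ln.SFEClassifier(small4_dataset).fit(epochs=2, seed=0)
        X, _, _ = small4_dataset.tensors("heldout")
        _, p_all, _ = res.predict(X[:10])
        _, p_one, _ = res.predict(X[3:4])
        assert np.allclose(p_all[3], p_one[0], atol=1e-6)

    def test_zero_epoch_adaptation_is_identity(self, small4_dataset):
        res = ln.SFEClassifier(small4_dataset).fit(epochs=2, seed=0)
        X, y, _ = small4_dataset.tensors("test")
        adapted = res.adapt(X[:8], y[:8], epochs_adapt=0)
        assert all(np.array_equal(a, b) for a, b in
                   zip(res.network.state_arrays(),
                       adapted.network.state_arrays()))

    def test_adaptation_freezes_extractor(self, small4_dataset):
        res = ln.SFEClassifier(small4_dataset).fit(epochs=2, seed=0)
        X, y, _ = small4_dataset.tensors("test")
        adapted = res.adapt(X, y, epochs_adapt=5, seed=1)
        before = res.network.extractor.params
        after = adapted.network.extractor.params
        assert all(np.array_equal(a, b) for a, b in zip(before, after))
        # ... while the head did move
        assert not all(np.array_equal(a, b) for a, b in
                       zip(res.network.head.params, adapted.network.head.params))

    def test_unseen_class_labels_rejected(self, small4_dataset):
        res = ln.SFEClassifier(small4_dataset).fit(epochs=2, seed=0)
        X, _, _ = small4_dataset.tensors("test")
        with pytest.raises(ValueError, match="class"):
            res.adapt(X[:4], np.array([0, 1, 2, 9]), epochs_adapt=1)
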