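"""Optimizer schedule, training loop, prediction and cross-validation."""

import numpy as np
import pandas as pd
import pytest

import tinyseg as ts
from tinyseg.training import _backward, _forward_tape, _loss_and_grad


class TestLrSchedule:
    def test_staircase_values(self):
        cfg = ts.TrainConfig()
        assert ts.lr_schedule(0, cfg) == pytest.approx(1e-3)
        assert ts.lr_schedule(800, cfg) == pytest.approx(9.6e-4)
        assert ts.lr_schedule(1599, cfg) == pytest.approx(9.6e-4)
        assert ts.lr_schedule(1600, cfg) == pytest.approx(1e-3 * 0.96 ** 2)

    def test_constant_within_windows(self):
        cfg = ts.TrainConfig()
        rates = {ts.lr_schedule(s, cfg) for s in range(800)}
        assert rates == {1e-3}


class TestGradients:
    def test_backward_matches_finite_differences(self, toy_quarter, rng):
        """Analytic gradients vs central differences on random weights."""
        toy_quarter.initialize(rng)
        x = rng.random((2, 16, 16, 1), dtype=np.float32)
        y = (rng.random((2, 16, 16)) < 0.05).astype(np.float32)
        y[:, 8, 8] = 1
        logits, tape, _ = _forward_tape(toy_quarter, x)
        _, dz = _loss_and_grad(y, logits)
        grads = _backward(toy_quarter, tape, dz)

        def loss_now():
            lg, _, _ = _forward_tape(toy_quarter, x)
            return _loss_and_grad(y, lg)[0]

        for nid in ("stem", "enc1/mrb/m1", "rp0/rep3/conv1", "out"):
            kernel = toy_quarter.node(nid).conv.kernel
            idx = tuple(rng.integers(0, s) for s in kernel.shape)
            orig = kernel[idx]
            kernel[idx] = orig + 1e-3
            up = loss_now()
            kernel[idx] = orig - 1e-3
            down = loss_now()
            kernel[idx] = orig
            numeric = (up - down) / 2e-3
            analytic = grads[nid][0][idx]
            assert analytic == pytest.approx(numeric, rel=0.03, abs=0.05)


class TestTrain:
    @staticmethod
    def tiny_data(rng, n=6, size=16):
        X, Y = ts.synth_dataset(n, ts.SceneConfig(
            size=size, particle_count=(1, 2),
            particle_diameter=(3, 4), max_foreground_fraction=0.2), rng)
        return X, Y.astype(np.float32)

    def test_zero_epochs_keeps_initialization(self, toy_quarter, rng):
        X, Y = self.tiny_data(rng)
        tm = ts.train(toy_quarter, X, Y, ts.TrainConfig(epochs=0, seed=3))
        reference = ts.build_model(
            "quarter_multiresunet",
            config={"stem": 5, "blocks": [6, 6], "respath": [4],
                    "decoder": [6]},
            input_shape=(16, 16, 1)).initialize(np.random.default_rng(3))
        for node in tm.model.conv_nodes():
            np.testing.assert_array_equal(
                node.conv.kernel, reference.node(node.id).conv.kernel)

    def test_loss_converges_when_overfitting_one_sample(self, rng):
        X, Y = ts.synth_dataset(1, ts.SceneConfig(
            size=24, particle_count=(2, 2), particle_diameter=(4, 6),
            max_foreground_fraction=0.2), rng)
        X = np.repeat(X, 4, axis=0)
        Y = np.repeat(Y.astype(np.float32), 4, axis=0)
        m = ts.build_model(
            "quarter_multiresunet",
            config={"stem": 8, "blocks": [12, 12], "respath": [8],
                    "decoder": [12]},
            input_shape=(24, 24, 1))
        tm = ts.train(m, X, Y, ts.TrainConfig(epochs=150, seed=0,
                                              batch_size=4, initial_lr=5e-3))
        losses = tm.history["loss"].to_numpy()
        assert losses[-1] < 0.2 * losses[0]

    def test_same_seed_identical_history(self, rng):
        X, Y = self.tiny_data(rng)
        runs = []
        for _ in range(2):
            m = ts.build_model(
                "quarter_multiresunet",
                config={"stem": 5, "blocks": [6, 6], "respath": [4],
                        "decoder": [6]},
                input_shape=(16, 16, 1))
            tm = ts.train(m, X, Y, ts.TrainConfig(epochs=3, seed=11))
            runs.append(tm.history)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_empty_dataset_rejected(self, toy_quarter):
        with pytest.raises(ValueError):
            ts.train(toy_quarter, np.empty((0, 16, 16)), np.empty((0, 16, 16)))


class TestPredictMask:
    def test_zero_weight_model_predicts_nothing(self, toy_quarter, rng):
        """Sigmoid 0.5 everywhere fails the strict > 0.5 test."""
        toy_quarter.initialize(rng)
        for n in toy_quarter.conv_nodes():
            n.conv.kernel[:] = 0
            n.conv.bias[:] = 0
        mask = ts.predict_mask(toy_quarter, rng.random((16, 16, 1)))
        assert mask.dtype == bool and not mask.any()

    def test_single_pixel_above_threshold(self):
        prob = np.full((8, 8), 0.5)
        prob[3, 4] = 0.51
        assert ts.binarize(prob, 0.5).sum() == 1

    def test_threshold_sweep_monotone(self, rng):
        prob = rng.random((32, 32))
        counts = [ts.binarize(prob, t).sum()
                  for t in np.linspace(0.5, 0.9, 9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCrossValidate:
    @staticmethod
    def data(rng, n=50, size=16):
        X = rng.random((n, size, size)).astype(np.float32)
        Y = (rng.random((n, size, size)) < 0.05).astype(np.uint8)
        Y[:, 4, 4] = 1
        return X, Y

    def test_perfect_oracle_scores_one_everywhere(self, rng):
        X, Y = self.data(rng)

        def factory(arch, fold):
            return lambda xs: Y[fold.test] > 0

        table = ts.cross_validate(["quarter_multiresunet"], X, Y,
                                  predictor_factory=factory)
        folds = table[table["fold"] != "avg"]
        assert len(folds) == 5
        assert (folds[["recall", "precision", "f1", "miou",
                       "rw_f1", "rw_miou"]] == 1.0).all().all()

    def test_constant_false_predictor_conventions(self, rng):
        X, Y = self.data(rng)

        def factory(arch, fold):
            return lambda xs: np.zeros_like(Y[fold.test], dtype=bool)

        table = ts.cross_validate("quarter_multiresunet", X, Y,
                                  predictor_factory=factory)
        folds = table[table["fold"] != "avg"]
        assert (folds["recall"] == 0).all()
        assert (folds["precision"] == 0).all()

    def test_fold_bookkeeping_disjoint_tests(self, rng):
        X, Y = self.data(rng, n=100)
        seen = []

        def factory(arch, fold):
            seen.append(fold.test)
            return lambda xs: Y[fold.test] > 0

        table = ts.cross_validate(["half_unet", "quarter_multiresunet"],
                                  X, Y, predictor_factory=factory)
        assert len(table) == 2 * (5 + 1)  # 5 folds + average row per model
        per_model = np.concatenate(seen[:5])
        assert len(np.unique(per_model)) == 100


class TestEstimator:
    def test_sklearn_param_contract(self):
        from sklearn.base import clone
        seg = ts.TinyObjectSegmenter(epochs=2, seed=9)
        params = seg.get_params()
        assert params["epochs"] == 2
        seg2 = clone(seg).set_params(epochs=4)
        assert seg2.get_params()["epochs"] == 4

    def test_fit_predict_shapes_and_score(self, rng):
        X, Y = ts.synth_dataset(12, ts.SceneConfig(
            size=16, particle_count=(1, 2), particle_diameter=(3, 4),
            max_foreground_fraction=0.2), rng)
        seg = ts.TinyObjectSegmenter(arch="quarter_multiresunet", epochs=2,
                                     validation_fraction=0.0, seed=0)
        seg.fit(X, Y)
        assert seg.model_.input_shape == (16, 16, 1)
        pred = seg.predict(X)
        assert pred.shape == Y.shape and pred.dtype == bool
        assert 0.0 <= seg.score(X, Y) <= 1.0

    def test_bad_shapes_rejected(self):
        seg = ts.TinyObjectSegmenter()
        with pytest.raises(ValueError):
            seg.fit(np.zeros((4, 16, 16)), np.zeros((4, 8, 8)))
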