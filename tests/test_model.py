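"""Two-block residual classifier: forward contracts, training, checkpoints."""

import numpy as np
import pytest

import dropweak as dw
from dropweak import nn
from dropweak.rng import substream
from conftest import small_arch, small_spec


def tiny_model(seed=0, **kw):
    return dw.build_model(small_arch(**kw), np.random.default_rng(seed))


def rand_batch(n=4, size=32, seed=1):
    return np.random.default_rng(seed).random((n, size, size))


class TestForward:
    def test_rows_on_probability_simplex(self):
        probs = tiny_model().forward(rand_batch())
        assert probs.shape == (4, 2)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic_pass_is_repeatable(self):
        model = tiny_model()
        x = rand_batch()
        assert np.array_equal(model.forward(x), model.forward(x))

    def test_deterministic_pass_ignores_seed(self):
        model = tiny_model()
        x = rand_batch()
        a = model.forward(x, stochastic=False, rng=np.random.default_rng(1))
        b = model.forward(x, stochastic=False, rng=np.random.default_rng(99))
        assert np.array_equal(a, b)

    def test_noop_masks_equal_deterministic_pass(self):
        model = tiny_model(dropweak_spec=dw.DropWeakSpec.off(), dropout_prob=0.0)
        x = rand_batch()
        det = model.forward(x, stochastic=False)
        sto = model.forward(x, stochastic=True, rng=np.random.default_rng(5))
        assert np.array_equal(det, sto)

    def test_wrong_spatial_size_rejected(self):
        with pytest.raises(ValueError):
            tiny_model().forward(rand_batch(size=16))

    def test_param_count_matches_hand_count(self):
        # closed form: stem 1->c1 (9c1+c1); block1 2(9c1^2+c1);
        # transition c1->c2 (9c1c2+c2); block2 2(9c2^2+c2); fc (c2*C+C)
        c1, c2, C = 6, 12, 2
        expected = (
            (9 * c1 + c1)
            + 2 * (9 * c1 * c1 + c1)
            + (9 * c1 * c2 + c2)
            + 2 * (9 * c2 * c2 + c2)
            + (c2 * C + C)
        )
        assert tiny_model().param_count() == expected


class TestTraining:
    def _dataset(self, n=120, seed=3):
        ds = dw.generate_dataset(small_spec(n=n, seed=seed))
        return dw.ArrayDataset(ds.images, ds.labels)

    def test_vanishing_learning_rate_leaves_weights(self):
        model = tiny_model()
        before = model.get_weights()
        dw.train(model, self._dataset(), dw.TrainConfig(learning_rate=1e-30, epochs=1, seed=0))
        after = model.get_weights()
        for k in before:
            assert np.allclose(before[k], after[k], atol=1e-6)

    def test_fixed_seed_reproduces_training_log(self):
        logs = []
        for _ in range(2):
            model = tiny_model(seed=7)
            dw.train(model, self._dataset(), dw.TrainConfig(epochs=2, seed=11))
            logs.append(model.training_log)
        assert logs[0] == logs[1]

    def test_loss_decreases_on_separable_task(self):
        model = tiny_model(seed=2)
        dw.train(model, self._dataset(n=200, seed=5), dw.TrainConfig(epochs=5, seed=0))
        log = model.training_log
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_divergence_raises_with_last_good_checkpoint(self):
        # an absurd learning rate blows the weights up within one epoch
        model = tiny_model()
        with pytest.raises(dw.DivergenceError) as exc:
            with np.errstate(all="ignore"):
                dw.train(model, self._dataset(n=60), dw.TrainConfig(learning_rate=1e5, epochs=3, seed=0))
        assert exc.value.last_good is not None
        # the rescued checkpoint is finite and usable
        probs = exc.value.last_good.forward(rand_batch())
        assert np.all(np.isfinite(probs))

    def test_label_range_validated(self):
        ads = self._dataset()
        ads.labels = ads.labels + 5
        with pytest.raises(ValueError):
            dw.train(tiny_model(), ads, dw.TrainConfig(epochs=1, seed=0))

    def test_regularization_narrows_generalization_gap(self):
        # 20% label noise; median train-test accuracy gap over 5 seeds
        # with DropWeak+DropOut must not exceed the unregularized gap.
        def gap(seed, regularized):
            spec = small_spec(n=240, seed=1000 + seed)
            spec = dw.SyntheticSpec(
                **{**spec.__dict__, "label_noise_rate": 0.2}
            )
            ds = dw.generate_dataset(spec)
            ads = dw.ArrayDataset(ds.images, ds.labels)
            if regularized:
                model = tiny_model(seed=seed)
            else:
                model = tiny_model(seed=seed, dropweak_spec=dw.DropWeakSpec.off(), dropout_prob=0.0)
            dw.train(model, ads, dw.TrainConfig(epochs=8, seed=seed, learning_rate=3e-3))
            xtr, ytr = ads.subset("train")
            xte, yte = ads.subset("test")
            acc_tr = (model.forward(xtr).argmax(1) == ytr).mean()
            acc_te = (model.forward(xte).argmax(1) == yte).mean()
            return acc_tr - acc_te

        gaps_reg = [gap(s, True) for s in range(5)]
        gaps_raw = [gap(s, False) for s in range(5)]
        assert np.median(gaps_reg) <= np.median(gaps_raw)


class TestCheckpoint:
    def test_round_trip_is_bit_identical(self, tmp_path):
        model = tiny_model(seed=4)
        model.norm_mean, model.norm_std = 0.41, 0.17
        model.training_log = [{"epoch": 0, "train_loss": 1.0, "val_accuracy": 0.5, "lr": 1e-3}]
        x = rand_batch()
        before = model.forward(x)
        path = tmp_path / "model.ckpt"
        dw.save_checkpoint(model, path)
        loaded = dw.load_checkpoint(path)
        assert np.array_equal(loaded.forward(x), before)
        assert loaded.training_log == model.training_log
        for k, v in model.get_weights().items():
            assert np.array_equal(loaded.get_weights()[k], v)


class TestNaiveBayesHead:
    class _UniformHead:
        def posteriors(self, features):
            return np.full((len(features), 2), 0.5)

    def test_uniform_nb_posterior_leaves_softmax(self):
        model = tiny_model()
        x = rand_batch()
        fused = dw.fused_predict(model, self._UniformHead(), x)
        assert np.allclose(fused, model.forward(x), atol=1e-7)

    def test_fused_probabilities_renormalized(self, small_dataset):
        model = tiny_model(seed=8)
        head = dw.naive_bayes_head_fit(model, small_dataset.images[:60], small_dataset.labels[:60])
        fused = dw.fused_predict(model, head, small_dataset.images[60:80])
        assert np.allclose(fused.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(fused >= 0)

    def test_uniform_softmax_returns_nb_posterior(self, small_dataset):
        model = tiny_model(seed=9)
        model.stage("fc").W[...] = 0.0  # logits all equal -> uniform SoftMax
        model.stage("fc").b[...] = 0.0
        head = dw.naive_bayes_head_fit(model, small_dataset.images[:60], small_dataset.labels[:60])
        x = small_dataset.images[60:70]
        fused = dw.fused_predict(model, head, x)
        model.forward_logits(x)
        nb = head.posteriors(model.stage_output("gap"))
        assert np.allclose(fused, nb, atol=1e-9)


class TestStochasticStreams:
    def test_dropout_layer_matches_independent_implementation(self):
        layer = nn.Dropout(0.4)
        x = np.ones((3, 5), dtype=nn.DTYPE)
        out = layer.forward(x, True, np.random.default_rng(21))
        ref_mask = (np.random.default_rng(21).random((3, 5)) >= 0.4) / 0.6
        assert np.allclose(out, ref_mask, atol=1e-7)

    def test_split_dataset_partitions(self):
        labels = np.array([0, 1] * 50)
        splits = dw.split_dataset(100, (0.8, 0.1, 0.1), np.random.default_rng(0), labels)
        all_idx = np.concatenate(list(splits.values()))
        assert sorted(all_idx) == list(range(100))
        # stratification: train split holds both classes in proportion
        assert abs(labels[splits["train"]].mean() - 0.5) < 0.1
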