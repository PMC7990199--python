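import numpy as np
import pytest

from atquant import nn
from atquant.dn import (
    DNConfig,
    SliceSample,
    build_dn,
    load_checkpoint,
    make_slice_samples,
    nested_cv,
    predict,
    save_checkpoint,
    train_dn,
)
from atquant.volume import BinaryMask, CTVolume

TINY = dict(growth_rate=2, initial_channels=4, dense_layers_per_block=2, batch_size=4)


def _blob_samples(rng, n, size=16):
    """Synthetic slices where the label is a smooth dark blob: learnable."""
    samples = []
    for _ in range(n):
        img = rng.random((size, size)).astype(np.float32) * 0.2 + 0.5
        cy, cx = rng.integers(4, size - 4, 2)
        yy, xx = np.ogrid[:size, :size]
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 < rng.integers(6, 20)
        img[blob] -= 0.4
        lung = np.ones((size, size), dtype=np.uint8)
        samples.append(SliceSample(img, blob.astype(np.uint8), lung))
    return samples


class TestArchitecture:
    def test_softmax_output_shape_and_normalization(self):
        cfg = DNConfig(**TINY)
        model = build_dn(cfg)
        x = np.random.default_rng(0).random((2, 1, 64, 64), dtype=np.float32)
        prob = model.forward(x, train=False)
        assert prob.shape == (2, 2, 64, 64)
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-6)

    def test_indivisible_input_rejected(self):
        model = build_dn(DNConfig(**TINY))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 63, 63), dtype=np.float32))

    def test_parameter_count_matches_channel_arithmetic_oracle(self):
        g, init, L, nd = 2, 4, 4, 2
        cfg = DNConfig(growth_rate=g, initial_channels=init,
                       dense_layers_per_block=L, n_down=nd, n_up=nd)
        model = build_dn(cfg)

        def conv3(cin, cout):
            return cout * cin * 9 + cout

        def dense_block(cin):
            total, c = 0, cin
            for _ in range(L):
                total += 2 * c + conv3(c, g)  # BN + 3x3 conv
                c += g
            return total, c

        expected = conv3(1, init)
        c = init
        skips = []
        for _ in range(nd):
            t, c = dense_block(c)
            skips.append(c)
            expected += t + 2 * c + (c * c + c)  # transition down: BN + 1x1
        t, cout = dense_block(c)
        expected += t
        c_new = g * L
        for skip in reversed(skips):
            expected += conv3(c_new, c_new)  # transposed conv
            t, cout = dense_block(skip + c_new)
            expected += t
            c_new = g * L
        expected += cout * 2 + 2  # 1x1 head
        assert model.n_parameters() == expected

    def test_backprop_matches_numerical_gradients(self):
        cfg = DNConfig(growth_rate=2, initial_channels=4, dense_layers_per_block=2,
                       batch_size=1, dtype="float64", seed=3)
        model = build_dn(cfg)
        rng = np.random.default_rng(5)
        x = rng.random((2, 1, 8, 8))
        y = (rng.random((2, 8, 8)) > 0.7).astype(float)

        prob = model.forward(x, train=True)
        loss, dp = nn.soft_dice_loss(prob[:, 1], y, with_grad=True)
        model.backward(nn.dice_grad_to_scores(prob, dp))
        params = model.params()
        check = np.random.default_rng(0)
        for pi in check.choice(len(params), 8, replace=False):
            p = params[pi]
            idx = np.unravel_index(check.integers(p.value.size), p.value.shape)
            eps, orig = 1e-6, p.value[idx]
            p.value[idx] = orig + eps
            lp = nn.soft_dice_loss(model.forward(x, train=True)[:, 1], y)
            p.value[idx] = orig - eps
            lm = nn.soft_dice_loss(model.forward(x, train=True)[:, 1], y)
            p.value[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert p.grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestSoftDiceLoss:
    def test_perfect_prediction_near_zero(self):
        y = np.zeros((8, 8))
        y[2:5, 2:5] = 1
        assert nn.soft_dice_loss(y.astype(float), y) < 0.06

    def test_disjoint_prediction_near_one(self):
        y = np.zeros((32, 32))
        y[:16] = 1
        assert nn.soft_dice_loss(1.0 - y, y) > 0.99

    def test_matches_direct_formula(self, rng):
        p = rng.random((8, 8))
        y = (rng.random((8, 8)) > 0.5).astype(float)
        expected = 1 - (2 * (p * y).sum() + 1) / (p.sum() + y.sum() + 1)
        assert nn.soft_dice_loss(p, y) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nn.soft_dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestTraining:
    def test_loss_decreases_on_learnable_task(self, rng):
        samples = _blob_samples(rng, 24)
        cfg = DNConfig(**TINY, epochs=8, learning_rate=0.05, seed=17)
        _, record = train_dn(samples, cfg)
        assert record.train_loss[-1] < record.train_loss[0]
        assert all(np.isfinite(record.train_loss))

    def test_seeded_training_is_bit_identical(self, rng):
        samples = _blob_samples(rng, 12)
        cfg = DNConfig(**TINY, epochs=2, learning_rate=0.02, seed=11)
        m1, r1 = train_dn(samples, cfg)
        m2, r2 = train_dn(samples, cfg)
        assert r1.train_loss == r2.train_loss
        for a, b in zip(m1.state_arrays(), m2.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_degenerate_inputs_rejected(self, rng):
        cfg = DNConfig(**TINY)
        with pytest.raises(ValueError):
            train_dn([], cfg)
        with pytest.raises(ValueError):
            train_dn(_blob_samples(rng, 2), cfg)  # fewer samples than batch

    def test_slice_sample_label_must_lie_in_lung(self):
        img = np.zeros((8, 8), dtype=np.float32)
        label = np.zeros((8, 8), dtype=np.uint8)
        label[0, 0] = 1
        with pytest.raises(ValueError):
            SliceSample(img, label, np.zeros((8, 8), dtype=np.uint8))


class TestNestedCV:
    def test_eight_equal_bipartitions(self):
        ids = [f"S{i}" for i in range(8)]
        splits = nested_cv(ids, seed=4)
        assert len(splits) == 8
        for train, test in splits:
            assert len(train) == 4 and len(test) == 4
            assert sorted(train + test) == sorted(ids)
            assert not set(train) & set(test)

    def test_odd_subject_count_splits_within_one(self):
        splits = nested_cv(list("ABCDE"), seed=0)
        for train, test in splits:
            assert abs(len(train) - len(test)) <= 1

    def test_seeded_reproducibility(self):
        ids = list("ABCDEFGH")
        assert nested_cv(ids, seed=9) == nested_cv(ids, seed=9)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            nested_cv(["only"], seed=0)


class TestPredict:
    def _tiny_volume(self, rng):
        exp = CTVolume(rng.normal(-800, 50, (4, 16, 16)))
        lung = np.zeros((4, 16, 16))
        lung[:, 4:12, 4:12] = 1
        return exp, BinaryMask(lung)

    def test_at_map_restricted_to_lung(self, rng):
        cfg = DNConfig(**TINY, seed=2)
        model = build_dn(cfg)
        exp, lung = self._tiny_volume(rng)
        prob, at, qat = predict(model, exp, lung, cfg)
        assert not np.any(at.as_bool() & ~lung.as_bool())
        assert prob.shape == exp.shape
        assert 0.0 <= qat.qat_percent <= 100.0
        assert qat.method == "dn"

    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path, rng):
        cfg = DNConfig(**TINY, seed=2)
        model = build_dn(cfg)
        exp, lung = self._tiny_volume(rng)
        prob1, _, _ = predict(model, exp, lung, cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        model2 = load_checkpoint(path)
        prob2, _, _ = predict(model2, exp, lung)
        np.testing.assert_array_equal(prob1.voxels, prob2.voxels)

    def test_make_slice_samples_skips_empty_slices(self, rng):
        exp, lung = self._tiny_volume(rng)
        lung_arr = lung.voxels.copy()
        lung_arr[0] = 0
        lung2 = BinaryMask(lung_arr)
        label = BinaryMask(np.zeros_like(lung_arr))
        cfg = DNConfig(**TINY)
        samples = make_slice_samples(exp, lung2, label, cfg)
        assert len(samples) == 3
        assert all(0.0 <= s.image.min() and s.image.max() <= 1.0 for s in samples)
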