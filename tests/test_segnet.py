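"""Segmentation network: architecture contracts, attention fusion,
augmentation, DSC, training plumbing."""

import dataclasses

import numpy as np
import pytest

from oppscreen import nn, phantom, segnet
from oppscreen.errors import ConfigurationError, ValidationError
from oppscreen.nn import functional as F


def small_model(seed=0, depth=4, base=4):
    cfg = segnet.SegModelConfig(depth=depth, base_channels=base, max_channels=16)
    return segnet.build_segmentation_model(cfg, seed=seed), cfg


class TestArchitecture:
    @pytest.mark.parametrize("size", [64, 96])
    def test_output_shape_desk(self, size):
        model = segnet.build_segmentation_model(segnet.SegModelConfig.desk())
        x = nn.Tensor(np.zeros((1, 1, size, size), dtype=np.float32))
        assert model(x).shape == (1, 1, size, size)

    def test_output_shape_full_depth(self):
        """The seven-layer profile maps (1,H,W) -> (1,H,W) when H is a
        multiple of 2^6."""
        model = segnet.build_segmentation_model(segnet.SegModelConfig(
            base_channels=4, max_channels=16))
        x = nn.Tensor(np.zeros((1, 1, 128, 128), dtype=np.float32))
        assert model(x).shape == (1, 1, 128, 128)

    def test_indivisible_size_rejected(self):
        model = segnet.build_segmentation_model(segnet.SegModelConfig.desk())
        with pytest.raises(ConfigurationError, match="divisible"):
            model(nn.Tensor(np.zeros((1, 1, 72, 72), dtype=np.float32)))

    def test_depth_floor(self):
        with pytest.raises(ConfigurationError):
            segnet.SegModelConfig(depth=2)

    def test_build_determinism(self):
        m1, cfg = small_model(seed=3)
        m2, _ = small_model(seed=3)
        assert m1.num_parameters() == m2.num_parameters()
        x = nn.Tensor(np.random.default_rng(0).normal(
            size=(2, 1, 32, 32)).astype(np.float32))
        m1.eval(), m2.eval()
        assert np.array_equal(m1(x).data, m2(x).data)

    def test_channel_scheme(self):
        cfg = segnet.SegModelConfig(depth=7, base_channels=16,
                                    channel_growth=2.0, max_channels=256)
        assert cfg.layer_channels == (16, 32, 64, 128, 256, 256, 256)


class TestChannelAttention:
    @pytest.fixture()
    def fusion(self):
        return segnet.ChannelAttentionFusion(
            channels=6, reduction=4, rng=np.random.default_rng(0))

    def test_zero_low_level_passthrough(self, fusion, rng):
        low = np.zeros((2, 6, 8, 8), dtype=np.float32)
        high = rng.normal(size=(2, 6, 8, 8)).astype(np.float32)
        out = segnet.channel_attention_fuse(fusion, low, high)
        assert np.array_equal(out, high)

    def test_output_shape(self, fusion, rng):
        low = rng.normal(size=(3, 6, 10, 10)).astype(np.float32)
        high = rng.normal(size=(3, 6, 10, 10)).astype(np.float32)
        assert segnet.channel_attention_fuse(fusion, low, high).shape \
            == high.shape

    def test_weights_in_unit_interval(self, fusion, rng):
        """Sigmoid-squashed channel weights stay strictly inside (0,1)."""
        for _ in range(100):
            low = nn.Tensor(rng.normal(size=(1, 6, 4, 4)).astype(np.float32))
            high = nn.Tensor(rng.normal(size=(1, 6, 4, 4)).astype(np.float32))
            w = fusion.weights(low, high).data
            assert np.all(w > 0) and np.all(w < 1)

    def test_unit_weights_reduce_to_addition(self, fusion, rng, monkeypatch):
        low = nn.Tensor(rng.normal(size=(2, 6, 8, 8)).astype(np.float32))
        high = nn.Tensor(rng.normal(size=(2, 6, 8, 8)).astype(np.float32))
        monkeypatch.setattr(fusion, "weights", lambda l, h: nn.Tensor(
            np.ones((2, 6, 1, 1), dtype=np.float32)))
        out = fusion(low, high)
        assert np.allclose(out.data, low.data + high.data, atol=1e-6)

    def test_spatial_mismatch(self, fusion):
        low = nn.Tensor(np.zeros((1, 6, 8, 8), dtype=np.float32))
        high = nn.Tensor(np.zeros((1, 6, 4, 4), dtype=np.float32))
        with pytest.raises(ValidationError):
            fusion(low, high)


class TestDsc:
    def test_identical_masks(self, rng):
        m = (rng.uniform(size=(20, 20)) > 0.6).astype(np.uint8)
        assert segnet.dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), dtype=np.uint8)
        b = np.zeros((10, 10), dtype=np.uint8)
        a[:2], b[5:7] = 1, 1
        assert segnet.dsc(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, :4] = 1          # |A| = 4
        b[0, 2:] = 1
        b[1, :2] = 1          # |B| = 4, overlap 2
        assert segnet.dsc(a, b) == 0.5

    def test_both_empty(self):
        z = np.zeros((5, 5), dtype=np.uint8)
        assert segnet.dsc(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            segnet.dsc(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_symmetry_and_set_formula_oracle(self, rng):
        for _ in range(25):
            a = rng.uniform(size=(16, 16)) > rng.uniform(0.2, 0.8)
            b = rng.uniform(size=(16, 16)) > rng.uniform(0.2, 0.8)
            sa = {tuple(p) for p in np.argwhere(a)}
            sb = {tuple(p) for p in np.argwhere(b)}
            expect = 1.0 if not (sa or sb) else \
                2 * len(sa & sb) / (len(sa) + len(sb))
            assert segnet.dsc(a, b) == pytest.approx(expect, abs=1e-12)
            assert segnet.dsc(a, b) == segnet.dsc(b, a)


class TestAugment:
    @pytest.fixture()
    def sample(self, desk_spec):
        s = phantom.generate_subject(desk_spec, 150.0, 150.0, seed=0)
        return s.l1_slice, s.l1_mask

    def test_all_off_identity(self, sample):
        img, msk = sample
        out_i, out_m = segnet.augment(img, msk, {}, seed=0)
        assert np.array_equal(out_i, img)
        assert np.array_equal(out_m, msk)

    def test_flip_involution(self, sample):
        img, _ = sample
        once = segnet.apply_transform(img, {"flip": True})
        twice = segnet.apply_transform(once, {"flip": True})
        assert np.array_equal(twice, img)
        once = segnet.apply_transform(img, {"mirror": True})
        twice = segnet.apply_transform(once, {"mirror": True})
        assert np.array_equal(twice, img)

    def test_mask_stays_binary_and_shapes_match(self, sample):
        img, msk = sample
        switches = dict(flip=True, rotation=True, mirror=True, crop=True)
        for seed in range(5):
            ai, am = segnet.augment(img, msk, switches, seed=seed)
            assert ai.shape == img.shape and am.shape == msk.shape
            assert set(np.unique(am)) <= {0, 1}

    def test_transform_replay_oracle(self, sample):
        """Replaying the logged parameters on the mask reproduces the
        augmented mask exactly (DSC 1)."""
        img, msk = sample
        switches = dict(flip=True, rotation=True, mirror=True, crop=True)
        for seed in range(5):
            _, am, params = segnet.augment(img, msk, switches, seed=seed,
                                           return_params=True)
            replay = segnet.apply_transform(msk, params, is_mask=True)
            assert segnet.dsc(am, replay) == 1.0

    def test_deterministic(self, sample):
        img, msk = sample
        switches = dict(flip=True, rotation=True, mirror=True, crop=True)
        a = segnet.augment(img, msk, switches, seed=11)
        b = segnet.augment(img, msk, switches, seed=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            segnet.augment(np.zeros((8, 8)), np.zeros((9, 9)), {}, seed=0)


def tiny_sets(desk_spec, n_train=12, n_tune=4, size=64):
    spec = phantom.PhantomSpec.desk(size)
    imgs, msks = [], []
    for i in range(n_train + n_tune):
        s = phantom.generate_subject(spec, 100.0 + i, 100.0 + i, seed=i)
        imgs.append(s.l1_slice)
        msks.append(s.l1_mask)
    return (imgs[:n_train], msks[:n_train], imgs[n_train:], msks[n_train:])


class TestTraining:
    def test_zero_epochs_rejected(self):
        with pytest.raises(ValidationError):
            segnet.SegTrainConfig(epochs=0)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValidationError):
            segnet.train_segmentation([], [], [], [])

    def test_non_sgd_rejected(self):
        with pytest.raises(ConfigurationError):
            segnet.SegTrainConfig(optimizer="adam")

    def test_training_determinism(self, desk_spec):
        tr_i, tr_m, tu_i, tu_m = tiny_sets(desk_spec)
        cfg = segnet.SegTrainConfig.desk(epochs=2, batch_size=4, seed=5)
        mcfg = segnet.SegModelConfig(depth=4, base_channels=4, max_channels=8)
        _, h1 = segnet.train_segmentation(tr_i, tr_m, tu_i, tu_m, mcfg, cfg)
        _, h2 = segnet.train_segmentation(tr_i, tr_m, tu_i, tu_m, mcfg, cfg)
        assert h1["tune_dsc"] == h2["tune_dsc"]
        assert h1["loss"] == h2["loss"]

    def test_history_and_best_selection(self, desk_spec):
        tr_i, tr_m, tu_i, tu_m = tiny_sets(desk_spec)
        cfg = segnet.SegTrainConfig.desk(epochs=3, batch_size=4, seed=1)
        mcfg = segnet.SegModelConfig(depth=4, base_channels=4, max_channels=8)
        model, hist = segnet.train_segmentation(tr_i, tr_m, tu_i, tu_m, mcfg, cfg)
        assert len(hist["loss"]) == 3 and len(hist["tune_dsc"]) == 3
        assert hist["best_tune_dsc"] == max(hist["tune_dsc"])
        m = segnet.evaluate_dsc(model, tu_i, tu_m)
        assert m.dsc_mean == pytest.approx(hist["best_tune_dsc"], abs=1e-6)

    def test_checkpoint_roundtrip(self, tmp_path, desk_spec):
        tr_i, tr_m, tu_i, tu_m = tiny_sets(desk_spec, n_train=6, n_tune=2)
        cfg = segnet.SegTrainConfig.desk(epochs=1, batch_size=4, seed=0)
        mcfg = segnet.SegModelConfig(depth=4, base_channels=4, max_channels=8)
        model, hist = segnet.train_segmentation(tr_i, tr_m, tu_i, tu_m, mcfg, cfg)
        segnet.save_checkpoint(model, hist, tmp_path / "ck")
        model2, hist2 = segnet.load_checkpoint(tmp_path / "ck")
        p1 = segnet.predict_masks(model, tu_i)
        p2 = segnet.predict_masks(model2, tu_i)
        for a, b in zip(p1, p2):
            assert np.array_equal(a, b)


class TestBaselines:
    def test_unet_baseline_shape_and_distinct_params(self):
        cfg = segnet.SegModelConfig.desk()
        unet = segnet.build_unet_baseline(cfg, seed=0)
        proposed = segnet.build_segmentation_model(cfg, seed=0)
        x = nn.Tensor(np.zeros((1, 1, 96, 96), dtype=np.float32))
        unet.eval()
        assert unet(x).shape == (1, 1, 96, 96)
        assert unet.num_parameters() != proposed.num_parameters()

    def test_trained_model_beats_fixed_ellipse_oracle(self):
        """On noise-free phantoms the trained network must outperform the
        best single fixed ellipse (mean of training masks, thresholded)."""
        spec = dataclasses.replace(
            phantom.PhantomSpec.desk(64), trabecular_noise_sd=0.0,
            vessel_probability=0.0, background_noise_sd=0.0)
        rng = np.random.default_rng(5)

        def make(n, s0):
            imgs, msks = [], []
            for i in range(n):
                b = float(rng.uniform(30, 280))
                s = phantom.generate_subject(spec, b, b, seed=s0 + i)
                imgs.append(s.l1_slice)
                msks.append(s.l1_mask)
            return imgs, msks

        train = make(60, 0)
        tune = make(8, 900)
        test = make(20, 2000)
        fixed = np.mean([m.astype(float) for m in train[1]], axis=0) > 0.5
        baseline = np.mean([segnet.dsc(fixed, m) for m in test[1]])
        cfg = segnet.SegTrainConfig.desk(epochs=9, seed=3)
        model, _ = segnet.train_segmentation(*train, *tune,
                                             segnet.SegModelConfig.desk(), cfg)
        trained = segnet.evaluate_dsc(model, *test).dsc_mean
        assert trained > baseline


class TestLearningCurve:
    def test_duplicate_sizes_identical(self, desk_spec):
        tr_i, tr_m, te_i, te_m = tiny_sets(desk_spec, n_train=10, n_tune=4)
        cfg = segnet.SegTrainConfig.desk(epochs=1, batch_size=4, seed=2)
        mcfg = segnet.SegModelConfig(depth=4, base_channels=4, max_channels=8)
        curve = segnet.learning_curve(tr_i, tr_m, te_i, te_m, [8, 8],
                                      mcfg, cfg)
        assert curve.entries[0] == curve.entries[1]

    def test_monotone_trend_with_training_size(self):
        """Held-out DSC does not degrade (within one sd) as the training
        subsample grows."""
        spec = phantom.PhantomSpec.desk(64)
        rng = np.random.default_rng(9)

        def make(n, s0):
            imgs, msks = [], []
            for i in range(n):
                b = float(rng.uniform(30, 280))
                s = phantom.generate_subject(spec, b, b, seed=s0 + i)
                imgs.append(s.l1_slice)
                msks.append(s.l1_mask)
            return imgs, msks

        pool = make(60, 0)
        test = make(16, 5000)
        cfg = segnet.SegTrainConfig.desk(epochs=5, seed=4)
        curve = segnet.learning_curve(*pool, *test, [12, 60],
                                      segnet.SegModelConfig.desk(), cfg)
        (n1, m1, s1), (n2, m2, s2) = curve.entries
        assert n2 > n1
        assert m2 >= m1 - max(s1, s2)

    def test_size_exceeding_pool(self, desk_spec):
        tr_i, tr_m, te_i, te_m = tiny_sets(desk_spec, n_train=6, n_tune=2)
        cfg = segnet.SegTrainConfig.desk(epochs=1, batch_size=4, seed=2)
        mcfg = segnet.SegModelConfig(depth=4, base_channels=4, max_channels=8)
        with pytest.raises(ValidationError):
            segnet.learning_curve(tr_i, tr_m, te_i, te_m, [7], mcfg, cfg)
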