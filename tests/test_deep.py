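"""Network structure, block partition and freeze schedules, augmentation
properties, and training contracts (freeze, determinism, learnability) on
miniature instances."""

import numpy as np
import pytest

from histocompare import deep as D
from histocompare import synthetic as syn


@pytest.fixture(scope="module")
def tiny_net():
    return D.VGG19Network(num_classes=2, scale_factor=32, input_size=32, seed=0)


@pytest.fixture(scope="module")
def binary_32(small_binary_set):
    imgs, labels = small_binary_set
    # 64x64 fixture images downsampled by striding keeps the test cheap
    return imgs[:, ::2, ::2], labels


class TestStructure:
    def test_19_weight_layers_at_any_scale(self):
        for s in (8, 32):
            net = D.VGG19Network(num_classes=5, scale_factor=s, input_size=32,
                                 seed=0)
            assert len(net.weight_layers) == 19

    def test_conv_pattern_2_2_4_4_4(self, tiny_net):
        part = D.BlockPartition.from_network(tiny_net)
        assert part.conv_counts == (2, 2, 4, 4, 4)
        assert len(part.blocks["B6"]) == 3
        all_layers = sorted(i for ids in part.blocks.values() for i in ids)
        assert all_layers == list(range(19))

    def test_final_layer_width_is_num_classes(self):
        net = D.VGG19Network(num_classes=8, scale_factor=32, input_size=32, seed=0)
        assert net.weight_layers[-1].W.value.shape[0] == 8

    def test_scaled_fc_width(self):
        net = D.VGG19Network(num_classes=2, scale_factor=8, input_size=32, seed=0)
        assert net.fc_width == 4096 // 8

    @pytest.mark.parametrize("kwargs", [
        dict(num_classes=1), dict(num_classes=2, scale_factor=0),
        dict(num_classes=2, input_size=48)])
    def test_invalid_construction_rejected(self, kwargs):
        with pytest.raises(ValueError):
            D.VGG19Network(**{"scale_factor": 8, "input_size": 32, **kwargs})


class TestSchedules:
    def test_b1_trains_everything(self, tiny_net):
        mask = D.apply_blockwise_schedule(tiny_net, "B1")
        assert all(mask.values())

    def test_b6_trains_only_dense_head(self, tiny_net):
        D.apply_blockwise_schedule(tiny_net, "B6")
        trainable = [l for l in tiny_net.weight_layers if l.params[0].trainable]
        assert len(trainable) == 3
        assert all(isinstance(l, D.Linear) for l in trainable)

    def test_b3_conv_counts(self, tiny_net):
        D.apply_blockwise_schedule(tiny_net, "B3")
        convs = [l for l in tiny_net.weight_layers if isinstance(l, D.Conv3x3)]
        assert sum(l.params[0].trainable for l in convs) == 12
        assert sum(not l.params[0].trainable for l in convs) == 4

    def test_trainable_count_strictly_increases_toward_b1(self, tiny_net):
        counts = []
        for block in ("B6", "B5", "B4", "B3", "B2", "B1"):
            D.apply_blockwise_schedule(tiny_net, block)
            counts.append(D.trainable_parameter_count(tiny_net))
        assert all(a < b for a, b in zip(counts, counts[1:]))

    def test_unknown_block_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            D.apply_blockwise_schedule(tiny_net, "B7")


class TestAugment:
    def test_rot180_is_involution(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        once = D.augment(img, which=4)
        assert np.array_equal(D.augment(once, which=4), img)

    def test_flip_preserves_pixel_multiset(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        for which in range(6):
            out = D.augment(img, which=which)
            assert np.array_equal(np.sort(out.reshape(-1, 3), axis=0),
                                  np.sort(img.reshape(-1, 3), axis=0))

    def test_uniform_draw_frequencies(self, rng):
        """6000 seeded draws hit each of the six transforms 1/6 +- 0.02.
        An asymmetric probe image makes every transform's output distinct."""
        probe = np.arange(48, dtype=np.uint8).reshape(4, 4, 3)
        outputs = {D.augment(probe, which=w).tobytes(): w for w in range(6)}
        assert len(outputs) == 6
        gen = np.random.default_rng(2024)
        draws = np.zeros(6)
        for _ in range(6000):
            draws[outputs[D.augment(probe, gen).tobytes()]] += 1
        assert np.allclose(draws / 6000, 1 / 6, atol=0.02)

    def test_non_square_rotation_rejected(self):
        img = np.zeros((8, 16, 3), np.uint8)
        with pytest.raises(ValueError):
            D.augment(img, which=3)
        assert D.augment(img, which=1).shape == img.shape  # flips are fine


class TestTraining:
    def test_frozen_blocks_bit_identical_after_training(self, binary_32):
        imgs, labels = binary_32
        net = D.VGG19Network(2, scale_factor=32, input_size=32, seed=1)
        snapshot = {p.name: p.value.copy() for p in net.parameters()
                    if p.block <= 3}
        cfg = D.TrainConfig(epochs=5, seed=0)
        D.FineTuneModel(net, imgs, labels, cfg, tune_from="B4").fit()
        for p in net.parameters():
            if p.block <= 3:
                assert np.array_equal(p.value, snapshot[p.name]), p.name

    def test_same_seed_identical_history(self, binary_32):
        imgs, labels = binary_32
        results = []
        for _ in range(2):
            net = D.VGG19Network(2, scale_factor=32, input_size=32, seed=2)
            res = D.FineTuneModel(net, imgs, labels,
                                  D.TrainConfig(epochs=3, seed=5)).fit()
            results.append(res)
        assert results[0].history.equals(results[1].history)

    def test_history_length_equals_epochs(self, binary_32):
        imgs, labels = binary_32
        net = D.VGG19Network(2, scale_factor=32, input_size=32, seed=0)
        res = D.FineTuneModel(net, imgs, labels,
                              D.TrainConfig(epochs=4, seed=0)).fit()
        assert len(res.history) == 4
        assert "B6-B6" in res.summary() or "schedule" in res.summary()

    def test_learnable_on_separable_synthetic_set(self):
        """Miniature instance (scale 8, 32x32 inputs), 400 images, 15 epochs:
        loss strictly decreases over the first five epochs and final train
        accuracy reaches 90%."""
        imgs, labels = [], []
        for i in range(200):
            for spec, lab, off in [(syn.default_benign_spec(), "benign", 0),
                                   (syn.default_malignant_spec(), "malignant", 1)]:
                p, _ = syn.generate_image(spec, (32, 32), 2 * i + off)
                imgs.append(p.pixels)
                labels.append(lab)
        net = D.VGG19Network(2, scale_factor=8, input_size=32, seed=0)
        res = D.FineTuneModel(net, np.stack(imgs), labels,
                              D.TrainConfig(epochs=15, seed=0),
                              tune_from="B1").fit()
        first5 = res.history["train_loss"].head(5).to_numpy()
        assert (np.diff(first5) < 0).all()
        assert res.history["train_accuracy"].iloc[-1] >= 90.0

    def test_mismatched_class_count_rejected(self, binary_32):
        imgs, labels = binary_32
        net = D.VGG19Network(3, scale_factor=32, input_size=32, seed=0)
        with pytest.raises(ValueError):
            D.FineTuneModel(net, imgs, labels)


class TestDeepFeatures:
    def test_width_rows_and_nonnegativity(self, binary_32):
        imgs, labels = binary_32
        net = D.VGG19Network(2, scale_factor=32, input_size=32, seed=0)
        feats = D.extract_deep_features(net, imgs[:6])
        assert feats.shape == (6, net.fc_width)
        assert (feats >= 0).all()

    def test_identical_images_identical_rows(self, binary_32):
        imgs, _ = binary_32
        net = D.VGG19Network(2, scale_factor=32, input_size=32, seed=0)
        feats = D.extract_deep_features(net, np.stack([imgs[0], imgs[0]]))
        assert np.array_equal(feats[0], feats[1])

    def test_size_mismatch_rejected(self, small_binary_set):
        imgs, _ = small_binary_set  # 64x64
        net = D.VGG19Network(2, scale_factor=32, input_size=32, seed=0)
        with pytest.raises(ValueError):
            D.extract_deep_features(net, imgs[:2])

    def test_transfer_copies_backbone_not_head(self, binary_32):
        a = D.VGG19Network(2, scale_factor=32, input_size=32, seed=0)
        b = D.VGG19Network(2, scale_factor=32, input_size=32, seed=1)
        head_before = b.weight_layers[-1].W.value.copy()
        D.transfer_weights(a, b)
        assert np.array_equal(a.weight_layers[0].W.value,
                              b.weight_layers[0].W.value)
        assert np.array_equal(b.weight_layers[-1].W.value, head_before)
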