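"""Encoder-decoder classifier: contracts, pooling round trip, training descent."""

import numpy as np
import pytest

from karstseg import (
    ArchitectureConfig,
    ConfigError,
    LabelRaster,
    TrainConfig,
    UsageError,
    binarize_labels,
    build_model,
    generate_scene,
    load_model,
    make_patchset,
    save_model,
    train,
    two_class_recipe,
)
from karstseg._layers import cross_entropy, max_pool_2x2, max_unpool_2x2
from karstseg.raster import PatchSet

TINY = ArchitectureConfig(
    stages=2, convs_per_stage=(1, 1), base_channels=8, input_channels=3, num_classes=3
)


class TestForwardContracts:
    def test_output_shape_and_softmax_normalization(self, rng):
        model = build_model(TINY, seed=0)
        tile = rng.random((32, 32, 3)).astype(np.float32) * 255
        probs = model.predict_tile(tile)
        assert probs.shape == (32, 32, 3)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_same_seed_identical_initial_predictions(self, rng):
        tile = rng.random((16, 16, 3)).astype(np.float32) * 255
        p1 = build_model(TINY, seed=42).predict_tile(tile)
        p2 = build_model(TINY, seed=42).predict_tile(tile)
        np.testing.assert_array_equal(p1, p2)

    def test_desk_scale_forward_on_256_tile(self, rng):
        model = build_model(ArchitectureConfig(num_classes=5), seed=0)
        tile = rng.random((256, 256, 3)).astype(np.float32) * 255
        probs = model.predict_tile(tile)
        assert probs.shape == (256, 256, 5)

    def test_indivisible_input_rejected(self, rng):
        model = build_model(TINY, seed=0)
        with pytest.raises(ConfigError):
            model.predict_tile(rng.random((30, 30, 3)))

    def test_channel_mismatch_rejected(self, rng):
        model = build_model(TINY, seed=0)
        with pytest.raises(ConfigError):
            model.predict_tile(rng.random((32, 32, 5)))


class TestPoolingRoundTrip:
    def test_unpool_restores_window_maxima_in_place(self, rng):
        """unpool(pool(x)) has each window maximum at its original position
        and zeros elsewhere — the index-unpooling structural guarantee."""
        x = rng.random((2, 8, 8, 3)).astype(np.float32)
        pooled, idx = max_pool_2x2(x)
        restored = max_unpool_2x2(pooled, idx)
        for n in range(2):
            for i in range(4):
                for j in range(4):
                    for c in range(3):
                        win = x[n, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2, c]
                        rwin = restored[n, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2, c]
                        pos = np.unravel_index(win.argmax(), (2, 2))
                        assert rwin[pos] == win.max()
                        assert (rwin != 0).sum() == 1

    def test_pool_picks_window_maximum(self, rng):
        x = rng.random((1, 16, 16, 4)).astype(np.float32)
        pooled, _ = max_pool_2x2(x)
        want = x.reshape(1, 8, 2, 8, 2, 4).max(axis=(2, 4))
        np.testing.assert_array_equal(pooled, want)


class TestLoss:
    def test_cross_entropy_zero_for_certain_correct_prediction(self, rng):
        labels = rng.integers(0, 3, size=(2, 4, 4))
        probs = np.zeros((2, 4, 4, 3))
        np.put_along_axis(probs, labels[..., None], 1.0, axis=-1)
        assert cross_entropy(probs, labels) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_gives_log_k(self, rng):
        labels = rng.integers(0, 4, size=(1, 8, 8))
        probs = np.full((1, 8, 8, 4), 0.25)
        assert cross_entropy(probs, labels) == pytest.approx(np.log(4))


class TestBinarize:
    def test_all_target_becomes_all_one(self, legend5):
        lr = LabelRaster(np.full((4, 4), 2, dtype=np.int64), legend5)
        out = binarize_labels(lr, 2)
        assert (out.labels == 1).all()

    def test_no_target_becomes_all_zero(self, legend5):
        lr = LabelRaster(np.zeros((4, 4), dtype=np.int64), legend5)
        out = binarize_labels(lr, 2)
        assert (out.labels == 0).all()

    def test_foreground_count_preserved_and_nodata_kept(self, legend5, rng):
        labels = rng.integers(0, 5, size=(16, 16)).astype(np.int64)
        labels[0, :4] = legend5.nodata_id
        lr = LabelRaster(labels, legend5)
        out = binarize_labels(lr, 3)
        assert (out.labels == 1).sum() == (labels == 3).sum()
        assert (out.labels == legend5.nodata_id).sum() == 4

    def test_unknown_target_rejected(self, legend5):
        lr = LabelRaster(np.zeros((4, 4), dtype=np.int64), legend5)
        with pytest.raises(UsageError):
            binarize_labels(lr, 7)


def _two_block_patchset(n=12, s=16, seed=0):
    """Trivially separable patches: left half dark class 0, right half bright
    class 1."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for _ in range(n):
        img = np.empty((s, s, 3), dtype=np.float32)
        img[:, : s // 2] = rng.normal(40, 5, size=(s, s // 2, 3))
        img[:, s // 2 :] = rng.normal(210, 5, size=(s, s // 2, 3))
        lab = np.zeros((s, s), dtype=np.int64)
        lab[:, s // 2 :] = 1
        images.append(np.clip(img, 0, 255))
        labels.append(lab)
    return PatchSet(images, labels, ["train"] * n, s, seed)


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        arch = ArchitectureConfig(stages=2, convs_per_stage=(1, 1), base_channels=8,
                                  input_channels=3, num_classes=2)
        model = build_model(arch, seed=0)
        ps = _two_block_patchset()
        cfg = TrainConfig(epochs=30, batch_size=8, seed=0)
        _, hist = train(model, ps, cfg)
        assert hist[-1] < hist[0]

    def test_same_seed_identical_loss_history(self):
        ps = _two_block_patchset()
        cfg = TrainConfig(epochs=3, seed=5)
        arch = ArchitectureConfig(stages=1, convs_per_stage=(1,), base_channels=8,
                                  input_channels=3, num_classes=2)
        _, h1 = train(build_model(arch, seed=1), ps, cfg)
        _, h2 = train(build_model(arch, seed=1), ps, cfg)
        assert h1 == h2

    def test_channel_mismatch_rejected(self):
        ps = _two_block_patchset()
        arch = ArchitectureConfig(stages=1, convs_per_stage=(1,), base_channels=8,
                                  input_channels=7, num_classes=2)
        with pytest.raises(ConfigError):
            train(build_model(arch, seed=0), ps, TrainConfig(epochs=1))

    def test_label_outside_classes_rejected(self):
        ps = _two_block_patchset()
        for lab in ps.labels:
            lab[0, 0] = 5
        arch = ArchitectureConfig(stages=1, convs_per_stage=(1,), base_channels=8,
                                  input_channels=3, num_classes=2)
        with pytest.raises(ConfigError):
            train(build_model(arch, seed=0), ps, TrainConfig(epochs=1))

    def test_more_epochs_do_not_increase_final_training_loss(self):
        """Per-epoch mean loss after 5 epochs is not above the first epoch's,
        across 3 seeds — the qualitative effect of longer training."""
        arch = ArchitectureConfig(stages=2, convs_per_stage=(1, 1), base_channels=8,
                                  input_channels=3, num_classes=2)
        gaps = []
        for seed in range(3):
            ps = _two_block_patchset(seed=seed)
            _, hist = train(build_model(arch, seed=seed), ps,
                            TrainConfig(epochs=5, seed=seed))
            gaps.append(hist[0] - hist[-1])
        assert np.mean(gaps) > 0

    def test_lr_schedule_steps_by_gamma(self):
        ps = _two_block_patchset(n=8)
        arch = ArchitectureConfig(stages=1, convs_per_stage=(1,), base_channels=4,
                                  input_channels=3, num_classes=2)
        model = build_model(arch, seed=0)
        cfg = TrainConfig(epochs=4, batch_size=8, step_size=2, seed=0)
        model, _ = train(model, ps, cfg)  # 4 iterations -> floor(3/2) = 1 step
        assert model.metadata["train"]["final_lr"] == pytest.approx(
            cfg.learning_rate * cfg.gamma
        )


class TestCheckpoint:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path, rng):
        model = build_model(TINY, seed=3)
        ps = _two_block_patchset(s=16)
        model, _ = train(model, ps, TrainConfig(epochs=1, seed=0))
        tile = rng.random((16, 16, 3)).astype(np.float32) * 255
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        np.testing.assert_allclose(back.predict_tile(tile), model.predict_tile(tile),
                                   atol=1e-7)

    def test_checkpoint_carries_legend_and_target_class(self, tmp_path, legend5):
        model = build_model(ArchitectureConfig(stages=1, convs_per_stage=(1,),
                                               base_channels=4, num_classes=2), seed=0)
        model.target_class = 2
        model.metadata["target_class"] = 2
        model.legend = legend5
        save_model(model, tmp_path / "ck")
        back = load_model(tmp_path / "ck")
        assert back.target_class == 2
        assert back.legend == legend5
        assert back.receptive_field == model.receptive_field


class TestReceptiveField:
    def test_bound_is_truthful_for_desk_arch(self, rng):
        """Perturbing inputs farther than the declared receptive field from a
        pixel leaves that pixel's prediction unchanged."""
        model = build_model(ArchitectureConfig(num_classes=2), seed=0)
        r = model.receptive_field
        tile = rng.random((128, 128, 3)).astype(np.float32) * 255
        base = model.predict_tile(tile)
        tile2 = tile.copy()
        tile2[: 64 - r, :] += 10  # outside the r-window of the center pixel
        tile2[64 + r + 1 :, :] += 10
        out = model.predict_tile(np.clip(tile2, 0, 255))
        np.testing.assert_allclose(out[64, 64], base[64, 64], atol=1e-5)
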