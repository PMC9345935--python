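"""Raster data model: I/O round trips, patch extraction, augmentation."""

import numpy as np
import pytest

from karstseg import (
    DataError,
    FormatError,
    LabelRaster,
    Legend,
    LegendMismatchError,
    PointSamples,
    Scene,
    UsageError,
    augment_patch,
    make_patchset,
    read_labels,
    read_scene,
    write_labels,
    write_scene,
)
from karstseg.raster import AUGMENT_OPS


class TestSceneIO:
    def test_tiff_round_trip_lossless(self, tmp_path, rng):
        pixels = rng.integers(0, 256, size=(4, 4, 3)).astype(np.uint8)
        write_scene(tmp_path / "s.tif", Scene(pixels))
        back = read_scene(tmp_path / "s.tif")
        np.testing.assert_array_equal(back.pixels, pixels)

    def test_png_round_trip_lossless(self, tmp_path, rng):
        pixels = rng.integers(0, 256, size=(5, 7, 3)).astype(np.uint8)
        write_scene(tmp_path / "s.png", Scene(pixels))
        back = read_scene(tmp_path / "s.png")
        np.testing.assert_array_equal(back.pixels, pixels)

    def test_nodata_tag_masks_exactly_the_zero_pixel(self, tmp_path):
        pixels = np.full((4, 4, 3), 100, dtype=np.uint8)
        pixels[2, 1] = 0
        mask = np.ones((4, 4), dtype=bool)
        mask[2, 1] = False
        write_scene(tmp_path / "s.tif", Scene(pixels, mask=mask), nodata=0)
        back = read_scene(tmp_path / "s.tif")
        expected = np.ones((4, 4), dtype=bool)
        expected[2, 1] = False
        np.testing.assert_array_equal(back.mask, expected)

    def test_png_alpha_zero_masks(self, tmp_path):
        pixels = np.full((3, 3, 3), 50, dtype=np.uint8)
        mask = np.ones((3, 3), dtype=bool)
        mask[0, 2] = False
        write_scene(tmp_path / "s.png", Scene(pixels, mask=mask))
        back = read_scene(tmp_path / "s.png")
        np.testing.assert_array_equal(back.mask, mask)

    def test_multiband_feature_stack_round_trip(self, tmp_path, rng):
        """Scenes with appended feature channels survive a GeoTIFF round trip."""
        pixels = np.concatenate(
            [
                rng.integers(0, 256, size=(8, 8, 3)).astype(np.float32),
                (rng.random((8, 8, 8)) * 255).astype(np.float32),
            ],
            axis=2,
        )
        write_scene(tmp_path / "m.tif", Scene(pixels))
        back = read_scene(tmp_path / "m.tif")
        np.testing.assert_allclose(back.pixels, pixels)

    def test_two_band_raster_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "b.tif", np.zeros((4, 4, 2), dtype=np.uint8),
                         photometric="minisblack", planarconfig="contig")
        with pytest.raises(FormatError):
            read_scene(tmp_path / "b.tif")

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            read_scene(tmp_path / "nope.tif")

    def test_georeference_carried_through(self, tmp_path):
        pixels = np.zeros((4, 4, 3), dtype=np.uint8)
        georef = {33550: (0.05, 0.05, 0.0), 33922: (0.0, 0.0, 0.0, 110.1, 25.1, 0.0)}
        write_scene(tmp_path / "g.tif", Scene(pixels, georef=georef))
        back = read_scene(tmp_path / "g.tif")
        assert back.georef is not None
        np.testing.assert_allclose(back.georef[33550], georef[33550])
        np.testing.assert_allclose(back.georef[33922], georef[33922])


class TestLabelIO:
    def test_single_band_round_trip(self, tmp_path, legend5, rng):
        labels = rng.integers(0, 5, size=(6, 6)).astype(np.int64)
        raster = LabelRaster(labels, legend5)
        for name in ("l.png", "l.tif"):
            write_labels(tmp_path / name, raster)
            back = read_labels(tmp_path / name, legend5)
            np.testing.assert_array_equal(back.labels, labels)

    def test_paletted_round_trip(self, tmp_path, legend5, rng):
        labels = rng.integers(0, 5, size=(6, 6)).astype(np.int64)
        write_labels(tmp_path / "p.png", LabelRaster(labels, legend5), paletted=True)
        back = read_labels(tmp_path / "p.png", legend5)
        np.testing.assert_array_equal(back.labels, labels)

    def test_unknown_color_raises_with_offenders(self, tmp_path, legend5):
        from PIL import Image

        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        rgb[:] = (1, 2, 3)  # not a legend color
        Image.fromarray(rgb).save(tmp_path / "bad.png")
        with pytest.raises(LegendMismatchError) as exc:
            read_labels(tmp_path / "bad.png", legend5)
        assert (1, 2, 3) in exc.value.offenders

    def test_out_of_legend_value_rejected(self, legend5):
        with pytest.raises(LegendMismatchError):
            LabelRaster(np.full((3, 3), 9, dtype=np.int64), legend5)


class TestLegend:
    def test_yaml_round_trip(self, tmp_path, legend5):
        legend5.save(tmp_path / "legend.yaml")
        assert Legend.load(tmp_path / "legend.yaml") == legend5

    def test_invariants(self):
        from karstseg import LegendEntry

        with pytest.raises(UsageError):
            Legend((LegendEntry(0, "a", (0, 0, 0)),))  # K < 2
        with pytest.raises(UsageError):
            Legend(
                (LegendEntry(0, "a", (0, 0, 0)), LegendEntry(2, "b", (1, 1, 1)))
            )  # non-contiguous
        with pytest.raises(UsageError):
            Legend(
                (LegendEntry(0, "a", (0, 0, 0)), LegendEntry(1, "b", (0, 0, 0)))
            )  # duplicate colors


class TestPointSamples:
    def test_csv_round_trip(self, tmp_path):
        ps = PointSamples(np.array([[1, 2, 0], [3, 0, 4]]))
        ps.save(tmp_path / "pts.csv")
        back = PointSamples.load(tmp_path / "pts.csv")
        np.testing.assert_array_equal(back.records, ps.records)

    def test_bounds_validation(self, legend5):
        ps = PointSamples(np.array([[10, 2, 0]]))
        with pytest.raises(DataError):
            ps.validate((5, 5), legend5)


class TestMakePatchset:
    def test_75_25_split_counts(self, legend5, rng):
        pixels = rng.integers(0, 256, size=(512, 512, 3)).astype(np.float32)
        labels = LabelRaster(
            rng.integers(0, 5, size=(512, 512)).astype(np.int64), legend5
        )
        ps = make_patchset(Scene(pixels), labels, patch_size=256, n_patches=8,
                           train_fraction=0.75, seed=3)
        assert ps.n_train == 6 and ps.n_test == 2

    @pytest.mark.parametrize("n,frac", [(10, 0.75), (13, 0.5), (7, 0.9)])
    def test_split_within_one_patch_of_fraction(self, legend5, rng, n, frac):
        pixels = rng.integers(0, 256, size=(128, 128, 3)).astype(np.float32)
        labels = LabelRaster(
            rng.integers(0, 5, size=(128, 128)).astype(np.int64), legend5
        )
        ps = make_patchset(Scene(pixels), labels, patch_size=32, n_patches=n,
                           train_fraction=frac, seed=0)
        assert ps.n_train + ps.n_test == n
        assert abs(ps.n_train - frac * n) < 1

    def test_patch_equal_to_scene_is_whole_scene(self, small_scene, small_labels):
        ps = make_patchset(small_scene, small_labels, patch_size=64, n_patches=3,
                           seed=1)
        for img, lab in zip(ps.images, ps.labels):
            np.testing.assert_array_equal(img, small_scene.pixels)
            np.testing.assert_array_equal(lab, small_labels.labels)

    def test_same_seed_byte_identical(self, small_scene, small_labels):
        a = make_patchset(small_scene, small_labels, patch_size=32, n_patches=6, seed=9)
        b = make_patchset(small_scene, small_labels, patch_size=32, n_patches=6, seed=9)
        for ia, ib in zip(a.images, b.images):
            np.testing.assert_array_equal(ia, ib)
        assert a.split == b.split

    def test_nodata_windows_rejected(self, legend5, rng):
        pixels = rng.integers(0, 256, size=(64, 64, 3)).astype(np.float32)
        labels = rng.integers(0, 5, size=(64, 64)).astype(np.int64)
        labels[:32, :] = legend5.nodata_id  # top half unlabeled
        ps = make_patchset(
            Scene(pixels), LabelRaster(labels, legend5), patch_size=16,
            n_patches=20, seed=0,
        )
        # every returned label patch must be nodata-free
        for lab in ps.labels:
            assert (lab != legend5.nodata_id).all()

    def test_all_nodata_errors_out(self, legend5, rng):
        pixels = rng.integers(0, 256, size=(32, 32, 3)).astype(np.float32)
        labels = np.full((32, 32), legend5.nodata_id, dtype=np.int64)
        with pytest.raises(DataError):
            make_patchset(
                Scene(pixels), LabelRaster(labels, legend5), patch_size=8,
                n_patches=2, seed=0, max_redraws=50,
            )


class TestAugmentation:
    @pytest.fixture
    def patch(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.float64)
        lab = rng.integers(0, 5, size=(16, 16)).astype(np.int64)
        return img, lab

    def test_flip_is_involution(self, patch):
        img, lab = patch
        for op in ("flip_x", "flip_y"):
            i1, l1 = augment_patch(img, lab, op)
            i2, l2 = augment_patch(i1, l1, op)
            np.testing.assert_array_equal(i2, img)
            np.testing.assert_array_equal(l2, lab)

    def test_rot90_four_times_is_identity(self, patch):
        img, lab = patch
        for _ in range(4):
            img2, lab2 = augment_patch(img, lab, "rot90")
            img, lab = img2, lab2
        np.testing.assert_array_equal(img, patch[0])
        np.testing.assert_array_equal(lab, patch[1])

    def test_invert_definition(self, patch):
        img, lab = patch
        inv, lab2 = augment_patch(img, lab, "invert")
        np.testing.assert_array_equal(inv[:, :, :3], 255 - img[:, :, :3])
        np.testing.assert_array_equal(lab2, lab)

    @pytest.mark.parametrize("op", ["rot90", "rot180", "rot270", "flip_x", "flip_y"])
    def test_geometric_ops_commute_with_labeling(self, patch, op):
        """Transforming the label-as-image equals transforming the label."""
        img, lab = patch
        _, lab_out = augment_patch(img, lab, op)
        lab_as_img = np.repeat(lab[:, :, None], 3, axis=2).astype(np.float64)
        img_out, _ = augment_patch(lab_as_img, lab, op)
        np.testing.assert_array_equal(img_out[:, :, 0].astype(np.int64), lab_out)

    def test_color_ops_leave_label_untouched(self, patch):
        img, lab = patch
        for op in ("color_shift", "invert"):
            _, lab2 = augment_patch(img, lab, op, seed=4)
            np.testing.assert_array_equal(lab2, lab)

    def test_random_scale_preserves_shape_and_range(self, patch):
        img, lab = patch
        for seed in range(5):
            i2, l2 = augment_patch(img, lab, "random_scale", seed=seed)
            assert i2.shape == img.shape and l2.shape == lab.shape
            assert i2.min() >= 0 and i2.max() <= 255
            assert set(np.unique(l2)) <= set(np.unique(lab))

    def test_ops_are_seeded_deterministic(self, patch):
        img, lab = patch
        for op in ("color_shift", "random_scale"):
            a = augment_patch(img, lab, op, seed=11)
            b = augment_patch(img, lab, op, seed=11)
            np.testing.assert_array_equal(a[0], b[0])

    def test_unknown_op_rejected(self, patch):
        with pytest.raises(UsageError):
            augment_patch(*patch, "sharpen")

    def test_all_declared_ops_run(self, patch):
        img, lab = patch
        for op in AUGMENT_OPS:
            i2, l2 = augment_patch(img, lab, op, seed=1)
            assert i2.shape == img.shape
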