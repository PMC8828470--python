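"""Image container, processing, watershed segmentation and spot features."""

import numpy as np
import pytest

from spomics import (
    ImageStore,
    SpotGeometry,
    calculate_features,
    generate_spot_crops,
    load_image,
    process,
    segment_watershed,
    simulate_blob_image,
)
from tests.conftest import make_dataset


class TestImageStore:
    def test_grayscale_promoted_to_one_channel(self):
        s = ImageStore()
        s.add("a", np.zeros((4, 5)))
        assert s["a"].shape == (4, 5, 1)

    def test_shape_mismatch_rejected(self):
        s = ImageStore()
        s.add("a", np.zeros((4, 5, 3)))
        with pytest.raises(ValueError, match="shape"):
            s.add("b", np.zeros((6, 5, 1)))

    def test_load_png_and_tiff(self, tmp_path):
        import imageio.v3 as iio
        import tifffile

        rgb = (np.random.default_rng(0).random((16, 16, 3)) * 255).astype(np.uint8)
        iio.imwrite(tmp_path / "x.png", rgb)
        s = load_image(tmp_path / "x.png", "rgb")
        assert s["rgb"].shape == (16, 16, 3)
        gray = rgb[:, :, 0]
        tifffile.imwrite(tmp_path / "y.tif", gray)
        load_image(tmp_path / "y.tif", "gray", s)
        assert s["gray"].shape == (16, 16, 1)


class TestProcess:
    def test_gray_of_pure_red(self):
        s = ImageStore()
        img = np.zeros((4, 4, 3))
        img[:, :, 0] = 1.0
        s.add("rgb", img)
        name = process(s, "rgb", "gray")
        np.testing.assert_allclose(s[name], 0.2125)

    def test_gray_requires_three_channels(self):
        s = ImageStore()
        s.add("g", np.zeros((4, 4, 1)))
        with pytest.raises(ValueError, match="3 channels"):
            process(s, "g", "gray")

    def test_smooth_preserves_constant(self):
        s = ImageStore()
        s.add("c", np.full((16, 16, 1), 0.7))
        name = process(s, "c", "smooth", sigma=2)
        np.testing.assert_allclose(s[name], 0.7, atol=1e-12)

    def test_tiled_equals_untiled_with_sufficient_overlap(self):
        """Tiled smoothing with overlap >= 4 sigma equals the whole-image
        result to 1e-6 (whole-image run is the oracle)."""
        rng = np.random.default_rng(1)
        s = ImageStore()
        s.add("im", rng.random((256, 256, 1)))
        sigma = 2.0
        whole = process(s, "im", "smooth", sigma=sigma, new_layer="whole")
        tiled = process(s, "im", "smooth", sigma=sigma, tile_size=64,
                        overlap=int(4 * sigma), new_layer="tiled")
        assert np.abs(s[whole] - s[tiled]).max() < 1e-6

    def test_custom_transform(self):
        s = ImageStore()
        s.add("im", np.full((8, 8, 1), 2.0))
        name = process(s, "im", lambda a: a * 0.5)
        np.testing.assert_allclose(s[name], 1.0)


class TestWatershed:
    def test_black_image_zero_objects(self):
        s = ImageStore()
        s.add("im", np.zeros((32, 32, 1)))
        with pytest.warns(UserWarning, match="empty foreground"):
            name = segment_watershed(s, "im", threshold=0.5)
        assert s[name].max() == 0

    def test_disjoint_disks_counted(self):
        s, centers = simulate_blob_image(5, radius=7, size=(128, 128), seed=3, noise_sd=0.0)
        name = segment_watershed(s, "image", threshold=0.5)
        assert s[name].max() == 5

    def test_labels_consecutive_from_one(self):
        s, _ = simulate_blob_image(4, radius=6, size=(96, 96), seed=4, noise_sd=0.02)
        name = segment_watershed(s, "image", threshold=0.5)
        ids = np.unique(s[name])
        np.testing.assert_array_equal(ids, np.arange(len(ids)))

    def test_touching_disks_split_by_markers(self):
        """Two disks overlapping by less than a radius still yield 2 labels."""
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        for cx in (24, 38):  # centers 14 apart, radius 9 -> overlap < radius
            img[(xx - cx) ** 2 + (yy - 32) ** 2 <= 81] = 1.0
        s = ImageStore()
        s.add("im", img)
        name = segment_watershed(s, "im", threshold=0.5, min_peak_distance=5)
        assert s[name].max() == 2

    def test_multichannel_rejected(self):
        s = ImageStore()
        s.add("rgb", np.zeros((8, 8, 3)))
        with pytest.raises(ValueError, match="single-channel"):
            segment_watershed(s, "rgb")

    @pytest.mark.parametrize("seed", range(10))
    def test_blob_count_recovered_across_seeds(self, seed):
        n = 3 + seed % 4
        s, _ = simulate_blob_image(n, radius=6, size=(128, 128), seed=seed, noise_sd=0.03)
        name = segment_watershed(s, "image", threshold=0.5)
        assert s[name].max() == n


class TestSpotCrops:
    def test_center_crop_is_exact_block(self):
        arr = np.arange(100, dtype=float).reshape(10, 10)
        s = ImageStore()
        s.add("im", arr)
        geom = SpotGeometry(centers=[(5, 5)], diameter=5)
        (_, crop, padded), = generate_spot_crops(s, geom, "im")
        np.testing.assert_array_equal(crop[:, :, 0], arr[3:8, 3:8])
        assert not padded

    def test_corner_spot_zero_padded_and_flagged(self):
        s = ImageStore()
        s.add("im", np.ones((10, 10, 1)))
        geom = SpotGeometry(centers=[(0, 0)], diameter=6)
        (_, crop, padded), = generate_spot_crops(s, geom, "im")
        assert padded
        assert crop[0, 0, 0] == 0  # padding region

    def test_crop_count_equals_n_obs(self):
        s = ImageStore()
        s.add("im", np.ones((20, 20, 1)))
        geom = SpotGeometry(centers=[(5, 5), (10, 10), (15, 15)], diameter=4)
        assert len(list(generate_spot_crops(s, geom, "im"))) == 3


class TestFeatures:
    def make_simple(self, value=0.4, n_spots=2, size=32):
        s = ImageStore()
        s.add("im", np.full((size, size, 1), value))
        centers = [(8, 8), (24, 24)][:n_spots]
        ds = make_dataset(np.array(centers, dtype=float), X=np.zeros((n_spots, 1)))
        geom = SpotGeometry(centers=np.array(centers, dtype=float), diameter=8)
        return ds, s, geom

    def test_constant_crop_summary(self):
        ds, s, geom = self.make_simple(0.4)
        f = calculate_features(ds, s, geom, "im", features=("summary",))
        assert f["summary_im_ch0_mean"].iloc[0] == pytest.approx(0.4)
        assert f["summary_im_ch0_std"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        for q in (0.1, 0.5, 0.9):
            assert f[f"summary_im_ch0_quantile_{q}"].iloc[0] == pytest.approx(0.4)

    def test_constant_crop_texture_limits(self):
        """Single-cell GLCM: contrast 0, dissimilarity 0, homogeneity 1, ASM 1."""
        ds, s, geom = self.make_simple(0.4)
        f = calculate_features(ds, s, geom, "im", features=("texture",), texture_range=(0, 1))
        assert f["texture_im_ch0_contrast_d1"].iloc[0] == 0.0
        assert f["texture_im_ch0_dissimilarity_d1"].iloc[0] == 0.0
        assert f["texture_im_ch0_homogeneity_d1"].iloc[0] == 1.0
        assert f["texture_im_ch0_asm_d1"].iloc[0] == 1.0

    def test_texture_float_without_range_rejected(self):
        ds, s, geom = self.make_simple()
        with pytest.raises(ValueError, match="range"):
            calculate_features(ds, s, geom, "im", features=("texture",))

    def test_painted_spots_mean_exact(self):
        """An image painted with a distinct constant per spot crop returns
        those constants exactly as the summary mean."""
        img = np.zeros((40, 40, 1))
        img[4:12, 4:12] = 0.25   # spot at (8, 8), side 8
        img[24:32, 24:32] = 0.75
        s = ImageStore()
        s.add("im", img)
        centers = np.array([(8.0, 8.0), (28.0, 28.0)])
        ds = make_dataset(centers, X=np.zeros((2, 1)))
        geom = SpotGeometry(centers=centers, diameter=8)
        f = calculate_features(ds, s, geom, "im", features=("summary",))
        assert f["summary_im_ch0_mean"].iloc[0] == 0.25
        assert f["summary_im_ch0_mean"].iloc[1] == 0.75

    def test_glcm_correlation_matches_dense_oracle(self):
        """Correlation property on a gradient crop against an explicit
        dense evaluation of the co-occurrence formula."""
        side = 16
        img = np.tile(np.linspace(0, 1, side), (side, 1))[:, :, None]
        s = ImageStore()
        s.add("im", img)
        centers = np.array([(side / 2, side / 2)])
        ds = make_dataset(centers, X=np.zeros((1, 1)))
        geom = SpotGeometry(centers=centers, diameter=side)
        levels = 8
        f = calculate_features(
            ds, s, geom, "im", features=("texture",),
            texture_levels=levels, texture_angles=(0.0,), texture_range=(0, 1),
        )
        # oracle: build the symmetric normalized GLCM for offset (0, 1) by hand
        crop = next(generate_spot_crops(s, geom, "im"))[1][:, :, 0]
        q = np.minimum((crop * levels).astype(int), levels - 1)
        C = np.zeros((levels, levels))
        for r in range(q.shape[0]):
            for c in range(q.shape[1] - 1):
                C[q[r, c], q[r, c + 1]] += 1
                C[q[r, c + 1], q[r, c]] += 1
        C /= C.sum()
        p = np.arange(levels)
        mu_p = (C.sum(axis=1) * p).sum()
        mu_q = (C.sum(axis=0) * p).sum()
        var_p = (C.sum(axis=1) * (p - mu_p) ** 2).sum()
        var_q = (C.sum(axis=0) * (p - mu_q) ** 2).sum()
        corr = sum(
            C[i, j] * (i - mu_p) * (j - mu_q) / np.sqrt(var_p * var_q)
            for i in range(levels)
            for j in range(levels)
        )
        assert f["texture_im_ch0_correlation_d1"].iloc[0] == pytest.approx(corr, abs=1e-10)

    def test_glcm_is_probability_distribution(self):
        """ASM and homogeneity in (0, 1] follow from the normalization."""
        rng = np.random.default_rng(6)
        s = ImageStore()
        s.add("im", rng.random((32, 32, 1)))
        centers = np.array([(16.0, 16.0)])
        ds = make_dataset(centers, X=np.zeros((1, 1)))
        geom = SpotGeometry(centers=centers, diameter=16)
        f = calculate_features(ds, s, geom, "im", features=("texture",), texture_range=(0, 1))
        assert 0 < f["texture_im_ch0_asm_d1"].iloc[0] <= 1
        assert 0 < f["texture_im_ch0_homogeneity_d1"].iloc[0] <= 1

    def test_histogram_counts(self):
        ds, s, geom = self.make_simple(0.4)
        f = calculate_features(
            ds, s, geom, "im", features=("histogram",), histogram_bins=4, histogram_range=(0, 1)
        )
        side = geom.crop_side
        assert f["histogram_im_ch0_bin1"].iloc[0] == side * side  # 0.4 falls in bin [0.25, 0.5)
        assert f["histogram_im_ch0_bin0"].iloc[0] == 0

    def test_segmentation_features_count_and_intensity(self):
        s, centers = simulate_blob_image(3, radius=6, size=(96, 96), seed=7, noise_sd=0.0)
        seg = segment_watershed(s, "image", threshold=0.5)
        ds = make_dataset(centers, X=np.zeros((3, 1)))
        geom = SpotGeometry(centers=centers, diameter=20)
        f = calculate_features(
            ds, s, geom, "image", features=("segmentation",),
            label_layer=seg, intensity_layer="image",
        )
        assert (f[f"segmentation_{seg}_count"] == 1).all()
        np.testing.assert_allclose(f[f"segmentation_{seg}_ch0_mean_intensity"], 1.0)

    def test_segmentation_without_label_layer_rejected(self):
        ds, s, geom = self.make_simple()
        with pytest.raises(ValueError, match="label_layer"):
            calculate_features(ds, s, geom, "im", features=("segmentation",))

    def test_row_order_follows_observations(self):
        """Permuting observations permutes feature rows accordingly."""
        img = np.zeros((40, 40, 1))
        img[4:12, 4:12] = 0.25
        img[24:32, 24:32] = 0.75
        s = ImageStore()
        s.add("im", img)
        c1 = np.array([(8.0, 8.0), (28.0, 28.0)])
        ds1 = make_dataset(c1, X=np.zeros((2, 1)))
        f1 = calculate_features(ds1, s, SpotGeometry(centers=c1, diameter=8), "im")
        c2 = c1[::-1]
        ds2 = make_dataset(c2, X=np.zeros((2, 1)))
        f2 = calculate_features(ds2, s, SpotGeometry(centers=c2, diameter=8), "im")
        np.testing.assert_array_equal(
            f1["summary_im_ch0_mean"].to_numpy(), f2["summary_im_ch0_mean"].to_numpy()[::-1]
        )
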