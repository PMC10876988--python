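import h5py
import numpy as np
import pytest

from ramanprep.hyperspectral import (
    CubeConfig,
    HyperspectralCube,
    channel_map,
    merge_rgb,
    pca_feature_maps,
    preprocess_cube,
    read_cube,
    simulate_cube,
    top_k_mean_spectrum,
    write_cube,
)
from ramanprep.io import Spectrum, ValidationError, WavenumberAxis
from ramanprep.metrics import snr_spec


@pytest.fixture
def small_cube(rng):
    ax = WavenumberAxis(np.linspace(400, 3200, 128))
    data = rng.uniform(0, 1, (4, 4, 128))
    return HyperspectralCube(ax, data)


@pytest.fixture
def sim_cube():
    return simulate_cube(CubeConfig(height=16, width=16, grid_len=256), np.random.default_rng(3))


class TestCubeIO:
    def test_round_trip_bitwise(self, small_cube, tmp_path):
        path = tmp_path / "cube.h5"
        write_cube(small_cube, path)
        back = read_cube(path)
        np.testing.assert_array_equal(back.intensities, small_cube.intensities)
        np.testing.assert_array_equal(back.axis.values, small_cube.axis.values)

    def test_masks_round_trip(self, sim_cube, tmp_path):
        path = tmp_path / "cube.h5"
        write_cube(sim_cube, path)
        back = read_cube(path)
        np.testing.assert_array_equal(back.signal_mask, sim_cube.signal_mask)

    def test_header_pixel_count_mismatch_rejected(self, small_cube, tmp_path):
        path = tmp_path / "cube.h5"
        write_cube(small_cube, path)
        with h5py.File(path, "r+") as f:
            f.attrs["H"] = 5
        with pytest.raises(ValidationError, match="pixels"):
            read_cube(path)

    def test_single_pixel_cube_valid(self, tmp_path, rng):
        ax = WavenumberAxis(np.linspace(400, 3200, 64))
        cube = HyperspectralCube(ax, rng.uniform(0, 1, (1, 1, 64)))
        write_cube(cube, tmp_path / "c.h5")
        assert read_cube(tmp_path / "c.h5").shape == (1, 1, 64)


class TestPreprocessCube:
    def test_identity_preprocessor_keeps_cube(self, small_cube):
        out = preprocess_cube(small_cube, lambda s: s)
        np.testing.assert_array_equal(out.intensities, small_cube.intensities)

    def test_pixels_processed_independently(self, small_cube):
        double = lambda s: Spectrum(s.axis, 2 * s.intensity)
        out = preprocess_cube(small_cube, double)
        for i in range(4):
            for j in range(4):
                np.testing.assert_array_equal(
                    out.intensities[i, j], 2 * small_cube.intensities[i, j]
                )

    def test_commutes_with_pixel_permutation(self, small_cube):
        half = lambda s: Spectrum(s.axis, 0.5 * s.intensity)
        out = preprocess_cube(small_cube, half)
        perm = HyperspectralCube(small_cube.axis, small_cube.intensities[::-1])
        out_perm = preprocess_cube(perm, half)
        np.testing.assert_array_equal(out.intensities[::-1], out_perm.intensities)


class TestTopKMean:
    def test_k_equals_all_is_plain_mean(self, small_cube):
        s = top_k_mean_spectrum(small_cube, k=16)
        np.testing.assert_allclose(s.intensity, small_cube.pixels_matrix().mean(axis=0))

    def test_k1_is_best_pixel(self, sim_cube):
        s1 = top_k_mean_spectrum(sim_cube, k=1)
        mat = sim_cube.pixels_matrix()
        snrs = [snr_spec(Spectrum(sim_cube.axis, mat[i])) for i in range(mat.shape[0])]
        np.testing.assert_array_equal(s1.intensity, mat[int(np.argmax(snrs))])

    def test_three_pixel_ranking(self):
        ax = np.linspace(400, 3200, 128)
        sig = (ax >= 2800) & (ax < 3200)
        sil = (ax >= 1800) & (ax < 2800)
        cube = np.zeros((1, 3, 128))
        for j, snr_lin in enumerate([1.0, 10.0, 100.0]):  # 0, 10, 20 dB
            cube[0, j, sig] = snr_lin
            cube[0, j, sil] = 1.0
        hc = HyperspectralCube(WavenumberAxis(ax), cube)
        out = top_k_mean_spectrum(hc, k=2)
        np.testing.assert_allclose(out.intensity, cube[0, 1:].mean(axis=0))

    def test_k_out_of_range_rejected(self, small_cube):
        with pytest.raises(ValidationError):
            top_k_mean_spectrum(small_cube, k=17)


class TestChannelMaps:
    def test_exact_grid_point_band0(self, small_cube):
        shift = float(small_cube.axis.values[40])
        img = channel_map(small_cube, shift)
        np.testing.assert_array_equal(img, small_cube.intensities[:, :, 40])

    def test_between_points_takes_nearest_lower_on_tie(self, small_cube):
        vals = small_cube.axis.values
        mid = float((vals[10] + vals[11]) / 2)  # exact tie
        img = channel_map(small_cube, mid)
        np.testing.assert_array_equal(img, small_cube.intensities[:, :, 10])

    def test_band_covers_three_points(self, small_cube):
        vals = small_cube.axis.values
        step = vals[1] - vals[0]
        img = channel_map(small_cube, float(vals[20]), band=1.1 * step)
        np.testing.assert_allclose(img, small_cube.intensities[:, :, 19:22].mean(axis=2))

    def test_shift_outside_span_rejected(self, small_cube):
        with pytest.raises(ValidationError):
            channel_map(small_cube, 5000.0)


class TestMergeRgb:
    def test_identical_maps_give_grayscale(self, rng):
        m = rng.uniform(0, 1, (4, 4))
        img = merge_rgb(m, m, m)
        np.testing.assert_array_equal(img[..., 0], img[..., 1])
        np.testing.assert_array_equal(img[..., 1], img[..., 2])

    def test_one_hot_maps_give_primary_colors(self):
        r = np.zeros((3, 3))
        r[0, 0] = 1.0
        g = np.zeros((3, 3))
        g[1, 1] = 1.0
        b = np.zeros((3, 3))
        b[2, 2] = 1.0
        img = merge_rgb(r, g, b)
        np.testing.assert_array_equal(img[0, 0], [1, 0, 0])
        np.testing.assert_array_equal(img[1, 1], [0, 1, 0])
        np.testing.assert_array_equal(img[2, 2], [0, 0, 1])

    def test_constant_map_scales_to_zero(self):
        img = merge_rgb(np.full((2, 2), 7.0), np.zeros((2, 2)), np.eye(2))
        np.testing.assert_array_equal(img[..., 0], 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            merge_rgb(np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((2, 2)))


class TestPcaMaps:
    def test_rank_one_cube_concentrates_variance(self, rng):
        ax = WavenumberAxis(np.linspace(400, 3200, 64))
        v = rng.uniform(0, 1, 64)
        c = rng.uniform(0.5, 2.0, (6, 6))
        cube = HyperspectralCube(ax, c[..., None] * v[None, None, :])
        maps, evr = pca_feature_maps(cube, n_components=3)
        assert len(maps) == 3
        assert evr[0] >= 0.999

    def test_explained_variance_non_increasing(self, sim_cube):
        _, evr = pca_feature_maps(sim_cube, n_components=3)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_too_many_components_rejected(self, small_cube):
        with pytest.raises(ValidationError):
            pca_feature_maps(small_cube, n_components=256)

    def test_degenerate_cube_rejected(self):
        ax = WavenumberAxis(np.linspace(400, 3200, 32))
        cube = HyperspectralCube(ax, np.ones((3, 3, 32)))
        with pytest.raises(ValidationError, match="degenerate"):
            pca_feature_maps(cube)


class TestSimulateCube:
    def test_masks_partition_and_are_disjoint(self, sim_cube):
        assert not np.any(sim_cube.signal_mask & sim_cube.background_mask)
        assert np.all(sim_cube.signal_mask | sim_cube.background_mask)

    def test_lipid_channel_brighter_inside_cells(self, sim_cube):
        img = channel_map(sim_cube, 2850.0, band=20.0)
        lipid_kindred = img[sim_cube.signal_mask].mean()
        assert lipid_kindred > img[sim_cube.background_mask].mean()

    def test_zero_noise_zero_baseline_silent_zone_capped_snr(self):
        cfg = CubeConfig(height=4, width=4, grid_len=256, noise_sd=0.0, baseline_amp=0.0)
        cube = simulate_cube(cfg, np.random.default_rng(1))
        i, j = np.argwhere(cube.signal_mask)[0]
        s = Spectrum(cube.axis, cube.intensities[i, j])
        silent = (cube.axis.values >= 1800) & (cube.axis.values < 2800)
        assert np.allclose(s.intensity[silent], 0.0, atol=1e-12)
        assert snr_spec(s) == 120.0

    def test_deterministic_by_seed(self):
        cfg = CubeConfig(height=8, width=8, grid_len=128)
        a = simulate_cube(cfg, np.random.default_rng(9))
        b = simulate_cube(cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a.intensities, b.intensities)
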