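"""Image PCA, score images and loading-extrema band selection."""

import numpy as np
import pytest

from litchi_hsi.bands import (
    CharacteristicBands,
    PCAResult,
    PixelMatrix,
    assemble_pixels,
    band_image,
    image_pca,
    pc_loading_extrema,
    score_image,
)
from litchi_hsi.hsi_io import ReflectanceCube, WavelengthAxis


def _axis(n: int, lo: float = 400.0, hi: float = 1000.0) -> WavelengthAxis:
    return WavelengthAxis(np.linspace(lo, hi, n))


def _cube(data) -> ReflectanceCube:
    data = np.asarray(data, np.float32)
    return ReflectanceCube(data, _axis(data.shape[2]))


class TestAssemblePixels:
    def test_pooling_and_subsampling_counts(self):
        cubes = [_cube(np.random.default_rng(i).random((10, 10, 5))) for i in range(2)]
        masks = [np.ones((10, 10), bool)] * 2
        pm = assemble_pixels(cubes, masks, max_pixels=120, seed=0)
        assert pm.data.shape == (120, 5)

    def test_cap_larger_than_available_keeps_all_without_duplication(self):
        cube = _cube(np.random.default_rng(0).random((6, 6, 4)))
        pm = assemble_pixels([cube], [np.ones((6, 6), bool)], max_pixels=1000, seed=0)
        assert pm.data.shape == (36, 4)
        assert np.unique(pm.data, axis=0).shape[0] == 36

    def test_same_seed_same_subsample(self):
        cube = _cube(np.random.default_rng(1).random((20, 20, 4)))
        mask = np.ones((20, 20), bool)
        a = assemble_pixels([cube], [mask], 50, seed=3)
        b = assemble_pixels([cube], [mask], 50, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_empty_mask_union_rejected(self):
        cube = _cube(np.zeros((4, 4, 3)))
        with pytest.raises(ValueError, match="empty"):
            assemble_pixels([cube], [np.zeros((4, 4), bool)], 10, seed=0)


class TestImagePCA:
    def test_collinear_data_gives_single_full_contribution(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=200)
        direction = np.array([1.0, 2.0, -1.0, 0.5])
        X = np.outer(t, direction) + 3.0
        pca = image_pca(PixelMatrix(X, _axis(4)), n_pc=4)
        np.testing.assert_allclose(pca.contribution[0], 100.0, atol=1e-8)
        np.testing.assert_allclose(pca.contribution[1:], 0.0, atol=1e-8)

    def test_isotropic_two_band_cloud_splits_contribution(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10_000, 2))
        pca = image_pca(PixelMatrix(X, _axis(2)), n_pc=2)
        assert abs(pca.contribution[0] - 50.0) < 5.0
        assert abs(pca.contribution[1] - 50.0) < 5.0

    def test_loadings_orthonormal_and_reconstruction_complete(self):
        rng = np.random.default_rng(4)
        X = rng.random((300, 6))
        pca = image_pca(PixelMatrix(X, _axis(6)), n_pc=6)
        np.testing.assert_allclose(pca.loadings.T @ pca.loadings, np.eye(6), atol=1e-8)
        Xc = X - pca.band_means
        recon = (Xc @ pca.loadings) @ pca.loadings.T
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_projections_onto_distinct_pcs_uncorrelated(self):
        rng = np.random.default_rng(5)
        X = rng.random((500, 5)) * np.array([3, 1, 1, 0.5, 0.2])
        pca = image_pca(PixelMatrix(X, _axis(5)), n_pc=5)
        scores = (X - pca.band_means) @ pca.loadings
        corr = np.corrcoef(scores.T)
        off = corr - np.diag(np.diag(corr))
        assert np.abs(off).max() < 1e-6

    def test_contribution_invariant_to_pixel_order_and_duplication(self):
        rng = np.random.default_rng(6)
        X = rng.random((100, 4))
        axis = _axis(4)
        base = image_pca(PixelMatrix(X, axis), n_pc=4).contribution
        perm = image_pca(PixelMatrix(X[rng.permutation(100)], axis), n_pc=4).contribution
        dup = image_pca(PixelMatrix(np.vstack([X, X]), axis), n_pc=4).contribution
        np.testing.assert_allclose(perm, base, atol=1e-9)
        np.testing.assert_allclose(dup, base, atol=1e-9)

    def test_cumulative_rates_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        pca = image_pca(PixelMatrix(rng.random((200, 8)), _axis(8)), n_pc=7)
        assert np.all(np.diff(pca.cumulative) >= 0)
        assert pca.cumulative[-1] <= 100.0 + 1e-9
        assert np.all(pca.contribution >= 0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            image_pca(PixelMatrix(np.ones((50, 4)), _axis(4)), n_pc=2)


class TestScoreImage:
    def test_constant_cube_gives_constant_image(self):
        cube = _cube(np.full((8, 8, 4), 0.3))
        rng = np.random.default_rng(8)
        ref = image_pca(PixelMatrix(rng.random((50, 4)), _axis(4)), n_pc=2)
        img = score_image(cube, ref, 1)
        assert np.all(img == img[0, 0])

    def test_min_max_rescaling_hits_both_ends(self):
        rng = np.random.default_rng(9)
        data = rng.random((10, 10, 4))
        cube = _cube(data)
        pca = image_pca(PixelMatrix(data.reshape(-1, 4), _axis(4)), n_pc=2)
        img = score_image(cube, pca, 1)
        assert img.min() == 0 and img.max() == 255

    def test_pc3_score_image_contrasts_damage_on_synthetic_fruit(self):
        """On the pooled per-class PC basis, the PC3 score image separates the
        bruise from intact pericarp by at least 10 gray levels."""
        from litchi_hsi import synth

        reprs = synth.generate_dataset(1, seed=9)
        cubes = [s.calibrated() for s in reprs]
        pixels = assemble_pixels(cubes, [s.fruit_mask for s in reprs],
                                 max_pixels=50_000, seed=1)
        pca = image_pca(pixels, n_pc=7)
        for s, cube in zip(reprs, cubes):
            if s.label == 0:
                continue
            img = score_image(cube, pca, 3).astype(float)
            contrast = abs(img[s.damage_mask].mean()
                           - img[s.fruit_mask & ~s.damage_mask].mean())
            assert contrast >= 10.0

    def test_index_out_of_range_rejected(self):
        rng = np.random.default_rng(10)
        pca = image_pca(PixelMatrix(rng.random((50, 4)), _axis(4)), n_pc=2)
        with pytest.raises(ValueError, match="pc_index"):
            score_image(_cube(rng.random((4, 4, 4))), pca, 3)


class TestBandImage:
    def test_fixed_scale_mapping(self):
        data = np.zeros((2, 2, 3), np.float32)
        data[..., 1] = [[0.0, 0.5], [1.0, 1.2]]
        cube = ReflectanceCube(data, _axis(3))
        img = band_image(cube, cube.axis.values[1])
        assert img[0, 0] == 0 and img[0, 1] == 128 and img[1, 0] == 255
        assert img[1, 1] == 255  # clipped


def _pca_with_loading(curve: np.ndarray, axis: WavelengthAxis) -> PCAResult:
    """Wrap a hand-built loading curve as the third component of a PCAResult."""
    n = curve.size
    loadings = np.zeros((n, 3))
    loadings[:, 2] = curve / np.linalg.norm(curve)
    loadings[0, 0] = loadings[1, 1] = 1.0
    ev = np.zeros(n)
    ev[:3] = [3, 2, 1]
    contrib = 100 * ev[:3] / ev.sum()
    return PCAResult(np.zeros(n), loadings, ev, contrib, np.cumsum(contrib), axis)


class TestLoadingExtrema:
    def test_sine_loading_extrema_at_closed_form_positions(self):
        axis = WavelengthAxis(400.0 + 2.8 * np.arange(215))
        curve = np.sin(2 * np.pi * (axis.values - 400.0) / 300.0)
        found = pc_loading_extrema(_pca_with_loading(curve, axis), 3)
        # closed form: extrema at 475 + 150 k nm; four fall inside 400-999.2
        assert len(found.wavelengths) == 4
        for target, got in zip((475.0, 625.0, 775.0, 925.0), found.wavelengths):
            assert abs(got - target) <= 2.8
        assert found.extremum_types == ["max", "min", "max", "min"]

    def test_monotone_loading_yields_empty_set(self):
        axis = _axis(50)
        found = pc_loading_extrema(_pca_with_loading(np.linspace(-1, 1, 50), axis), 3)
        assert found.wavelengths.size == 0

    def test_planted_bumps_at_sensitive_wavelengths_recovered_exactly(self):
        """A loading built with features at 694/725/798 nm returns exactly those."""
        axis = WavelengthAxis(np.arange(400.0, 1001.0, 1.0))
        lam = axis.values
        curve = (0.6 * np.exp(-0.5 * ((lam - 694) / 8) ** 2)
                 - 0.8 * np.exp(-0.5 * ((lam - 725) / 7) ** 2)
                 + 0.5 * np.exp(-0.5 * ((lam - 798) / 10) ** 2))
        found = pc_loading_extrema(_pca_with_loading(curve, axis), 3)
        assert found.wavelengths.tolist() == [694.0, 725.0, 798.0]

    def test_extrema_invariant_to_sign_flip(self):
        axis = WavelengthAxis(np.arange(400.0, 1001.0, 1.0))
        lam = axis.values
        curve = (np.exp(-0.5 * ((lam - 550) / 20) ** 2)
                 - np.exp(-0.5 * ((lam - 700) / 20) ** 2))
        a = pc_loading_extrema(_pca_with_loading(curve, axis), 3)
        b = pc_loading_extrema(_pca_with_loading(-curve, axis), 3)
        np.testing.assert_allclose(a.wavelengths, b.wavelengths)
        assert a.extremum_types == ["max", "min"]
        assert b.extremum_types == ["min", "max"]
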