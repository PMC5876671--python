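"""Equalization, Otsu, Roberts edges, fuzzy c-means and damage segmentation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from litchi_hsi import synth
from litchi_hsi.bands import band_image
from litchi_hsi.segment import (
    equalize_hist,
    fuzzy_cmeans,
    mask_iou,
    otsu_threshold,
    robert_edges,
    segment_damage,
)


def _otsu_bruteforce(values: np.ndarray) -> int:
    """Independent oracle: try every threshold, maximize between-class variance."""
    v = np.asarray(values).ravel().astype(float)
    best_t, best_var = 0, -1.0
    for t in range(255):
        lo, hi = v[v <= t], v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / v.size, hi.size / v.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


class TestEqualizeHist:
    def test_constant_image_unchanged(self):
        img = np.full((5, 5), 77, dtype=np.uint8)
        np.testing.assert_array_equal(equalize_hist(img), img)

    def test_two_level_image_preserves_order(self):
        img = np.where(np.arange(100).reshape(10, 10) < 50, 10, 20).astype(np.uint8)
        out = equalize_hist(img)
        assert len(np.unique(out)) == 2
        assert out[img == 10].max() < out[img == 20].min()

    def test_mapping_monotone_nondecreasing(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        out = equalize_hist(img)
        order = np.argsort(img.ravel(), kind="stable")
        assert np.all(np.diff(out.ravel()[order].astype(int)) >= 0)

    def test_flattens_skewed_histogram(self):
        """Equalized histogram is closer to flat (chi-squared) than the input's."""
        rng = np.random.default_rng(1)
        img = np.clip(rng.normal(60, 15, (100, 100)), 0, 255).astype(np.uint8)
        out = equalize_hist(img)

        def chi2_vs_flat(a, bins=16):
            h, _ = np.histogram(a, bins=bins, range=(0, 256))
            e = a.size / bins
            return ((h - e) ** 2 / e).sum()

        assert chi2_vs_flat(out) < chi2_vs_flat(img)


class TestOtsu:
    def test_half_and_half_splits_evenly(self):
        img = np.concatenate([np.zeros(50, int), np.full(50, 255)])
        t, mask = otsu_threshold(img)
        assert t == _otsu_bruteforce(img)
        assert mask.sum() == 50

    def test_unbalanced_two_level(self):
        img = np.concatenate([np.full(90, 50), np.full(10, 200)])
        t, mask = otsu_threshold(img)
        assert 50 <= t < 200
        assert mask.sum() == 10

    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_search_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=40)
        if np.all(img == img[0]):
            return
        t, _ = otsu_threshold(img)
        assert t == _otsu_bruteforce(img)

    def test_matches_exhaustive_search_on_bimodal_images(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            img = np.clip(np.concatenate([
                rng.normal(70, 12, 300), rng.normal(180, 20, 120)
            ]), 0, 255).astype(int)
            t, _ = otsu_threshold(img)
            assert t == _otsu_bruteforce(img)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full((4, 4), 9))


class TestRobertEdges:
    def test_constant_image_zero_magnitude(self):
        mag, mask = robert_edges(np.full((6, 6), 40))
        np.testing.assert_array_equal(mag, 0.0)
        assert not mask.any()

    def test_vertical_step_magnitude(self):
        """Hand-evaluated stencils on a 0|255 vertical step."""
        img = np.zeros((4, 4), int)
        img[:, 2:] = 255
        mag, _ = robert_edges(img)
        # stencils anchored at column 1 straddle the step: |Gx| = |Gy| = 255
        np.testing.assert_allclose(mag[:3, 1], 255.0 * np.sqrt(2))
        np.testing.assert_allclose(mag[:3, 0], 0.0)
        np.testing.assert_allclose(mag[:3, 2], 0.0)

    def test_checkerboard_invisible_to_diagonal_stencils(self):
        """Both Roberts stencils difference diagonal neighbors, which share
        the checkerboard parity — the gradient is identically zero."""
        img = 255 * ((np.add.outer(np.arange(6), np.arange(6))) % 2)
        mag, _ = robert_edges(img)
        np.testing.assert_allclose(mag, 0.0)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="2 x 2"):
            robert_edges(np.zeros((1, 5)))


class TestFuzzyCMeans:
    def test_two_well_separated_groups_recovered(self):
        vals = np.array([0.0, 0.0, 0.0, 100.0, 100.0, 100.0])
        state = fuzzy_cmeans(vals, c=2, seed=0)
        centers = np.sort(state.centers.ravel())
        np.testing.assert_allclose(centers, [0.0, 100.0], atol=1e-3)
        assert state.memberships.max(axis=1).min() >= 0.99

    def test_memberships_row_stochastic(self):
        rng = np.random.default_rng(3)
        state = fuzzy_cmeans(rng.normal(size=(50, 2)), c=3, seed=1)
        np.testing.assert_allclose(state.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert state.memberships.min() >= 0.0

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0, 1, 80), rng.normal(8, 1, 40)])
        state = fuzzy_cmeans(vals, c=2, seed=2)
        assert np.all(np.diff(state.objective_trace) <= 1e-9)

    def test_near_crisp_limit_agrees_with_kmeans(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 0.5, 60), rng.normal(10, 0.5, 60)])
        state = fuzzy_cmeans(vals, c=2, m=1.05, seed=3)
        km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(vals[:, None])
        ours = state.hard_labels()
        theirs = km.labels_
        agreement = max((ours == theirs).mean(), (ours != theirs).mean())
        assert agreement == 1.0

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fuzzy_cmeans(np.full(10, 5.0), c=2)

    def test_point_on_center_gets_crisp_membership(self):
        vals = np.array([0.0, 0.0, 10.0, 10.0, 5.0])
        state = fuzzy_cmeans(vals, c=2, seed=0, max_iter=1)
        # centers start at percentiles; any coincident point is handled crisply
        assert np.isfinite(state.memberships).all()


@pytest.fixture(scope="module")
def samples():
    return synth.generate_dataset(2, seed=11)


class TestSegmentDamage:
    def test_fresh_fruit_has_no_false_damage(self, samples):
        for s in samples:
            if s.label != 0:
                continue
            res = segment_damage(band_image(s.calibrated(), 725), seed=0)
            assert res.damage_fraction < 0.02

    def test_damaged_fruit_blob_recovered(self, samples):
        """2 h and 4 h bruises localize with IoU >= 0.5 vs ground truth."""
        for s in samples:
            if s.label not in (2, 3):
                continue
            res = segment_damage(band_image(s.calibrated(), 725), seed=0)
            assert mask_iou(res.damage_mask, s.damage_mask) >= 0.5

    def test_fruit_mask_covers_true_disc(self, samples):
        s = samples[0]
        res = segment_damage(band_image(s.calibrated(), 725), seed=0)
        assert mask_iou(res.fruit_mask, s.fruit_mask) >= 0.9

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError, match="no fruit"):
            segment_damage(np.zeros((50, 50), dtype=np.uint8))

    def test_invariant_to_positive_affine_intensity_change(self, samples):
        """Equalization before thresholding absorbs a*I + b re-scalings."""
        s = next(x for x in samples if x.label == 3)
        gray = band_image(s.calibrated(), 725).astype(float)
        res_a = segment_damage(gray.astype(np.uint8), seed=0)
        rescaled = np.clip(0.6 * gray + 30, 0, 255).astype(np.uint8)
        res_b = segment_damage(rescaled, seed=0)
        assert mask_iou(res_a.fruit_mask, res_b.fruit_mask) > 0.95
        assert mask_iou(res_a.damage_mask, res_b.damage_mask) > 0.8
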