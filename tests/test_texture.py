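"""GLCM, homogeneity, patch layer, and feature-vector structure."""
import numpy as np
import pytest

from abruptcut.levelset import contract_border
from abruptcut.texture import (
    COLOR_SPACES,
    GLCMParams,
    NoPairsError,
    build_patch_layer,
    compute_glcm,
    extract_features,
    homogeneity,
    patch_statistics,
    quantize_channel,
)

from conftest import disk_mask, random_blob


def brute_force_glcm(quantized, member, offset, levels):
    """Independent oracle: double loop over all pixel pairs."""
    h, w = quantized.shape
    dx, dy = offset
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            if not member[r, c]:
                continue
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w and member[r2, c2]:
                counts[quantized[r, c], quantized[r2, c2]] += 1
    return counts + counts.T


class TestQuantizeChannel:
    def test_two_levels_threshold(self):
        img = np.array([[100.0, 200.0]])
        q = quantize_channel(img, 2)
        assert q[0, 0] == 0 and q[0, 1] == 1

    def test_constant_channel_single_level(self):
        q = quantize_channel(np.full((4, 4), 37.0), 32)
        assert len(np.unique(q)) == 1

    def test_monotone_and_in_range(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (16, 16))
        q = quantize_channel(img, 32)
        assert q.min() >= 0 and q.max() < 32
        flat_i = img.ravel()
        flat_q = q.ravel()
        order = np.argsort(flat_i)
        assert (np.diff(flat_q[order]) >= 0).all()


class TestComputeGLCM:
    def test_hand_enumerated_2x2(self):
        # [[0,0],[1,1]] horizontal offset: pairs (0,0) and (1,1) ->
        # symmetrized, normalized diag(0.5, 0.5)
        q = np.array([[0, 0], [1, 1]])
        rows, cols = np.mgrid[0:2, 0:2]
        g = compute_glcm(q, rows.ravel(), cols.ravel(), offset=(1, 0), levels=2)
        assert np.allclose(g.counts, np.diag([0.5, 0.5]))

    def test_constant_patch_all_mass_on_diagonal(self):
        q = np.full((4, 4), 3)
        rows, cols = np.mgrid[0:4, 0:4]
        g = compute_glcm(q, rows.ravel(), cols.ravel(), offset=(1, 0), levels=8)
        assert g.counts[3, 3] == 1.0 and g.counts.sum() == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_patches(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.integers(0, 8, (8, 8))
        member = rng.random((8, 8)) < 0.7
        offset = [(1, 0), (0, 1), (1, 1), (-1, 2)][seed % 4]
        rows, cols = np.nonzero(member)
        oracle = brute_force_glcm(q, member, offset, 8)
        if oracle.sum() == 0:
            with pytest.raises(NoPairsError):
                compute_glcm(q, rows, cols, offset=offset, levels=8)
            return
        g = compute_glcm(q, rows, cols, offset=offset, levels=8)
        assert np.allclose(g.counts, oracle / oracle.sum())

    def test_no_pairs_raises(self):
        q = np.zeros((3, 3), int)
        with pytest.raises(NoPairsError):
            compute_glcm(q, np.array([0]), np.array([0]), offset=(1, 0), levels=2)


class TestHomogeneity:
    def test_diagonal_matrix_is_one(self):
        assert homogeneity(np.diag([0.5, 0.5])) == pytest.approx(1.0)

    def test_uniform_2x2_value(self):
        # 0.25*(1 + 0.5 + 0.5 + 1) = 0.75 by direct evaluation
        assert homogeneity(np.full((2, 2), 0.25)) == pytest.approx(0.75)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            homogeneity(np.ones((2, 2)))

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_on_random_normalized_glcm(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((8, 8))
        m = (m + m.T) / 2
        m /= m.sum()
        h = homogeneity(m)
        assert 1.0 / 8 <= h <= 1.0
        off_diag = m.sum() - np.trace(m)
        if off_diag > 0:
            assert h < 1.0


class TestPatchStatistics:
    def test_constant_patch(self):
        arr = np.full((6, 6), 100.0)
        rows, cols = np.mgrid[0:6, 0:6]
        h, m, s = patch_statistics(arr, rows.ravel(), cols.ravel())
        assert (h, m, s) == (pytest.approx(1.0), 100.0, 0.0)

    def test_two_value_patch_closed_form(self):
        arr = np.zeros((2, 4))
        arr[1] = 255.0
        rows, cols = np.mgrid[0:2, 0:4]
        _, m, s = patch_statistics(arr, rows.ravel(), cols.ravel())
        assert m == pytest.approx(127.5) and s == pytest.approx(127.5)

    def test_checkerboard_rougher_than_gradient(self):
        rows, cols = np.mgrid[0:8, 0:8]
        checker = 255.0 * ((rows + cols) % 2)
        gradient = np.tile(np.linspace(0, 255, 8), (8, 1))
        h_check, _, _ = patch_statistics(checker, rows.ravel(), cols.ravel())
        h_grad, _, _ = patch_statistics(gradient, rows.ravel(), cols.ravel())
        assert h_check < h_grad


class TestBuildPatchLayer:
    def test_disk_patch_count(self):
        # mid-curve circumference / spacing: ceil(2*pi*50/10) = 32
        result = contract_border(disk_mask(60, size=151), 20.0, method="distance")
        ps = build_patch_layer(result, 10.0)
        assert abs(len(ps) - 32) <= 2

    def test_centers_on_mid_curve(self):
        result = contract_border(disk_mask(60, size=151), 20.0, method="distance")
        ps = build_patch_layer(result, 10.0)
        boundary = result.original.point_array()
        from scipy.spatial import cKDTree

        d = cKDTree(boundary).query(ps.centers)[0]
        assert np.all(np.abs(d - 10.0) <= 1.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_union_covers_annulus(self, seed):
        mask = random_blob(seed, size=200, base_radius=62)
        result = contract_border(mask, 20.0, method="distance")
        ps = build_patch_layer(result, 10.0)
        annulus = result.annulus_mask.astype(bool)
        cov = np.zeros_like(annulus)
        for rr, cc in ps.patch_pixel_sets:
            cov[rr, cc] = True
        assert cov[annulus].mean() >= 0.95

    def test_requires_matching_contraction_distance(self):
        result = contract_border(disk_mask(60, size=151), 20.0, method="distance")
        with pytest.raises(ValueError, match="L = 14"):
            build_patch_layer(result, 7.0)

    def test_lesion_too_small_for_radius(self):
        result = contract_border(disk_mask(12, size=41), 8.0, method="distance")
        with pytest.raises(ValueError):
            build_patch_layer(result, 4.0, min_pixels=200)


class TestExtractFeatures:
    @pytest.fixture(scope="class")
    def contraction(self, sample_lesion_cls):
        img, mask, _ = sample_lesion_cls
        return img, contract_border(mask, 20.0, method="distance")

    @pytest.fixture(scope="class")
    def sample_lesion_cls(self):
        from abruptcut.synth import LesionSpec, generate_lesion

        return generate_lesion(LesionSpec(seed=3, edge_profile="abrupt"))

    @pytest.mark.parametrize(
        "color_space,length", [("RGB", 18), ("HSV", 18), ("RGB+HSV", 36)]
    )
    def test_feature_dimensionality(self, contraction, color_space, length):
        img, result = contraction
        fv = extract_features(img, result, 10.0, color_space)
        assert len(fv) == length
        assert len(fv.names) == length
        channels = COLOR_SPACES[color_space]
        assert fv.names[0].startswith(channels[0])

    def test_uniform_lesion_degenerate_features(self):
        img = np.full((121, 121, 3), 120, np.uint8)
        mask = disk_mask(50, size=121)
        result = contract_border(mask, 20.0, method="distance")
        fv = extract_features(img, result, 10.0, "RGB")
        d = fv.as_dict()
        for ch in "RGB":
            assert d[f"{ch}_hom_mean"] == pytest.approx(1.0)
            assert d[f"{ch}_std_mean"] == pytest.approx(0.0)

    def test_min_le_mean_aggregates(self, contraction):
        img, result = contraction
        fv = extract_features(img, result, 10.0, "RGB+HSV")
        d = fv.as_dict()
        for ch in "RGBHSV":
            assert d[f"{ch}_hom_min"] <= d[f"{ch}_hom_mean"]
            assert d[f"{ch}_mean_min"] <= d[f"{ch}_mean_mean"]
            assert d[f"{ch}_std_min"] <= d[f"{ch}_std_mean"]
            assert 0.0 < d[f"{ch}_hom_min"] <= 1.0

    def test_bit_identical_determinism(self, contraction):
        img, result = contraction
        a = extract_features(img, result, 10.0, "RGB")
        b = extract_features(img, result, 10.0, "RGB")
        assert np.array_equal(a.values, b.values)

    def test_unknown_color_space_rejected(self, contraction):
        img, result = contraction
        with pytest.raises(ValueError):
            extract_features(img, result, 10.0, "LAB")
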