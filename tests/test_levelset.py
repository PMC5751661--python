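"""Level-set contraction: analytic disks, distance-transform oracle, entropy."""
import numpy as np
import pytest
from scipy import ndimage
from skimage import measure

from abruptcut._geometry import (
    as_closed,
    hausdorff_distance,
    is_simple_closed,
    shoelace_area,
)
from abruptcut.boundary import trace_chain_code
from abruptcut.levelset import (
    ContractionSpec,
    LevelSetField,
    OverContractionError,
    contract_border,
    evolve,
    extract_zero_level_set,
    init_signed_distance,
    inradius,
    naive_normal_offset,
)

from conftest import disk_mask, random_blob, star_mask


def edt_iso_curve(mask: np.ndarray, depth: float) -> np.ndarray:
    """Oracle: iso-curve of the Euclidean distance transform at *depth*.

    The distance transform measures to background pixel centers; the
    continuous boundary lies half a pixel closer, hence the +0.5 level.
    """
    edt = ndimage.distance_transform_edt(mask.astype(bool))
    contours = measure.find_contours(edt, depth + 0.5)
    return as_closed(max(contours, key=len))


class TestInitSignedDistance:
    def test_disk_center_value(self):
        field = init_signed_distance(disk_mask(30, size=101))
        assert abs(field.phi[50, 50] + 30.0) <= 0.5

    def test_background_corner_positive(self):
        field = init_signed_distance(disk_mask(30, size=101))
        assert field.phi[0, 0] > 0

    def test_matches_brute_force_distance(self):
        # exhaustive pairwise distance to boundary pixels on random samples
        mask = random_blob(5).astype(bool)
        field = init_signed_distance(mask)
        boundary = np.argwhere(
            mask & ~ndimage.binary_erosion(mask, np.ones((3, 3), bool))
        )
        rng = np.random.default_rng(0)
        h, w = mask.shape
        for _ in range(20):
            r, c = rng.integers(0, h), rng.integers(0, w)
            d = np.min(np.hypot(boundary[:, 0] - r, boundary[:, 1] - c))
            assert abs(abs(field.phi[r, c]) - d) <= 1.0

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(OverContractionError):
            init_signed_distance(np.zeros((5, 5), np.uint8))
        with pytest.raises(OverContractionError):
            init_signed_distance(np.ones((5, 5), np.uint8))


class TestEvolve:
    def test_zero_distance_is_identity(self):
        field = init_signed_distance(disk_mask(20))
        out = evolve(field, ContractionSpec(0.0))
        assert np.array_equal(out.phi, field.phi)
        assert out.time == field.time

    def test_disk_offset(self):
        field = init_signed_distance(disk_mask(30, size=101))
        out = evolve(field, ContractionSpec(10.0))
        loop = extract_zero_level_set(out)[0]
        radii = np.hypot(loop[:, 0] - 50, loop[:, 1] - 50)
        assert np.all(np.abs(radii - 20.0) <= 1.0)

    def test_monotone_shrinkage(self):
        field = init_signed_distance(random_blob(2))
        areas = [int((field.phi < 0).sum())]
        for _ in range(6):
            field = evolve(field, ContractionSpec(2.0))
            areas.append(int((field.phi < 0).sum()))
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            ContractionSpec(5.0, dt=0.75)

    def test_over_contraction_names_feasible_distance(self):
        field = init_signed_distance(disk_mask(15))
        with pytest.raises(OverContractionError, match="feasible"):
            evolve(field, ContractionSpec(40.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_distance_transform_oracle_on_blobs(self, seed):
        # For constant speed the entropy solution equals the distance
        # transform offset; Hausdorff distance must stay below 1.5 px.
        mask = random_blob(seed)
        L = 10.0
        result = contract_border(mask, L, method="pde")
        oracle = edt_iso_curve(result.mask, L)
        assert hausdorff_distance(result.contracted, oracle) < 1.5


class TestExtractZeroLevelSet:
    def test_disk_recovery_at_t0(self):
        field = init_signed_distance(disk_mask(30, size=101))
        loop = extract_zero_level_set(field)[0]
        radii = np.hypot(loop[:, 0] - 50, loop[:, 1] - 50)
        assert np.all(np.abs(radii - 30.0) <= 0.5)
        assert len(loop) >= 8

    def test_area_matches_pixel_count(self):
        mask = random_blob(9)
        field = init_signed_distance(mask)
        loop = extract_zero_level_set(field)[0]
        area = abs(shoelace_area(loop))
        inside = int((field.phi < 0).sum())
        perimeter = len(loop)
        assert abs(area - inside) <= perimeter

    def test_vanished_front_raises(self):
        field = LevelSetField(np.ones((8, 8)), time=0.0)
        with pytest.raises(OverContractionError):
            extract_zero_level_set(field)


class TestContractBorder:
    @pytest.mark.parametrize("R", [20, 30, 50])
    @pytest.mark.parametrize("L", [5, 10, 15])
    def test_analytic_disk(self, R, L):
        if L >= R:
            pytest.skip("infeasible")
        n = 2 * R + 21
        result = contract_border(disk_mask(R, size=n), float(L), method="pde")
        c = (n - 1) / 2.0
        radii = np.hypot(result.contracted[:, 0] - c, result.contracted[:, 1] - c)
        assert np.all(np.abs(radii - (R - L)) <= 1.0)

    def test_disk_annulus_area(self):
        n = 121
        result = contract_border(disk_mask(50, size=n), 20.0)
        expected = np.pi * (50**2 - 30**2)
        assert abs(result.annulus_mask.sum() - expected) / expected < 0.05

    def test_high_curvature_star_stays_simple(self):
        # concavity curvature radius ~3 px << L = 15: naive offsets shock,
        # the entropy-conditioned front must not.
        result = contract_border(star_mask(), 15.0, method="pde")
        for loop in result.loops:
            assert is_simple_closed(loop)

    def test_vertex_distance_band_on_blob(self):
        # brute-force check against the traced boundary points
        mask = random_blob(3)
        result = contract_border(mask, 10.0, method="pde")
        boundary = result.original.point_array()
        from scipy.spatial import cKDTree

        d = cKDTree(boundary).query(result.contracted)[0]
        assert d.min() >= 8.5 and d.max() <= 11.5

    def test_pde_and_distance_paths_agree(self):
        mask = random_blob(8)
        a = contract_border(mask, 12.0, method="pde")
        b = contract_border(mask, 12.0, method="distance")
        assert hausdorff_distance(a.contracted, b.contracted) < 1.0

    def test_composition_of_contractions(self):
        mask = random_blob(4)
        first = contract_border(mask, 8.0, method="pde")
        inner = (first.phi_L < 0).astype(np.uint8)
        second = contract_border(inner, 6.0, method="pde")
        direct = contract_border(mask, 14.0, method="pde")
        assert hausdorff_distance(second.contracted, direct.contracted) < 1.5

    def test_infeasible_distance_raises(self):
        with pytest.raises(OverContractionError, match="feasible"):
            contract_border(disk_mask(15), 20.0)

    def test_annulus_is_original_minus_interior(self):
        mask = random_blob(6)
        result = contract_border(mask, 10.0)
        annulus = result.annulus_mask.astype(bool)
        assert not (annulus & ~result.mask.astype(bool)).any()
        assert not (annulus & (result.phi_L < 0)).any()


class TestNaiveNormalOffset:
    def test_disk_matches_circle(self):
        n = 121
        contour = trace_chain_code(disk_mask(50, size=n))
        off = naive_normal_offset(contour, 20.0)
        c = (n - 1) / 2.0
        radii = np.hypot(off[:, 0] - c, off[:, 1] - c)
        assert np.all(np.abs(radii - 30.0) <= 1.5)

    def test_self_intersects_where_lsp_does_not(self):
        mask = star_mask()
        contour = trace_chain_code(mask)
        off = naive_normal_offset(contour, 15.0)
        assert not is_simple_closed(off)
        lsp = contract_border(mask, 15.0, method="pde")
        assert all(is_simple_closed(l) for l in lsp.loops)

    def test_agrees_with_lsp_on_convex_blob(self):
        n = 161
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2.0
        theta = np.arctan2(yy - c, xx - c)
        mask = (np.hypot(yy - c, xx - c) <= 70 * (1 + 0.05 * np.cos(3 * theta))).astype(
            np.uint8
        )
        off = naive_normal_offset(trace_chain_code(mask), 10.0)
        lsp = contract_border(mask, 10.0, method="pde")
        assert hausdorff_distance(off, lsp.contracted) < 1.5


def test_inradius_of_disk():
    assert abs(inradius(disk_mask(25)) - 25.0) <= 1.0
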