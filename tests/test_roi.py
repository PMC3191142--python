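import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dmncausal as dc
from dmncausal.roi import VoxelGrid, VoxelMask, select_best_component


@pytest.fixture(scope="module")
def grid():
    return VoxelGrid(dims=(12, 12, 10), voxel_size_mm=(2.0, 2.0, 2.0))


def _brute_force_sphere(grid, center, radius):
    out = set()
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                c = np.array(grid.origin_mm) + np.array(grid.voxel_size_mm) * (i, j, k)
                if np.linalg.norm(c - np.asarray(center)) <= radius:
                    out.add((i, j, k))
    return out


class TestSphereMask:
    def test_zero_radius_on_voxel_center(self, grid):
        mask = dc.sphere_mask(grid, (8.0, 8.0, 8.0), 0.0)
        assert mask.voxels == {(4, 4, 4)}

    def test_matches_brute_force_enumeration(self, grid):
        center, radius = (11.0, 9.0, 8.0), 10.0
        mask = dc.sphere_mask(grid, center, radius)
        assert mask.voxels == _brute_force_sphere(grid, center, radius)

    def test_deterministic(self, grid):
        a = dc.sphere_mask(grid, (5.0, 5.0, 5.0), 5.0)
        b = dc.sphere_mask(grid, (5.0, 5.0, 5.0), 5.0)
        assert a.voxels == b.voxels

    @given(r1=st.floats(0, 12), r2=st.floats(0, 12))
    def test_monotone_in_radius(self, r1, r2):
        grid = VoxelGrid(dims=(10, 10, 10), voxel_size_mm=(2.0, 2.0, 2.0))
        lo, hi = sorted([r1, r2])
        small = dc.sphere_mask(grid, (9.0, 9.0, 9.0), lo)
        big = dc.sphere_mask(grid, (9.0, 9.0, 9.0), hi)
        assert small.voxels <= big.voxels

    def test_off_grid_center_gives_empty_mask(self, grid):
        assert len(dc.sphere_mask(grid, (500.0, 500.0, 500.0), 5.0)) == 0


class TestIntersectWithThreshold:
    def test_identity_annihilation_and_brute_force(self, grid, rng):
        mask = dc.sphere_mask(grid, (10.0, 10.0, 10.0), 8.0)
        stat = rng.normal(size=grid.dims)
        assert dc.intersect_with_threshold(mask, stat, -np.inf).voxels == mask.voxels
        assert len(dc.intersect_with_threshold(mask, stat, stat.max())) == 0
        out = dc.intersect_with_threshold(mask, stat, 0.5)
        assert out.voxels == {v for v in mask.voxels if stat[v] > 0.5}

    def test_grid_mismatch_rejected(self, grid):
        mask = dc.sphere_mask(grid, (10.0, 10.0, 10.0), 4.0)
        with pytest.raises(ValueError):
            dc.intersect_with_threshold(mask, np.zeros((3, 3, 3)), 0.0)


class TestTemplateFitScore:
    def test_indicator_map_scores_one(self, grid):
        spheres = [dc.sphere_mask(grid, (6.0, 6.0, 6.0), 4.0),
                   dc.sphere_mask(grid, (16.0, 16.0, 12.0), 4.0)]
        comp = np.zeros(grid.dims)
        for sph in spheres:
            comp[sph.indices()] = 1.0
        assert dc.template_fit_score(comp, spheres) == pytest.approx(1.0)

    def test_constant_map_scores_zero(self, grid):
        spheres = [dc.sphere_mask(grid, (6.0, 6.0, 6.0), 4.0)]
        assert dc.template_fit_score(np.full(grid.dims, 3.7), spheres) == pytest.approx(0.0)

    def test_matches_hand_enumeration_on_toy_map(self, rng):
        grid = VoxelGrid(dims=(4, 4, 4))
        sphere = VoxelMask(grid, frozenset({(0, 0, 0), (1, 1, 1), (2, 2, 2)}))
        comp = rng.normal(size=(4, 4, 4))
        inside = [comp[0, 0, 0], comp[1, 1, 1], comp[2, 2, 2]]
        outside = [comp[v] for v in np.ndindex(4, 4, 4)
                   if v not in sphere.voxels]
        expected = np.mean(inside) - np.mean(outside)
        assert dc.template_fit_score(comp, [sphere]) == pytest.approx(expected)

    def test_shift_invariance_and_linear_scaling(self, grid, rng):
        spheres = [dc.sphere_mask(grid, (8.0, 8.0, 8.0), 5.0)]
        comp = rng.normal(size=grid.dims)
        base = dc.template_fit_score(comp, spheres)
        assert dc.template_fit_score(comp + 11.0, spheres) == pytest.approx(base)
        assert dc.template_fit_score(3.0 * comp, spheres) == pytest.approx(3.0 * base)

    def test_best_component_selection_tie_breaks_low_index(self, grid):
        spheres = [dc.sphere_mask(grid, (8.0, 8.0, 8.0), 5.0)]
        good = np.zeros(grid.dims)
        good[spheres[0].indices()] = 2.0
        flat = np.zeros(grid.dims)
        idx, score = select_best_component([flat, good, good.copy()], spheres)
        assert idx == 1 and score == pytest.approx(dc.template_fit_score(good, spheres))


class TestExtractRoiTimeseries:
    def test_single_voxel_mask_returns_that_series(self, rng):
        grid = VoxelGrid(dims=(3, 3, 3))
        vols = rng.normal(size=(3, 3, 3, 20))
        mask = VoxelMask(grid, frozenset({(1, 2, 0)}))
        np.testing.assert_array_equal(
            dc.extract_roi_timeseries(vols, mask), vols[1, 2, 0]
        )

    def test_constant_volume(self):
        grid = VoxelGrid(dims=(3, 3, 3))
        vols = np.full((3, 3, 3, 5), 4.2)
        mask = VoxelMask(grid, frozenset({(0, 0, 0), (2, 2, 2)}))
        np.testing.assert_allclose(dc.extract_roi_timeseries(vols, mask), 4.2)

    def test_matches_brute_force_mean(self, rng):
        grid = VoxelGrid(dims=(4, 3, 2))
        vols = rng.normal(size=(4, 3, 2, 7))
        voxels = {(0, 1, 0), (3, 2, 1), (2, 0, 0)}
        mask = VoxelMask(grid, frozenset(voxels))
        expected = np.mean([vols[v] for v in voxels], axis=0)
        np.testing.assert_allclose(dc.extract_roi_timeseries(vols, mask), expected)

    def test_empty_mask_rejected(self):
        grid = VoxelGrid(dims=(2, 2, 2))
        with pytest.raises(ValueError):
            dc.extract_roi_timeseries(np.zeros((2, 2, 2, 3)),
                                      VoxelMask(grid, frozenset()))


def test_nifti_round_trip(tmp_path, rng):
    nib = pytest.importorskip("nibabel")
    from dmncausal.roi import load_nifti_volume, save_nifti_mask

    grid = VoxelGrid(dims=(6, 6, 6), voxel_size_mm=(3.0, 3.0, 3.0),
                     origin_mm=(-9.0, -9.0, -9.0))
    mask = dc.sphere_mask(grid, (0.0, 0.0, 0.0), 5.0)
    save_nifti_mask(mask, tmp_path / "mask.nii.gz")
    data, grid2 = load_nifti_volume(tmp_path / "mask.nii.gz")
    assert grid2 == grid
    recovered = {tuple(v) for v in np.argwhere(data > 0.5)}
    assert recovered == mask.voxels
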