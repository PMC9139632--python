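import numpy as np
import pytest

from bmseg.patching import (
    extract_all,
    extract_stack,
    merge_probabilities,
    plan_grid,
    stack_slice_indices,
)

from conftest import make_image, make_label


def brute_force_offsets(extent, patch, stride):
    """Independent enumeration: stride multiples plus a flush border window."""
    offs = []
    pos = 0
    while pos + patch <= extent:
        offs.append(pos)
        pos += stride
    if offs[-1] + patch < extent:
        offs.append(extent - patch)
    return offs


class TestPlanGrid:
    def test_clinical_slice_grid(self):
        grid = plan_grid(1024, 1024, 128, 64)
        assert len(grid.row_offsets) == len(grid.col_offsets) == 15
        assert grid.patches_per_slice == 225

    def test_patch_equals_slice(self):
        grid = plan_grid(128, 128, 128, 64)
        assert grid.row_offsets == (0,) and grid.col_offsets == (0,)

    def test_border_patch_appended(self):
        grid = plan_grid(200, 200, 128, 64)
        assert grid.row_offsets == (0, 64, 72)
        assert grid.col_offsets == (0, 64, 72)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_brute_force_on_random_geometry(self, trial, rng):
        r = np.random.default_rng(trial)
        patch = int(r.integers(4, 40))
        rows = int(r.integers(patch, 160))
        cols = int(r.integers(patch, 160))
        stride = int(r.integers(1, patch + 1))
        grid = plan_grid(rows, cols, patch, stride)
        assert list(grid.row_offsets) == brute_force_offsets(rows, patch, stride)
        assert list(grid.col_offsets) == brute_force_offsets(cols, patch, stride)
        # full coverage
        covered = np.zeros((rows, cols), dtype=bool)
        for a, b in grid.windows():
            covered[a : a + patch, b : b + patch] = True
        assert covered.all()

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            plan_grid(100, 100, 128, 64)


class TestExtractStack:
    def test_interior_slices_literal(self, rng):
        image = make_image(rng.random((9, 16, 16)))
        gt = make_label(np.zeros((9, 16, 16)))
        s = extract_stack(image, gt, z=4, row=0, col=0, patch_size=16)
        np.testing.assert_array_equal(s.data, image.data[2:7])

    def test_edge_replication_at_z0(self, rng):
        image = make_image(rng.random((6, 8, 8)))
        s = extract_stack(image, None, z=0, row=0, col=0, patch_size=8)
        assert stack_slice_indices(0, 6) == [0, 0, 0, 1, 2]
        np.testing.assert_array_equal(s.data[0], image.data[0])
        np.testing.assert_array_equal(s.data[1], image.data[0])
        np.testing.assert_array_equal(s.data[4], image.data[2])

    def test_empty_label_is_healthy(self, rng):
        image = make_image(rng.random((5, 8, 8)))
        gt = make_label(np.zeros((5, 8, 8)))
        gt.data[0, 0, 0] = 0
        s = extract_stack(image, gt, z=2, row=0, col=0, patch_size=8)
        assert not s.is_tumor

    def test_label_from_reference_slice_only(self, rng):
        image = make_image(rng.random((5, 8, 8)))
        gt_data = np.zeros((5, 8, 8), dtype=np.uint8)
        gt_data[1, 3, 3] = 1  # neighbour slice, not the reference
        gt = make_label(gt_data)
        s = extract_stack(image, gt, z=2, row=0, col=0, patch_size=8)
        assert not s.is_tumor
        s = extract_stack(image, gt, z=1, row=0, col=0, patch_size=8)
        assert s.is_tumor

    def test_off_volume_window_rejected(self, rng):
        image = make_image(rng.random((5, 8, 8)))
        with pytest.raises(ValueError):
            extract_stack(image, None, z=2, row=4, col=0, patch_size=8)


class TestExtractAll:
    def test_count_formula(self, rng):
        image = make_image(rng.random((10, 64, 64)))
        gt = make_label(np.zeros((10, 64, 64)))
        grid = plan_grid(64, 64, 16, 8)
        stacks = list(extract_all(image, gt, grid))
        assert len(stacks) == 10 * grid.patches_per_slice

    def test_single_window_volume(self, rng):
        image = make_image(rng.random((1, 16, 16)))
        grid = plan_grid(16, 16, 16, 8)
        assert len(list(extract_all(image, None, grid))) == 1

    def test_tumor_count_matches_window_intersection(self, rng):
        image = make_image(rng.random((6, 32, 32)))
        gt_data = np.zeros((6, 32, 32), dtype=np.uint8)
        gt_data[2:4, 10:14, 20:25] = 1
        gt = make_label(gt_data)
        grid = plan_grid(32, 32, 16, 8)
        got = sum(p.is_tumor for p in extract_all(image, gt, grid))
        expected = 0
        for z in range(6):
            for r, c in grid.windows():
                expected += bool(gt_data[z, r : r + 16, c : c + 16].any())
        assert got == expected

    def test_misaligned_shapes_rejected(self, rng):
        image = make_image(rng.random((5, 16, 16)))
        gt = make_label(np.zeros((4, 16, 16)))
        grid = plan_grid(16, 16, 16, 8)
        with pytest.raises(ValueError):
            list(extract_all(image, gt, grid))


class TestMerge:
    def test_mean_of_two_overlapping(self):
        p1 = np.full((4, 4), 0.4)
        p2 = np.full((4, 4), 0.8)
        out = merge_probabilities([(0, 0, p1), (0, 2, p2)], 4, 6)
        assert out[0, 3] == pytest.approx(0.6)  # overlap region
        assert out[0, 0] == pytest.approx(0.4)
        assert out[0, 5] == pytest.approx(0.8)

    def test_constant_patches_merge_to_constant(self):
        grid = plan_grid(20, 20, 8, 4)
        patches = [(r, c, np.full((8, 8), 0.7)) for r, c in grid.windows()]
        np.testing.assert_allclose(merge_probabilities(patches, 20, 20), 0.7)

    @pytest.mark.parametrize("rows,cols,patch,stride", [
        (32, 32, 8, 4), (30, 26, 8, 3), (64, 64, 16, 16),
    ])
    def test_cut_then_merge_round_trip(self, rows, cols, patch, stride, rng):
        target = rng.random((rows, cols))
        grid = plan_grid(rows, cols, patch, stride)
        patches = [
            (r, c, target[r : r + patch, c : c + patch]) for r, c in grid.windows()
        ]
        out = merge_probabilities(patches, rows, cols)
        np.testing.assert_allclose(out, target, atol=1e-12)

    def test_uncovered_pixel_raises(self):
        with pytest.raises(ValueError, match="not covered"):
            merge_probabilities([(0, 0, np.zeros((2, 2)))], 4, 4)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            merge_probabilities([(0, 0, np.full((2, 2), 1.5))], 2, 2)
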