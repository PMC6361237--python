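"""Mask primitives: thresholding, disk rasterization, dilation and CDNF."""

import math

import numpy as np
import pytest
from scipy import ndimage

from circoast.imaging import (BinaryMask, CdnfValue, CellModel,
                              ColocObservation, compute_cdnf,
                              count_colocalized, dilate_network, disk_element,
                              effective_cell_model, pool_cdnf,
                              quantify_connected_components,
                              segment_global_threshold, stamp_cells)


def brute_disk_count(radius: float) -> int:
    """Enumeration oracle: integer offsets with dx^2+dy^2 <= r^2."""
    r = int(math.ceil(radius))
    return sum(1 for dx in range(-r, r + 1) for dy in range(-r, r + 1)
               if dx * dx + dy * dy <= radius * radius)


class TestSegmentation:
    def test_all_zero_image_gives_empty_mask(self):
        mask = segment_global_threshold(np.zeros((4, 5), dtype=np.uint8), 1)
        assert not mask.grid.any()

    def test_threshold_is_inclusive(self):
        img = np.full((3, 3), 7, dtype=np.uint8)
        assert segment_global_threshold(img, 7).grid.all()

    def test_counts_pixels_at_or_above_threshold(self):
        img = np.arange(9, dtype=np.uint8).reshape(3, 3)
        assert segment_global_threshold(img, 5).grid.sum() == 4

    def test_rejects_multichannel_with_hint(self):
        with pytest.raises(ValueError, match="channel"):
            segment_global_threshold(np.zeros((3, 3, 3), dtype=np.uint8), 1)

    def test_rejects_out_of_range_threshold(self):
        with pytest.raises(ValueError, match="range"):
            segment_global_threshold(np.zeros((3, 3), dtype=np.uint8), 300)


class TestDiskElement:
    @pytest.mark.parametrize("radius, pixels", [
        (0.5, 1), (1.0, 5), (2.0, 13), (2.5, 21), (3.0, 29), (5.0, 81)])
    def test_pixel_counts_match_enumeration(self, radius, pixels):
        assert disk_element(radius).sum() == brute_disk_count(radius) == pixels

    def test_four_fold_symmetry_and_odd_side(self):
        d = disk_element(3.7)
        assert d.shape[0] % 2 == 1 and d.shape[0] == d.shape[1]
        assert np.array_equal(d, d[::-1]) and np.array_equal(d, d[:, ::-1])
        assert np.array_equal(d, d.T)

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValueError):
            disk_element(0.4)


class TestDilation:
    def test_empty_and_full_masks_are_fixed_points(self, cell10):
        empty = BinaryMask(np.zeros((16, 16), dtype=bool))
        full = BinaryMask(np.ones((16, 16), dtype=bool))
        assert not dilate_network(empty, cell10).grid.any()
        assert dilate_network(full, cell10).grid.all()

    def test_single_center_pixel_stamps_the_disk(self):
        grid = np.zeros((21, 21), dtype=bool)
        grid[10, 10] = True
        out = dilate_network(BinaryMask(grid), CellModel(4.0))  # radius 2
        assert out.grid.sum() == 13

    @pytest.mark.parametrize("radius", [0.5, 1.0, 2.0, 2.5, 3.0, 4.5])
    def test_matches_binary_dilation_with_shared_disk(self, rng, radius):
        """EDT-threshold dilation equals morphological dilation with the
        shared disk rasterization on random masks."""
        for _ in range(5):
            grid = rng.random((64, 64)) < 0.02
            expected = ndimage.binary_dilation(grid,
                                               structure=disk_element(radius))
            got = dilate_network(BinaryMask(grid), CellModel(2 * radius)).grid
            assert np.array_equal(got, expected)

    def test_membership_equals_brute_force_overlap(self, rng):
        """A center is in the dilated mask iff a disk placed there overlaps
        the raw network by >= 1 pixel (clipped at image bounds)."""
        grid = rng.random((48, 48)) < 0.01
        cell = CellModel(6.0)
        dilated = dilate_network(BinaryMask(grid), cell)
        for _ in range(200):
            x = int(rng.integers(0, 48))
            y = int(rng.integers(0, 48))
            stamp = stamp_cells([(x, y)], cell, 48, 48)
            overlap = bool((stamp.grid & grid).any())
            assert overlap == bool(dilated.grid[y, x])

    def test_result_contains_network(self, small_network, cell10):
        dil = dilate_network(small_network, cell10)
        assert (dil.grid | small_network.grid == dil.grid).all()

    def test_cdnf_monotone_in_radius_and_mask(self, small_network):
        ps = [compute_cdnf(small_network, CellModel(d)).p
              for d in (2, 4, 8, 16)]
        assert ps == sorted(ps)
        sub = BinaryMask(small_network.grid.copy())
        sub.grid[::2] = False
        assert (compute_cdnf(sub, CellModel(8)).p
                <= compute_cdnf(small_network, CellModel(8)).p)


class TestCdnfPooling:
    def test_empty_and_full_network_fractions(self, cell10):
        assert compute_cdnf(BinaryMask(np.zeros((8, 8), bool)), cell10).p == 0
        assert compute_cdnf(BinaryMask(np.ones((8, 8), bool)), cell10).p == 1

    def test_equal_area_pooling_averages(self):
        a = CdnfValue(20, 100)
        b = CdnfValue(40, 100)
        assert pool_cdnf([a, b]).p == pytest.approx(0.3)

    def test_single_value_identity(self):
        v = CdnfValue(7, 50)
        assert pool_cdnf([v]).p == v.p

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pool_cdnf([])

    def test_dilate_then_split_quadrants_pools_exactly(self, small_network,
                                                       cell10):
        """Splitting a dilated image into four sub-images and pooling
        reproduces the whole-image CDNF exactly."""
        whole = compute_cdnf(small_network, cell10)
        dil = dilate_network(small_network, cell10).grid
        h, w = dil.shape
        quads = [dil[:h // 2, :w // 2], dil[:h // 2, w // 2:],
                 dil[h // 2:, :w // 2], dil[h // 2:, w // 2:]]
        parts = [CdnfValue(int(q.sum()), q.size) for q in quads]
        pooled = pool_cdnf(parts)
        assert pooled.dilated_pixels == whole.dilated_pixels
        assert pooled.p == whole.p


class TestCountColocalized:
    def test_no_centers(self, small_network, cell10):
        obs = count_colocalized(np.empty((0, 2)), dilate_network(small_network,
                                                                 cell10))
        assert (obs.n, obs.c) == (0, 0)

    def test_all_true_mask_counts_everything(self):
        mask = BinaryMask(np.ones((10, 10), bool))
        obs = count_colocalized([(1, 2)] * 7, mask)
        assert (obs.n, obs.c) == (7, 7)

    def test_out_of_bounds_center_reports_index(self):
        mask = BinaryMask(np.ones((10, 10), bool))
        with pytest.raises(ValueError, match="index 1"):
            count_colocalized([(1, 1), (10, 3)], mask)

    def test_agrees_with_per_cell_overlap_oracle(self, rng):
        grid = rng.random((64, 64)) < 0.03
        cell = CellModel(7.0)
        dilated = dilate_network(BinaryMask(grid), cell)
        centers = np.column_stack([rng.integers(0, 64, 50),
                                   rng.integers(0, 64, 50)])
        obs = count_colocalized(centers, dilated)
        brute = sum(bool((stamp_cells([c], cell, 64, 64).grid & grid).any())
                    for c in centers)
        assert obs.c == brute and obs.n == 50


class TestCellQuantification:
    def test_effective_diameter_inverts_disk_area(self):
        assert effective_cell_model([math.pi * 25]).diameter == pytest.approx(10)
        assert effective_cell_model([math.pi * 4, math.pi * 16]).diameter == \
            pytest.approx(2 * math.sqrt(10))

    def test_effective_diameter_rejects_empty_input(self):
        with pytest.raises(ValueError):
            effective_cell_model([])

    def test_connected_components_empty_mask(self):
        count, mean = quantify_connected_components(
            BinaryMask(np.zeros((8, 8), bool)))
        assert count == 0 and math.isnan(mean)

    def test_two_disjoint_disks(self):
        mask = stamp_cells([(6, 6), (20, 20)], CellModel(4.0), 28, 28)
        assert quantify_connected_components(mask) == (2, 13.0)

    def test_disks_sharing_one_pixel_merge(self):
        # centers 4 px apart: the midpoint pixel is within radius 2 of both
        mask = stamp_cells([(10, 10), (14, 10)], CellModel(4.0), 28, 28)
        assert quantify_connected_components(mask) == (1, 25.0)

    def test_centroids_of_isolated_disks_are_the_centers(self):
        centers = [(6, 6), (20, 20)]
        mask = stamp_cells(centers, CellModel(4.0), 28, 28)
        _, _, cents = quantify_connected_components(mask, return_centroids=True)
        assert sorted(map(tuple, cents)) == sorted(centers)
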