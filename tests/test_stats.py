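"""Replicate pooling, pseudo-null one-sample test, permutation two-sample test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from circoast.imaging import (BinaryMask, CellModel, ColocObservation,
                              compute_cdnf, dilate_network)
from circoast.null_models import circoast_image_p
from circoast.placement_sim import place_cells_uniform
from circoast.stats import (ImageData, PerImageMetrics, bates_mean_cdf,
                            generic_group_stats, one_sample_circoast,
                            replicate_test, two_sample_circoast)

from conftest import STUDY_SEED


def half_mask(p_true=0.5):
    """Network whose CDNF at diameter 1 is exactly p_true."""
    grid = np.zeros((10, 10), bool)
    grid[:, :int(10 * p_true)] = True
    return BinaryMask(grid)


class TestReplicateTest:
    def test_single_image_equals_image_test(self, small_network, cell10):
        centers = place_cells_uniform(40, 128, 128, seed=STUDY_SEED)
        rep = replicate_test([ImageData(small_network, centers=centers)],
                             cell10)
        p = compute_cdnf(small_network, cell10)
        assert rep.circoast_p == circoast_image_p(rep.pooled_obs, p)

    def test_pooled_two_image_example(self):
        """(n=5,c=5) and (n=5,c=0) at CDNF 0.5 pool to P(X>=5 | 10, 0.5)."""
        cell = CellModel(1.0)  # radius 0.5: dilation is the identity
        imgs = [ImageData(half_mask(), observation=ColocObservation(5, 5)),
                ImageData(half_mask(), observation=ColocObservation(5, 0))]
        rep = replicate_test(imgs, cell)
        assert rep.pooled_obs.n == 10 and rep.pooled_obs.c == 5
        assert rep.pooled_cdnf.p == 0.5
        assert rep.circoast_p == pytest.approx(0.623046875, rel=1e-12)

    def test_quadrant_split_preserves_p(self, small_network, cell10):
        """Dilate-then-split into four sub-images gives the identical pooled
        test to the whole image."""
        centers = place_cells_uniform(60, 128, 128, seed=STUDY_SEED + 2)
        whole = replicate_test([ImageData(small_network, centers=centers)],
                               cell10)
        dil = dilate_network(small_network, cell10).grid
        obs_parts, cdnf_parts = [], []
        imgs = []
        for qy in (0, 64):
            for qx in (0, 64):
                quad = dil[qy:qy + 64, qx:qx + 64]
                sel = ((centers[:, 0] >= qx) & (centers[:, 0] < qx + 64) &
                       (centers[:, 1] >= qy) & (centers[:, 1] < qy + 64))
                sub = centers[sel] - [qx, qy]
                c = int(quad[sub[:, 1], sub[:, 0]].sum())
                # sub-image CDNF taken from the pre-split dilation
                imgs.append(ImageData(
                    BinaryMask(quad), observation=ColocObservation(len(sub), c)))
        cell1 = CellModel(1.0)  # identity dilation: quads are already dilated
        split = replicate_test(imgs, cell1)
        assert split.pooled_obs.n == whole.pooled_obs.n
        assert split.pooled_obs.c == whole.pooled_obs.c
        assert split.pooled_cdnf.p == whole.pooled_cdnf.p
        assert split.circoast_p == whole.circoast_p

    def test_zero_total_cells_rejected(self, small_network, cell10):
        img = ImageData(small_network, observation=ColocObservation(0, 0))
        with pytest.raises(ValueError, match="zero cells"):
            replicate_test([img], cell10)


class TestBatesCdf:
    @pytest.mark.parametrize("m, n, expected", [
        (0.3, 1, 0.3),
        (0.25, 2, 0.125),      # 2m^2 for m <= 1/2
        (0.5, 1, 0.5), (0.5, 2, 0.5), (0.5, 7, 0.5),  # symmetry
        (0.75, 2, 0.875),
        (0.0, 3, 0.0), (1.0, 3, 1.0),
    ])
    def test_known_values(self, m, n, expected):
        assert bates_mean_cdf(m, n) == pytest.approx(expected, abs=1e-12)

    def test_matches_irwin_hall_via_uniform_convolution(self):
        # numerical oracle: convolve N uniform densities on a fine grid
        N = 4
        h = 1e-4
        grid = np.ones(int(1 / h))
        dens = grid.copy()
        for _ in range(N - 1):
            dens = np.convolve(dens, grid) * h
        xs = np.arange(dens.size) * h
        for m in (0.2, 0.35, 0.5, 0.8):
            numeric = dens[xs <= m * N].sum() * h
            assert bates_mean_cdf(m, N) == pytest.approx(numeric, abs=1e-3)


class TestOneSample:
    def test_single_replicate_percentile_is_uniform(self):
        res = one_sample_circoast([0.3], trials=100_000, seed=STUDY_SEED)
        se = math.sqrt(0.3 * 0.7 / 100_000)
        assert abs(res.one_sample_p - 0.3) <= 4 * se

    def test_two_replicates_match_analytic(self):
        res = one_sample_circoast([0.2, 0.3], trials=100_000, seed=STUDY_SEED)
        q = bates_mean_cdf(0.25, 2)
        se = math.sqrt(q * (1 - q) / 100_000)
        assert abs(res.one_sample_p - q) <= 4 * se

    def test_all_zero_pvalues_bounded_by_add_one_guard(self):
        res = one_sample_circoast([0.0, 0.0, 0.0], trials=10_000, seed=1)
        assert res.one_sample_p == pytest.approx(1 / 10_001)

    def test_analytic_method(self):
        res = one_sample_circoast([0.2, 0.3], method="analytic")
        assert res.one_sample_p == pytest.approx(0.125)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            one_sample_circoast([])


def brute_force_ranksum_permutation_p(a, b):
    """Oracle: enumerate all splits; two-sided rank-sum p-values are a
    monotone transform of |W - E[W]|, so count splits at least as extreme."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    e_w = n_a * (len(pooled) + 1) / 2
    obs = abs(ranks[:n_a].sum() - e_w)
    stats = [abs(ranks[list(idx)].sum() - e_w)
             for idx in itertools.combinations(range(len(pooled)), n_a)]
    return np.mean([s >= obs - 1e-9 for s in stats])


class TestTwoSample:
    def test_identical_multisets_are_degenerate(self):
        with pytest.warns(UserWarning, match="tied"):
            res = two_sample_circoast([0.2, 0.2], [0.2, 0.2],
                                      permutations=1000)
        assert res.two_sample_p == 1.0 and res.degenerate

    @pytest.mark.parametrize("a, b", [
        ([0.01, 0.2, 0.11], [0.5, 0.6, 0.9]),
        ([0.3, 0.1, 0.25, 0.7], [0.2, 0.8, 0.65, 0.9]),
    ])
    def test_exhaustive_matches_brute_force(self, a, b):
        res = two_sample_circoast(a, b, test="ranksum", permutations=10_000,
                                  seed=1)
        assert res.exhaustive
        assert res.two_sample_p == pytest.approx(
            brute_force_ranksum_permutation_p(a, b), abs=1e-12)

    def test_monte_carlo_mode_agrees_with_exhaustive(self):
        a = [0.05, 0.12, 0.3, 0.2, 0.18]
        b = [0.4, 0.55, 0.3, 0.8, 0.25]
        ex = two_sample_circoast(a, b, permutations=10_000)
        mc = two_sample_circoast(a, b, permutations=20_000, seed=STUDY_SEED,
                                 exhaustive=False)
        se = math.sqrt(ex.two_sample_p * (1 - ex.two_sample_p) / 20_000)
        assert abs(mc.two_sample_p - ex.two_sample_p) <= 4 * se + 1e-4

    def test_type_one_error_calibrated(self):
        """Random labels on null data reject at ~alpha."""
        rng = np.random.default_rng(STUDY_SEED)
        rejections = 0
        runs = 300
        for _ in range(runs):
            vals = rng.random(8)
            res = two_sample_circoast(vals[:4], vals[4:], permutations=1000)
            rejections += res.two_sample_p <= 0.05
        rate = rejections / runs
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / runs)

    def test_t_statistic_mode(self):
        res = two_sample_circoast([0.1, 0.2, 0.15], [0.7, 0.8, 0.75],
                                  test="t", permutations=1000)
        assert res.two_sample_p == pytest.approx(1 / math.comb(6, 3) * 2)


class TestGenericStats:
    def records(self, cs, n=50, length=1000.0):
        return [PerImageMetrics(c, n, length) for c in cs]

    def test_identical_groups_not_significant(self):
        a = self.records([5, 8, 11, 7])
        res = generic_group_stats(a, self.records([5, 8, 11, 7]))
        assert all(p == pytest.approx(1.0) for p in res.p_values.values())

    def test_doubled_counts_shrink_per_fov_p(self):
        base = [5, 8, 11, 7, 9]
        res1 = generic_group_stats(self.records(base),
                                   self.records([c + 1 for c in base]))
        res2 = generic_group_stats(self.records(base),
                                   self.records([c * 2 for c in base]))
        assert res2.p_values["coloc_per_fov"] < res1.p_values["coloc_per_fov"]

    def test_hand_computed_toy_manifest(self):
        # image 1: 4/20 cells on 2 mm of vessel; image 2: 6/30 on 3 mm
        a = [PerImageMetrics(4, 20, 2000.0), PerImageMetrics(6, 30, 3000.0)]
        b = [PerImageMetrics(2, 20, 2000.0), PerImageMetrics(4, 30, 3000.0)]
        res = generic_group_stats(a, b)
        assert res.metrics_a["coloc_per_fov"] == [4.0, 6.0]
        assert res.metrics_a["coloc_per_mm"] == pytest.approx([2.0, 2.0])
        assert res.metrics_a["coloc_fraction"] == pytest.approx([0.2, 0.2])
        t, p = sps.ttest_ind([4, 6], [2, 4])
        assert res.p_values["coloc_per_fov"] == pytest.approx(float(p))

    def test_zero_length_image_excluded_with_warning(self):
        a = [PerImageMetrics(4, 20, 0.0), PerImageMetrics(6, 30, 3000.0),
             PerImageMetrics(5, 25, 2500.0)]
        b = self.records([2, 3, 4])
        with pytest.warns(UserWarning, match="zero vessel length"):
            res = generic_group_stats(a, b)
        assert len(res.metrics_a["coloc_per_mm"]) == 2
        assert res.excluded == 1
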