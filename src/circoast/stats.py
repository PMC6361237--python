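"""Group-level colocalization statistics.

Single-image binomial p-values are combined in three stages:

* per biological replicate, images are pooled (area-weighted CDNF, summed
  cell counts) and one binomial tail p-value is computed;
* a study group of N replicates is tested against a simulated pseudo-null of
  mean p-values — under the null each replicate p-value is Uniform(0, 1), so
  the null mean follows the Bates distribution (mean of N uniforms), which
  is also available analytically as an Irwin–Hall sum;
* two study groups are compared by a two-sample test (Wilcoxon rank-sum by
  default, or Student's t) on the replicate p-values, calibrated by
  permutation of the group labels.

The generic per-image metrics (colocalized count per field of view, per
vessel length, and colocalized fraction) are provided for comparison; they
are confounded by cell and network density, which is the failure mode the
permutation-calibrated test avoids.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .imaging import (BinaryMask, CdnfValue, CellModel, ColocObservation,
                      compute_cdnf, count_colocalized, dilate_network,
                      pool_cdnf)
from .null_models import circoast_image_p


# --------------------------------------------------------------------------
# replicate pooling
# --------------------------------------------------------------------------


@dataclass
class ImageData:
    """One field of view: the network mask plus the observed cells.

    Cells may be given as centers (colocalization is then counted against
    the dilated network) or as a precomputed (n, c) observation.
    """

    network: BinaryMask
    centers: np.ndarray | None = None
    observation: ColocObservation | None = None

    def __post_init__(self) -> None:
        if (self.centers is None) == (self.observation is None):
            raise ValueError("provide exactly one of centers or observation")


@dataclass
class ReplicateResult:
    replicate_id: str
    observations: list[ColocObservation]
    cdnf_values: list[CdnfValue]
    pooled_cdnf: CdnfValue
    pooled_obs: ColocObservation
    circoast_p: float


@dataclass
class GroupResult:
    replicate_p_values: list[float]
    observed_mean_p: float
    one_sample_p: float
    trials: int
    method: str
    seed: int | None = None


@dataclass
class ComparisonResult:
    group_a: list[float]
    group_b: list[float]
    test: str
    observed_p: float
    two_sample_p: float
    permutations: int
    exhaustive: bool
    seed: int | None = None
    degenerate: bool = False


def replicate_test(images: list[ImageData], cell: CellModel,
                   replicate_id: str = "") -> ReplicateResult:
    """Pool images of one biological replicate and test colocalization.

    The pooled CDNF is the combined dilated-pixel fraction across images and
    cell counts are summed, so sampling sufficiency is governed by the total
    number of cells rather than by fields of view.
    """
    if not images:
        raise ValueError("replicate contains no images")
    cdnfs, obs = [], []
    for img in images:
        cdnfs.append(compute_cdnf(img.network, cell))
        if img.observation is not None:
            obs.append(img.observation)
        else:
            obs.append(count_colocalized(img.centers,
                                         dilate_network(img.network, cell)))
    pooled_c = pool_cdnf(cdnfs)
    pooled_o = ColocObservation(sum(o.n for o in obs), sum(o.c for o in obs))
    if pooled_o.n == 0:
        raise ValueError("replicate has zero cells in total; test undefined")
    return ReplicateResult(replicate_id, obs, cdnfs, pooled_c, pooled_o,
                           circoast_image_p(pooled_o, pooled_c))


# --------------------------------------------------------------------------
# one-sample test (pseudo-null of mean uniform p-values)
# --------------------------------------------------------------------------


def bates_mean_cdf(m: float, N: int) -> float:
    """Exact CDF of the mean of N iid Uniform(0,1) variables (Bates).

    Irwin–Hall piecewise polynomial evaluated at x = N·m:
    P(sum <= x) = (1/N!) Σ_{k=0}^{floor(x)} (−1)^k C(N,k) (x−k)^N.
    Numerically adequate in double precision for N up to ~100.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if m <= 0:
        return 0.0
    if m >= 1:
        return 1.0
    x = N * m
    total = 0.0
    for k in range(int(math.floor(x)) + 1):
        total += (-1) ** k * math.comb(N, k) * (x - k) ** N
    total /= math.factorial(N)
    return float(min(max(total, 0.0), 1.0))


def one_sample_circoast(p_values, trials: int = 10_000_000, seed=None,
                        method: str = "simulation",
                        chunk: int = 1_000_000) -> GroupResult:
    """Test a study group for enriched colocalization.

    The observed statistic is the mean of the replicate p-values.  Its null
    distribution (each p-value Uniform(0,1)) is simulated by drawing
    ``trials`` sets of N uniforms; the left-tail fraction of null means at
    or below the observed mean is the group p-value, reported with the
    add-one Monte-Carlo correction so it is never exactly zero.  With
    ``method="analytic"`` the exact Bates CDF is used instead (no trials).
    """
    p_values = [float(p) for p in p_values]
    if not p_values:
        raise ValueError("no replicate p-values provided")
    if any(not 0 <= p <= 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    n_rep = len(p_values)
    observed = float(np.mean(p_values))
    if method == "analytic":
        return GroupResult(p_values, observed, bates_mean_cdf(observed, n_rep),
                           0, "analytic", None)
    if method != "simulation":
        raise ValueError(f"unknown method {method!r}")
    if trials < 10_000:
        raise ValueError("need at least 10^4 pseudo-null trials")
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < trials:
        size = min(chunk, trials - done)
        means = rng.random((size, n_rep)).mean(axis=1)
        count += int((means <= observed).sum())
        done += size
    p = (1 + count) / (trials + 1)
    return GroupResult(p_values, observed, p, trials, "simulation",
                       seed if isinstance(seed, int) else None)


# --------------------------------------------------------------------------
# two-sample permutation test
# --------------------------------------------------------------------------


def _ranksum_pvalues(pooled: np.ndarray, idx_a: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation Wilcoxon rank-sum p-values for a batch
    of group-A index sets (rows of ``idx_a``)."""
    n_tot = pooled.size
    n_a = idx_a.shape[1]
    n_b = n_tot - n_a
    ranks = sps.rankdata(pooled)
    w = ranks[idx_a].sum(axis=1)
    expect = n_a * (n_tot + 1) / 2.0
    sd = math.sqrt(n_a * n_b * (n_tot + 1) / 12.0)
    z = (w - expect) / sd
    return 2.0 * sps.norm.sf(np.abs(z))


def _ttest_pvalues(pooled: np.ndarray, idx_a: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance t-test p-values for a batch of splits."""
    n_tot = pooled.size
    n_a = idx_a.shape[1]
    n_b = n_tot - n_a
    tot = pooled.sum()
    tot2 = (pooled ** 2).sum()
    sum_a = pooled[idx_a].sum(axis=1)
    sum2_a = (pooled[idx_a] ** 2).sum(axis=1)
    sum_b = tot - sum_a
    sum2_b = tot2 - sum2_a
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    ss_a = sum2_a - n_a * mean_a ** 2
    ss_b = sum2_b - n_b * mean_b ** 2
    df = n_a + n_b - 2
    pooled_var = (ss_a + ss_b) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(pooled_var * (1 / n_a + 1 / n_b))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return np.where(np.isfinite(t), p, 1.0)


_TEST_FUNCS = {"ranksum": _ranksum_pvalues, "t": _ttest_pvalues}


def two_sample_circoast(group_a, group_b, test: str = "ranksum",
                        permutations: int = 10_000_000, seed=None,
                        exhaustive: str | bool = "auto") -> ComparisonResult:
    """Compare colocalization affinity between two study groups.

    The observed statistic is the p-value of a two-sample test (Wilcoxon
    rank-sum or pooled t) on the groups' replicate p-values.  Group labels
    are then permuted; the reported p-value is the fraction of permuted test
    p-values at or below the observed one.  When the number of distinct
    label assignments is at most ``permutations`` (and ``exhaustive`` is not
    False) all splits are enumerated and the fraction is exact; otherwise
    labels are resampled uniformly with the add-one correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if test not in _TEST_FUNCS:
        raise ValueError(f"test must be one of {sorted(_TEST_FUNCS)}")
    if permutations < 1_000:
        raise ValueError("need at least 10^3 permutations")
    pooled = np.concatenate([a, b])
    n_tot, n_a = pooled.size, a.size
    pfunc = _TEST_FUNCS[test]
    observed = float(pfunc(pooled, np.arange(n_a)[None, :])[0])

    if np.unique(pooled).size == 1:
        warnings.warn("all values tied across both groups; comparison is "
                      "degenerate", stacklevel=2)
        return ComparisonResult(list(a), list(b), test, observed, 1.0, 0,
                                False, None, degenerate=True)

    n_splits = math.comb(n_tot, n_a)
    use_exhaustive = (exhaustive is True or
                      (exhaustive == "auto" and n_splits <= permutations))
    if use_exhaustive:
        idx = np.array(list(itertools.combinations(range(n_tot), n_a)))
        perm_p = pfunc(pooled, idx)
        two_p = float((perm_p <= observed + 1e-12).mean())
        return ComparisonResult(list(a), list(b), test, observed, two_p,
                                n_splits, True,
                                seed if isinstance(seed, int) else None)
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    batch = 100_000
    while done < permutations:
        size = min(batch, permutations - done)
        idx = np.argsort(rng.random((size, n_tot)), axis=1)[:, :n_a]
        perm_p = pfunc(pooled, idx)
        count += int((perm_p <= observed + 1e-12).sum())
        done += size
    two_p = (1 + count) / (permutations + 1)
    return ComparisonResult(list(a), list(b), test, observed, two_p,
                            permutations, False,
                            seed if isinstance(seed, int) else None)


# --------------------------------------------------------------------------
# generic (density-confounded) per-image statistics
# --------------------------------------------------------------------------


@dataclass
class PerImageMetrics:
    """Generic per-image colocalization metrics input record."""

    c: int
    n: int
    centerline_length_px: float
    pixel_size: float = 1.0  # µm per pixel


@dataclass
class GenericStatsResult:
    metrics_a: dict
    metrics_b: dict
    p_values: dict
    excluded: int = 0


def generic_group_stats(records_a: list[PerImageMetrics],
                        records_b: list[PerImageMetrics]) -> GenericStatsResult:
    """Three density-confounded metrics compared by unpaired t-tests.

    Per image: colocalized count per field of view; colocalized count per
    1 mm of vessel centerline; fraction of cells colocalizing.  Images with
    zero vessel length or zero cells are excluded from the affected metric.
    """
    excluded = 0

    def extract(records):
        nonlocal excluded
        per_fov, per_mm, frac = [], [], []
        for r in records:
            per_fov.append(float(r.c))
            length_mm = r.centerline_length_px * r.pixel_size / 1000.0
            if length_mm > 0:
                per_mm.append(r.c / length_mm)
            else:
                excluded += 1
                warnings.warn("image with zero vessel length excluded from "
                              "per-length metric", stacklevel=3)
            if r.n > 0:
                frac.append(r.c / r.n)
            else:
                excluded += 1
                warnings.warn("image with zero cells excluded from "
                              "colocalized-fraction metric", stacklevel=3)
        return {"coloc_per_fov": per_fov, "coloc_per_mm": per_mm,
                "coloc_fraction": frac}

    ma, mb = extract(records_a), extract(records_b)
    pvals = {}
    for key in ma:
        res = sps.ttest_ind(ma[key], mb[key])
        pvals[key] = float(res.pvalue)
    return GenericStatsResult(ma, mb, pvals, excluded)
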