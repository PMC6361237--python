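"""In-silico validation experiments.

These experiments exercise the whole pipeline on synthetic data:

* a randomized parameter sweep establishing that the CDNF — and no other
  structural parameter — determines the mean ICF under random placement
  (Pearson correlations and z-scored multivariable linear regression);
* a Bland–Altman comparison of the closed-form binomial model against the
  Monte Carlo model;
* a density-confound design showing that generic colocalization metrics
  produce false positives when cell and vessel density differ between
  groups of randomly placed cells, while the permutation-calibrated test
  stays at its nominal level;
* a miscounting experiment where overlapping cells are quantified as merged
  connected components, inflating the one-sample false-positive rate unless
  the effective mean-area disk correction is applied;
* a check that heterogeneous cell diameters are well approximated by a
  single mean-diameter disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, stats as sps

from ._seeds import as_seed_sequence
from .imaging import (BinaryMask, CellModel, ColocObservation, compute_cdnf,
                      count_colocalized, dilate_network, effective_cell_model,
                      stamp_cells)
from .network_synthesis import (NetworkParams, generate_network,
                                skeleton_length)
from .placement_sim import icf_samples, place_cells_uniform
from .null_models import circoast_image_p
from .stats import (PerImageMetrics, bates_mean_cdf, generic_group_stats,
                    two_sample_circoast)

PREDICTORS = ["cell_diameter", "cell_number", "network_radius",
              "network_fraction", "length_density", "cdnf"]

#: Default randomized-sweep parameter ranges (uniform draws).  Image size is
#: 512x512; ranges are chosen to span the vessel densities of vascularized
#: tissues (mask fractions roughly 0.05-0.6 before dilation) and typical
#: cell sizes at this resolution.
DEFAULT_RANGES = {
    "width": 512,
    "height": 512,
    "min_point_distance": 24.0,
    "cell_diameter": (6.0, 30.0),
    "cell_number": (50, 300),
    "network_radius": (2, 10),
    "target_fraction": (0.05, 0.6),
}


@dataclass
class SweepRecord:
    """One simulated experiment: structural parameters, CDNF and model means."""

    cell_diameter: float
    cell_number: int
    network_radius: float
    network_fraction: float
    length_density: float
    cdnf: float
    mcmrp_mean_icf: float
    trials: int
    seed: int

    @property
    def bmrp_mean_icf(self) -> float:
        # the binomial model's mean ICF is the CDNF itself (μ/n = p)
        return self.cdnf


@dataclass
class RegressionSummary:
    coefficients: pd.Series
    std_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    r_squared: float
    f_statistic: float
    f_pvalue: float
    condition_number: float


def _draw_params(rng, ranges):
    lo, hi = ranges["cell_diameter"]
    diameter = float(rng.uniform(lo, hi))
    lo, hi = ranges["cell_number"]
    number = int(rng.integers(lo, hi + 1))
    lo, hi = ranges["network_radius"]
    radius = int(rng.integers(lo, hi + 1))
    lo, hi = ranges["target_fraction"]
    target = float(rng.uniform(lo, hi))
    return diameter, number, radius, target


def simulate_image(ranges, trials: int, seed) -> SweepRecord:
    """Generate one random network, compute its CDNF and MCMRP mean ICF."""
    ss = as_seed_sequence(seed)
    s_param, s_net, s_mc = ss.spawn(3)
    rng = np.random.default_rng(s_param)
    diameter, number, radius, target = _draw_params(rng, ranges)
    net = generate_network(
        NetworkParams(ranges["width"], ranges["height"], network_radius=radius,
                      min_point_distance=ranges["min_point_distance"],
                      network_fraction=target), s_net)
    cell = CellModel(diameter)
    cdnf = compute_cdnf(net.mask, cell)
    dilated = dilate_network(net.mask, cell)
    samples = icf_samples(dilated.grid, number, trials,
                          np.random.default_rng(s_mc))
    seed_int = seed if isinstance(seed, int) else int(ss.entropy % (2**31))
    return SweepRecord(cell_diameter=diameter, cell_number=number,
                       network_radius=float(radius),
                       network_fraction=net.measured.network_fraction,
                       length_density=net.measured.length_density,
                       cdnf=cdnf.p, mcmrp_mean_icf=float(samples.mean()),
                       trials=trials, seed=seed_int)


def run_parameter_sweep(n_images: int, trials_per_image: int, seed=None,
                        ranges: dict | None = None) -> list[SweepRecord]:
    """Randomized parameter sweep of simulated colocalization experiments."""
    if n_images < 10:
        raise ValueError("need at least 10 images for a sweep")
    if trials_per_image < 100:
        raise ValueError("need at least 100 Monte Carlo trials per image")
    cfg = dict(DEFAULT_RANGES)
    if ranges:
        cfg.update(ranges)
    ss = as_seed_sequence(seed)
    records = []
    for child in ss.spawn(n_images):
        records.append(simulate_image(cfg, trials_per_image, child))
    return records


def sweep_frame(records: list[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_diameter": r.cell_diameter, "cell_number": r.cell_number,
        "network_radius": r.network_radius,
        "network_fraction": r.network_fraction,
        "length_density": r.length_density, "cdnf": r.cdnf,
        "mcmrp_mean_icf": r.mcmrp_mean_icf, "bmrp_mean_icf": r.bmrp_mean_icf,
        "trials": r.trials}
        for r in records])


def correlate_sweep(records: list[SweepRecord],
                    response: str = "mcmrp_mean_icf") -> pd.DataFrame:
    """Pearson r (with Fisher-z 95% CI and p-value) of each structural
    parameter against the mean ICF."""
    if len(records) < 10:
        raise ValueError("need at least 10 records")
    df = sweep_frame(records)
    rows = []
    y = df[response].to_numpy()
    for param in PREDICTORS:
        x = df[param].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"parameter": param, "r": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "degenerate": True})
            continue
        r, p = sps.pearsonr(x, y)
        z = np.arctanh(min(max(r, -1 + 1e-15), 1 - 1e-15))
        se = 1.0 / math.sqrt(len(df) - 3)
        lo, hi = np.tanh(z - 1.96 * se), np.tanh(z + 1.96 * se)
        rows.append({"parameter": param, "r": float(r), "ci_low": float(lo),
                     "ci_high": float(hi), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows)


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std(ddof=1)


def zscore_mvlr(records: list[SweepRecord],
                response: str = "mcmrp_mean_icf") -> RegressionSummary:
    """OLS of the z-scored response on the six z-scored structural
    parameters (with intercept), so coefficients share one scale."""
    df = sweep_frame(records)
    if len(df) < len(PREDICTORS) + 2:
        raise ValueError("not enough records for the regression")
    X = np.column_stack([_zscore(df[p].to_numpy(dtype=float))
                         for p in PREDICTORS])
    y = _zscore(df[response].to_numpy(dtype=float))
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; condition number "
            f"{np.linalg.cond(Xc):.3g} — check for duplicated or constant "
            "parameters")
    fit = sm.OLS(y, Xc).fit()
    names = ["intercept"] + PREDICTORS
    return RegressionSummary(
        coefficients=pd.Series(fit.params, index=names),
        std_errors=pd.Series(fit.bse, index=names),
        t_values=pd.Series(fit.tvalues, index=names),
        p_values=pd.Series(fit.pvalues, index=names),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue), f_pvalue=float(fit.f_pvalue),
        condition_number=float(np.linalg.cond(Xc)))


def bland_altman(pairs) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement for (BMRP, MCMRP) pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2 or pairs.shape[1] != 2:
        raise ValueError("need >= 2 (model_a, model_b) pairs")
    d = pairs[:, 0] - pairs[:, 1]
    mean = float(d.mean())
    spread = 1.96 * float(d.std(ddof=1))
    return mean, mean - spread, mean + spread


@dataclass
class ModelComparisonReport:
    mean_difference: float
    limits: tuple[float, float]
    paired_t_p: float
    frac_within_mc_bound: float
    discrepancy_mvlr: RegressionSummary


def compare_bmrp_mcmrp(records: list[SweepRecord]) -> ModelComparisonReport:
    """Binomial-vs-Monte-Carlo model comparison on a sweep.

    Per image the discrepancy is BMRP mean ICF (= CDNF) minus the MCMRP
    mean; the Monte-Carlo standard error of the latter is
    sqrt(p(1−p)/(n·trials)), so calibrated discrepancies should fall within
    ±1.96 of that bound about 95% of the time and carry no systematic
    parameter dependence.
    """
    df = sweep_frame(records)
    d = (df["bmrp_mean_icf"] - df["mcmrp_mean_icf"]).to_numpy()
    mean, lo, hi = bland_altman(df[["bmrp_mean_icf", "mcmrp_mean_icf"]].to_numpy())
    t_p = float(sps.ttest_rel(df["bmrp_mean_icf"], df["mcmrp_mean_icf"]).pvalue)
    p = df["cdnf"].to_numpy()
    n = df["cell_number"].to_numpy(dtype=float)
    trials = df["trials"].to_numpy(dtype=float)
    se = np.sqrt(np.maximum(p * (1 - p), 1e-300) / (n * trials))
    within = float((np.abs(d) <= 1.96 * se).mean())
    # regress the z-scored discrepancy on the z-scored parameters
    disc_records = records
    summary = _discrepancy_mvlr(disc_records, d)
    return ModelComparisonReport(mean, (lo, hi), t_p, within, summary)


def _discrepancy_mvlr(records, discrepancy: np.ndarray) -> RegressionSummary:
    df = sweep_frame(records)
    X = np.column_stack([_zscore(df[p].to_numpy(dtype=float))
                         for p in PREDICTORS])
    y = _zscore(discrepancy)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    names = ["intercept"] + PREDICTORS
    return RegressionSummary(pd.Series(fit.params, index=names),
                             pd.Series(fit.bse, index=names),
                             pd.Series(fit.tvalues, index=names),
                             pd.Series(fit.pvalues, index=names),
                             float(fit.rsquared), float(fit.fvalue),
                             float(fit.f_pvalue),
                             float(np.linalg.cond(sm.add_constant(X))))


# --------------------------------------------------------------------------
# density-confound experiment
# --------------------------------------------------------------------------


@dataclass
class GroupDesign:
    """Study-group simulation parameters for the confound experiment."""

    cell_number: int
    target_fraction: float
    cell_diameter: float = 10.0
    width: int = 256
    height: int = 256
    network_radius: int = 4
    min_point_distance: float = 20.0


@dataclass
class ConfoundRunReport:
    circoast_two_sample_p: float
    generic_p: dict
    replicate_p_a: list[float]
    replicate_p_b: list[float]


def _simulate_group(design: GroupDesign, n_replicates: int,
                    images_per_replicate: int, ss) -> tuple[list[float],
                                                            list[PerImageMetrics]]:
    cell = CellModel(design.cell_diameter)
    rep_ps, metrics = [], []
    for _ in range(n_replicates):
        pooled_dil, pooled_tot, n_sum, c_sum = 0, 0, 0, 0
        for child in ss.spawn(images_per_replicate):
            s_net, s_place = child.spawn(2)
            net = generate_network(
                NetworkParams(design.width, design.height,
                              network_radius=design.network_radius,
                              min_point_distance=design.min_point_distance,
                              network_fraction=design.target_fraction), s_net)
            dilated = dilate_network(net.mask, cell)
            centers = place_cells_uniform(design.cell_number, design.width,
                                          design.height, s_place)
            obs = count_colocalized(centers, dilated)
            pooled_dil += int(dilated.grid.sum())
            pooled_tot += dilated.grid.size
            n_sum += obs.n
            c_sum += obs.c
            metrics.append(PerImageMetrics(
                obs.c, obs.n,
                centerline_length_px=skeleton_length(net.skeleton.grid)))
        p = pooled_dil / pooled_tot
        rep_ps.append(circoast_image_p(ColocObservation(n_sum, c_sum), p))
    return rep_ps, metrics


def density_confound_experiment(n_replicates_per_group: int,
                                images_per_replicate: int,
                                dense: GroupDesign, sparse: GroupDesign,
                                seed=None,
                                permutations: int = 100_000) -> ConfoundRunReport:
    """Two-group design with truly random cells but different densities.

    Cells are placed uniformly at random in both groups, so a correct
    statistical analysis should find no colocalization difference; generic
    metrics nonetheless respond to the density differences.
    """
    ss = as_seed_sequence(seed)
    s_a, s_b, s_perm = ss.spawn(3)
    p_a, m_a = _simulate_group(dense, n_replicates_per_group,
                               images_per_replicate, s_a)
    p_b, m_b = _simulate_group(sparse, n_replicates_per_group,
                               images_per_replicate, s_b)
    comp = two_sample_circoast(p_a, p_b, test="ranksum",
                               permutations=permutations, seed=s_perm)
    gen = generic_group_stats(m_a, m_b)
    return ConfoundRunReport(comp.two_sample_p, gen.p_values, p_a, p_b)


def density_confound_rejection_rates(runs: int, n_replicates_per_group: int,
                                     images_per_replicate: int,
                                     dense: GroupDesign, sparse: GroupDesign,
                                     seed=None, alpha: float = 0.05) -> dict:
    """Repeated-run rejection rates at level alpha for each method."""
    ss = as_seed_sequence(seed)
    keys = ["circoast", "coloc_per_fov", "coloc_per_mm", "coloc_fraction"]
    rej = {k: 0 for k in keys}
    for child in ss.spawn(runs):
        rep = density_confound_experiment(n_replicates_per_group,
                                          images_per_replicate, dense, sparse,
                                          child)
        rej["circoast"] += rep.circoast_two_sample_p <= alpha
        for k in ("coloc_per_fov", "coloc_per_mm", "coloc_fraction"):
            rej[k] += rep.generic_p[k] <= alpha
    return {k: v / runs for k, v in rej.items()}


# --------------------------------------------------------------------------
# miscount experiment
# --------------------------------------------------------------------------


@dataclass
class MiscountReport:
    fp_rate_miscount: float
    fp_rate_mitigated: float
    fp_rate_truth: float
    mean_miscount_fraction: float
    group_p: pd.DataFrame


def miscount_experiment(n_groups: int, images_per_group: int,
                        cell_number: int, cell_diameter: float,
                        target_fraction: float = 0.25, width: int = 256,
                        height: int = 256, network_radius: int = 4,
                        min_point_distance: float = 20.0, seed=None,
                        alpha: float = 0.05) -> MiscountReport:
    """Effect of connected-components miscounting on the one-sample test.

    Cells are placed uniformly (overlap allowed) and quantified as
    8-connected components of the rendered cell mask, so touching cells
    merge.  An observed "cell" (component) colocalizes when any of its
    pixels overlap the network; merged components cover more area than one
    cell, so their colocalization frequency exceeds the single-cell CDNF.
    Three analysis conditions are compared: (a) component counts modeled at
    the nominal cell diameter, (b) component counts modeled at the
    effective mean-component-area diameter (mitigation), and (c)
    ground-truth centers and diameter.  Since all placement is random, any
    rejection of the one-sample test (analytic pseudo-null over the group's
    images) is a false positive.
    """
    cell = CellModel(cell_diameter)
    ss = as_seed_sequence(seed)
    rows = []
    miscount_fracs = []
    for g, g_ss in enumerate(ss.spawn(n_groups)):
        ps = {"miscount": [], "mitigated": [], "truth": []}
        for child in g_ss.spawn(images_per_group):
            s_net, s_place = child.spawn(2)
            net = generate_network(
                NetworkParams(width, height, network_radius=network_radius,
                              min_point_distance=min_point_distance,
                              network_fraction=target_fraction), s_net)
            centers = place_cells_uniform(cell_number, width, height, s_place)
            cell_mask = stamp_cells(centers, cell, width, height)
            labels, count = ndimage.label(cell_mask.grid,
                                          structure=np.ones((3, 3), bool))
            mean_area = float(cell_mask.grid.sum()) / count
            miscount_fracs.append(1.0 - count / cell_number)
            # components whose pixels overlap the network colocalize
            c_obs = int(np.unique(labels[net.mask.grid & (labels > 0)]).size)
            obs = ColocObservation(count, c_obs)

            # (a) merged components analyzed at the nominal cell diameter
            dil_true = dilate_network(net.mask, cell)
            ps["miscount"].append(
                circoast_image_p(obs, float(dil_true.grid.mean())))

            # (b) same observation at the effective mean-area diameter
            eff = effective_cell_model([mean_area])
            dil_eff = dilate_network(net.mask, eff)
            ps["mitigated"].append(
                circoast_image_p(obs, float(dil_eff.grid.mean())))

            # (c) ground truth
            obs_t = count_colocalized(centers, dil_true)
            ps["truth"].append(
                circoast_image_p(obs_t, float(dil_true.grid.mean())))
        row = {"group": g}
        for key, vals in ps.items():
            row[key] = bates_mean_cdf(float(np.mean(vals)), len(vals))
        rows.append(row)
    df = pd.DataFrame(rows)
    return MiscountReport(
        fp_rate_miscount=float((df["miscount"] <= alpha).mean()),
        fp_rate_mitigated=float((df["mitigated"] <= alpha).mean()),
        fp_rate_truth=float((df["truth"] <= alpha).mean()),
        mean_miscount_fraction=float(np.mean(miscount_fracs)),
        group_p=df)


# --------------------------------------------------------------------------
# heterogeneous-diameter check
# --------------------------------------------------------------------------


@dataclass
class HeterogeneityReport:
    mean_icf_heterogeneous: float
    mean_icf_mean_diameter: float
    abs_difference: float
    effect_size: float  # Cohen's d between the two trial ICF samples


def heterogeneous_diameter_check(diameter_low: float, diameter_high: float,
                                 network: BinaryMask, n: int, trials: int,
                                 seed=None) -> HeterogeneityReport:
    """Compare per-cell sampled diameters against one mean-diameter disk.

    Cell i colocalizes iff the network's Euclidean distance transform at its
    center is at most its own radius, so heterogeneous diameters are handled
    with a single distance transform.  Diameters are Uniform(low, high).
    The two models share the same placement draws (common random numbers),
    so a degenerate diameter distribution agrees exactly and the comparison
    is a paired one.
    """
    if not 1 <= diameter_low <= diameter_high:
        raise ValueError("need 1 <= diameter_low <= diameter_high")
    rng = np.random.default_rng(seed)
    dist = ndimage.distance_transform_edt(~network.grid)
    flat = rng.integers(0, dist.size, size=(trials, n))
    dvals = dist.reshape(-1)[flat]
    radii = rng.uniform(diameter_low / 2, diameter_high / 2, size=(trials, n))
    icf_het = (dvals <= radii).mean(axis=1)
    mean_r = (diameter_low + diameter_high) / 4.0
    icf_hom = (dvals <= mean_r).mean(axis=1)
    pooled_sd = math.sqrt((icf_het.var(ddof=1) + icf_hom.var(ddof=1)) / 2)
    diff = float(icf_het.mean() - icf_hom.mean())
    d = diff / pooled_sd if pooled_sd > 0 else 0.0
    return HeterogeneityReport(float(icf_het.mean()), float(icf_hom.mean()),
                               abs(diff), float(d))
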