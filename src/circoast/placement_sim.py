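"""Monte Carlo models of random cell placement.

The Monte Carlo model of random placement (MCMRP) spawns disk-shaped cells
at uniformly random pixel sites and records the intercellular colocalization
fraction (ICF) — the fraction of cells overlapping the network by at least
one pixel — per trial.  Variants place cells without pixel overlap (random
sequential adsorption of pixelated disks, with exact saturation detection)
and in clumps; the saturation process yields the packing ratio η that
parameterizes the hypergeometric model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._seeds import as_seed_sequence
from .imaging import (BinaryMask, CellModel, count_colocalized, dilate_network,
                      disk_element)

HEX_PACKING_RATIO = 0.901  # ideal hexagonal disk packing; upper bound for η


@dataclass
class ICFDistribution:
    """Empirical ICF distribution from repeated random-placement trials."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if ((self.samples < 0) | (self.samples > 1)).any():
            raise ValueError("ICF samples must lie in [0, 1]")

    @property
    def trials(self) -> int:
        return int(self.samples.size)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1)) if self.trials > 1 else 0.0


@dataclass(frozen=True)
class PackingEntry:
    """Monte-Carlo packing ratio for one (cell diameter, image size) key."""

    diameter: int
    width: int
    height: int
    eta: float
    sd: float
    trials: int

    def __post_init__(self) -> None:
        if self.diameter < 5:
            raise ValueError("packing is only defined for diameters >= 5 px")
        if not 0 < self.eta < HEX_PACKING_RATIO:
            raise ValueError(f"eta must lie in (0, {HEX_PACKING_RATIO})")


@dataclass
class PackingTable:
    """Lookup of packing ratios keyed exactly by (diameter, width, height)."""

    entries: dict = field(default_factory=dict)
    seed: int | None = None
    trials: int = 0

    def add(self, entry: PackingEntry) -> None:
        self.entries[(entry.diameter, entry.width, entry.height)] = entry

    def lookup(self, diameter: float, width: int, height: int,
               interpolate: bool = False) -> float:
        key = (int(round(diameter)), width, height)
        if key in self.entries:
            return self.entries[key].eta
        if not interpolate:
            raise KeyError(
                f"no packing entry for diameter={key[0]}, size={width}x{height}"
                " (pass interpolate=True to interpolate over diameter)")
        cands = sorted(d for d, w, h in self.entries if (w, h) == (width, height))
        if not cands:
            raise KeyError(f"no packing entries for size {width}x{height}")
        xs = np.asarray(cands, dtype=float)
        ys = np.asarray([self.entries[(int(d), width, height)].eta for d in cands])
        return float(np.interp(key[0], xs, ys))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"diameter": e.diameter, "width": e.width, "height": e.height,
              "eta": e.eta, "sd": e.sd, "trials": e.trials}
             for e in self.entries.values()])


# --------------------------------------------------------------------------
# unconstrained uniform placement (MCMRP)
# --------------------------------------------------------------------------


def place_cells_uniform(n: int, width: int, height: int, seed=None) -> np.ndarray:
    """n independent uniformly random pixel sites (overlap allowed)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    flat = rng.integers(0, width * height, size=n)
    return np.column_stack([flat % width, flat // width]).astype(int)


def icf_samples(dilated_grid: np.ndarray, n: int, trials: int, rng) -> np.ndarray:
    """Vectorized ICF samples against a precomputed dilated mask."""
    flat = rng.integers(0, dilated_grid.size, size=(trials, n))
    return dilated_grid.reshape(-1)[flat].mean(axis=1)


def mcmrp_distribution(network: BinaryMask, cell: CellModel, n: int,
                       trials: int, seed=None) -> ICFDistribution:
    """Empirical ICF distribution under uniformly random placement.

    Per trial, ``n`` cell centers are drawn uniformly over all pixels and the
    ICF is the fraction of centers on the cell-radius-dilated network.  The
    colocalized count per trial is therefore Binomial(n, CDNF) by
    construction, and the distribution mean estimates the CDNF.
    """
    if n < 1 or trials < 1:
        raise ValueError("need n >= 1 and trials >= 1")
    rng = np.random.default_rng(seed)
    dilated = dilate_network(network, cell)
    return ICFDistribution(icf_samples(dilated.grid, n, trials, rng))


# --------------------------------------------------------------------------
# non-overlapping placement and packing
# --------------------------------------------------------------------------


def _conflict_footprint(radius: float) -> np.ndarray:
    """Center offsets at which two pixelated disks share at least one pixel.

    The Minkowski sum of the disk with itself: offset δ conflicts iff some
    pixel lies within ``radius`` of both centers.
    """
    disk = disk_element(radius)
    r = disk.shape[0] // 2
    padded = np.pad(disk, r)
    return ndimage.binary_dilation(padded, structure=disk)


def _containment_margin(radius: float) -> int:
    return int(math.floor(radius))


def _rsa_fill(cell: CellModel, width: int, height: int, rng,
              n_max: int | None = None):
    """Random sequential adsorption of fully contained, pairwise-disjoint
    pixelated disks; exact saturation.

    Candidate centers are all admissible (fully-contained) pixels in a
    seeded uniform random order; each candidate still free when reached is
    accepted.  This is distributionally identical to dart throwing, and by
    construction the image is saturated exactly when the candidate list is
    exhausted.  Returns ``(centers, saturated)``.
    """
    r = cell.radius
    m = _containment_margin(r)
    iw, ih = width - 2 * m, height - 2 * m
    if iw <= 0 or ih <= 0:
        return np.empty((0, 2), dtype=int), True
    foot = _conflict_footprint(r)
    fr = foot.shape[0] // 2
    free = np.ones((ih, iw), dtype=bool)
    order = rng.permutation(free.size)
    centers = []
    for flat in order:
        y, x = divmod(int(flat), iw)
        if not free[y, x]:
            continue
        centers.append((x + m, y + m))
        y0, y1 = max(y - fr, 0), min(y + fr + 1, ih)
        x0, x1 = max(x - fr, 0), min(x + fr + 1, iw)
        free[y0:y1, x0:x1] &= ~foot[y0 - (y - fr):y1 - (y - fr),
                                    x0 - (x - fr):x1 - (x - fr)]
        if n_max is not None and len(centers) >= n_max:
            return np.asarray(centers, dtype=int), not free.any()
    return (np.asarray(centers, dtype=int).reshape(-1, 2), True)


def place_cells_nonoverlapping(n: int, cell: CellModel, width: int,
                               height: int, seed=None):
    """Sequentially place up to ``n`` disjoint, fully contained disks.

    Returns ``(centers, saturated)``: ``saturated`` is True iff no admissible
    center remains after placement (detected exactly, not heuristically).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return _rsa_fill(cell, width, height, rng, n_max=n)


def saturate_packing(cell: CellModel, width: int, height: int, seed=None) -> float:
    """Packing ratio of randomly placed disjoint disks at saturation.

    Cells must be fully contained in the image (a border cell's
    colocalization state is unknowable).  Diameters below 5 px are rejected:
    distinct cells cannot be resolved at that scale.
    """
    if cell.diameter < 5:
        raise ValueError("packing invalid for cell diameters < 5 px")
    rng = np.random.default_rng(seed)
    centers, _ = _rsa_fill(cell, width, height, rng)
    disk_px = int(disk_element(cell.radius).sum())
    return centers.shape[0] * disk_px / (width * height)


def build_packing_table(widths, heights, diameters, trials: int,
                        seed=None) -> PackingTable:
    """Monte-Carlo packing table over image sizes and cell diameters."""
    ss = as_seed_sequence(seed)
    table = PackingTable(seed=seed if isinstance(seed, int) else None,
                         trials=trials)
    for width, height in zip(widths, heights):
        for d in diameters:
            child = np.random.default_rng(ss.spawn(1)[0])
            etas = np.array([
                saturate_packing(CellModel(d), width, height,
                                 child.integers(0, 2**31))
                for _ in range(trials)])
            table.add(PackingEntry(int(d), width, height,
                                   float(etas.mean()),
                                   float(etas.std(ddof=1)) if trials > 1 else 0.0,
                                   trials))
    return table


# --------------------------------------------------------------------------
# clumped placement
# --------------------------------------------------------------------------


def _touch_offsets(radius: float) -> np.ndarray:
    """Near-touching disjoint center offsets, ordered by distance.

    The smallest offsets at which two pixelated disks do not share a pixel;
    pixelation means the minimal disjoint center distance can slightly exceed
    the diameter.  Offsets up to one pixel beyond the minimum are candidates.
    """
    foot = _conflict_footprint(radius)
    fr = foot.shape[0] // 2
    dy, dx = np.mgrid[-fr - 2:fr + 3, -fr - 2:fr + 3]
    conflict = np.zeros(dy.shape, dtype=bool)
    conflict[2:-2, 2:-2] = foot
    dist = np.hypot(dx, dy)
    free = ~conflict
    dmin = dist[free].min()
    sel = free & (dist <= dmin + 1.0)
    return np.column_stack([dx[sel], dy[sel]])


def place_clumps(n_clumps: int, clump_size: int, overlap_allowed: bool,
                 cell: CellModel, width: int, height: int, seed=None):
    """Place cells in clumps: a uniformly placed anchor plus adjacent members.

    In overlap mode the anchor is an unconstrained uniform pixel and members
    are jittered within one cell radius of it; ``clump_size == 1`` therefore
    reduces exactly to uniform placement.  In non-overlap mode anchors avoid
    existing cells and members are placed at near-touching disjoint offsets
    from the anchor (falling back to any clump member when the anchor ring is
    full).  Returns ``(centers, saturated)``.
    """
    if n_clumps < 1 or clump_size < 1:
        raise ValueError("need n_clumps >= 1 and clump_size >= 1")
    rng = np.random.default_rng(seed)
    r = cell.radius

    if overlap_allowed:
        anchors = place_cells_uniform(n_clumps, width, height, rng)
        centers = []
        for ax, ay in anchors:
            centers.append((ax, ay))
            for _ in range(clump_size - 1):
                while True:
                    jx, jy = rng.uniform(-r, r, size=2)
                    if jx * jx + jy * jy <= r * r:
                        break
                x = int(np.clip(round(ax + jx), 0, width - 1))
                y = int(np.clip(round(ay + jy), 0, height - 1))
                centers.append((x, y))
        return np.asarray(centers, dtype=int), False

    foot = _conflict_footprint(r)
    fr = foot.shape[0] // 2
    m = _containment_margin(r)
    touch = _touch_offsets(r)
    free = np.zeros((height, width), dtype=bool)
    free[m:height - m, m:width - m] = True

    def occupy(x: int, y: int) -> None:
        y0, y1 = max(y - fr, 0), min(y + fr + 1, height)
        x0, x1 = max(x - fr, 0), min(x + fr + 1, width)
        free[y0:y1, x0:x1] &= ~foot[y0 - (y - fr):y1 - (y - fr),
                                    x0 - (x - fr):x1 - (x - fr)]

    centers: list[tuple[int, int]] = []
    saturated = False
    for _ in range(n_clumps):
        idx = np.flatnonzero(free.reshape(-1))
        if idx.size == 0:
            saturated = True
            break
        flat = int(rng.choice(idx))
        ay, ax = divmod(flat, width)
        clump = [(ax, ay)]
        occupy(ax, ay)
        for _ in range(clump_size - 1):
            placed = False
            for px, py in clump:  # prefer the anchor, then earlier members
                for k in rng.permutation(touch.shape[0]):
                    x, y = px + int(touch[k, 0]), py + int(touch[k, 1])
                    if 0 <= x < width and 0 <= y < height and free[y, x]:
                        clump.append((x, y))
                        occupy(x, y)
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                saturated = True
                break
        centers.extend(clump)
        if saturated:
            break
    return np.asarray(centers, dtype=int).reshape(-1, 2), saturated


def clump_icf_mean(network: BinaryMask, cell: CellModel, n_clumps: int,
                   clump_size: int, overlap_allowed: bool, trials: int,
                   seed=None) -> ICFDistribution:
    """ICF distribution when cells arrive in clumps rather than singly."""
    ss = as_seed_sequence(seed)
    dilated = dilate_network(network, cell)
    samples = np.empty(trials)
    for t, child in enumerate(ss.spawn(trials)):
        centers, _ = place_clumps(n_clumps, clump_size, overlap_allowed,
                                  cell, network.width, network.height, child)
        obs = count_colocalized(centers, dilated)
        samples[t] = obs.c / obs.n
    return ICFDistribution(samples)
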