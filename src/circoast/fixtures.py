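"""Synthetic end-to-end fixtures: image sets with known ground-truth
colocalization enrichment.

``make_fixture`` writes network masks as PNGs, cell centroid CSVs, and a
manifest, with a stated enrichment level: a fraction of the cells is forced
onto the cell-dilated network (enrichment 0 is pure random placement, so
downstream group p-values are calibrated; enrichment 1 puts every cell on
the network).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import io
from ._seeds import as_seed_sequence
from .imaging import CellModel, dilate_network
from .network_synthesis import NetworkParams, generate_network
from .placement_sim import place_cells_uniform

KINDS = ("image-set", "confound", "sweep")


def enriched_centers(network_mask, cell: CellModel, n: int, enrichment: float,
                     seed=None) -> np.ndarray:
    """n cell centers with a forced fraction on the dilated network.

    ``round(enrichment * n)`` centers are drawn uniformly from the dilated
    (colocalizing) pixels, the rest uniformly from the whole image.
    """
    if not 0 <= enrichment <= 1:
        raise ValueError("enrichment must be in [0, 1]")
    rng = np.random.default_rng(as_seed_sequence(seed))
    dilated = dilate_network(network_mask, cell)
    n_on = int(round(enrichment * n))
    on_idx = np.flatnonzero(dilated.grid.reshape(-1))
    if n_on > 0 and on_idx.size == 0:
        raise ValueError("cannot enrich onto an empty network")
    chosen = rng.choice(on_idx, size=n_on, replace=True) if n_on else np.empty(0, int)
    w = network_mask.width
    forced = np.column_stack([chosen % w, chosen // w]).astype(int)
    free = place_cells_uniform(n - n_on, w, network_mask.height, rng)
    return np.vstack([forced, free])


def make_fixture(kind: str, out_dir, seed=None, n_groups: int = 2,
                 n_replicates: int = 3, images_per_replicate: int = 2,
                 width: int = 192, height: int = 192, cell_diameter: float = 10.0,
                 cell_number: int = 60, target_fraction: float = 0.25,
                 network_radius: int = 3, min_point_distance: float = 18.0,
                 enrichment: float = 0.0) -> Path:
    """Write a synthetic image set + manifest; returns the manifest path.

    * ``image-set``: ``n_groups`` groups with the same densities and the
      given enrichment applied to the first group only.
    * ``confound``: 2 groups of randomly placed cells with the second group
      at half the cell count and 40% of the network target.
    * ``sweep``: a flat list of single-image records with varied parameters.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = as_seed_sequence(seed)
    cell = CellModel(cell_diameter)
    rows = []

    if kind == "sweep":
        n_groups, n_replicates = 1, 1
        images_per_replicate = 8

    for g in range(n_groups):
        g_cells = cell_number
        g_target = target_fraction
        g_enrich = enrichment if g == 0 else 0.0
        if kind == "confound":
            g_enrich = 0.0
            if g == 1:
                g_cells = max(cell_number // 2, 5)
                g_target = target_fraction * 0.4
        for r in range(n_replicates):
            for i, child in enumerate(ss.spawn(images_per_replicate)):
                s_net, s_cells = child.spawn(2)
                if kind == "sweep":
                    rng = np.random.default_rng(child)
                    g_target = float(rng.uniform(0.08, 0.5))
                    g_cells = int(rng.integers(30, 120))
                net = generate_network(
                    NetworkParams(width, height, network_radius=network_radius,
                                  min_point_distance=min_point_distance,
                                  network_fraction=g_target), s_net)
                centers = enriched_centers(net.mask, cell, g_cells, g_enrich,
                                           s_cells)
                stem = f"g{g}_r{r}_i{i}"
                img_path = out / f"{stem}_network.png"
                cells_path = out / f"{stem}_cells.csv"
                io.write_mask(img_path, net.mask)
                io.write_centroids(cells_path, centers)
                rows.append({"group": f"group{g}", "replicate": f"rep{g}_{r}",
                             "image_path": img_path.name,
                             "cells_path_or_count": cells_path.name,
                             "threshold": 128})
    manifest = out / "manifest.csv"
    io.write_manifest(manifest, rows)
    return manifest
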