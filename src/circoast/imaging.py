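"""Binary-mask primitives: segmentation, disk morphology and the cell-dilated
network fraction (CDNF).

The colocalization framework represents a cell of interest (COI) as a
pixelated disk.  A cell placed at pixel ``(x, y)`` overlaps the network by at
least one pixel exactly when its center lies inside the network mask dilated
by the cell radius; the true-pixel fraction of that dilated mask is the CDNF,
which equals the mean intercellular colocalization fraction (ICF) under
uniformly random cell placement.

One disk rasterization rule is used throughout the package (dilation, cell
placement, packing, overlap counting): a pixel offset ``(dx, dy)`` from the
disk center belongs to the disk iff ``dx**2 + dy**2 <= radius**2``
(pixel-center Euclidean test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class BinaryMask:
    """A 2D boolean pixel grid with an optional physical pixel size (µm/px)."""

    grid: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError(f"mask must be 2D, got {self.grid.ndim}D")
        if self.grid.size == 0:
            raise ValueError("mask must have positive width and height")
        if self.grid.dtype != bool:
            if not np.isin(self.grid, (0, 1)).all():
                raise ValueError("mask values must be strictly boolean (0/1)")
            self.grid = self.grid.astype(bool)
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def fraction(self) -> float:
        """Fraction of true pixels."""
        return float(self.grid.mean())


@dataclass(frozen=True)
class CellModel:
    """A disk-shaped cell of interest, parameterized by its pixel diameter."""

    diameter: float

    def __post_init__(self) -> None:
        if not self.diameter >= 1:
            raise ValueError("cell diameter must be >= 1 pixel")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class CdnfValue:
    """Cell-dilated network fraction: dilated true pixels over total pixels."""

    dilated_pixels: int
    total_pixels: int

    def __post_init__(self) -> None:
        if self.total_pixels <= 0:
            raise ValueError("total_pixels must be positive")
        if not 0 <= self.dilated_pixels <= self.total_pixels:
            raise ValueError("dilated_pixels out of range")

    @property
    def p(self) -> float:
        return self.dilated_pixels / self.total_pixels

    def to_json(self) -> dict:
        return {
            "p": self.p,
            "dilated_pixels": int(self.dilated_pixels),
            "total_pixels": int(self.total_pixels),
        }


@dataclass
class ColocObservation:
    """Observed cell counts in one image (or pooled): n total, c colocalized."""

    n: int
    c: int

    def __post_init__(self) -> None:
        if self.n < 0 or not 0 <= self.c <= max(self.n, 0):
            raise ValueError(f"need 0 <= c <= n, got c={self.c}, n={self.n}")

    def to_json(self) -> dict:
        return {"n": int(self.n), "c": int(self.c)}


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def segment_global_threshold(image: np.ndarray, threshold: float,
                             pixel_size: float = 1.0) -> BinaryMask:
    """Segment a single-channel intensity image with a global threshold.

    A pixel is foreground iff its intensity is >= ``threshold`` (inclusive).
    Multi-channel input is rejected; select a channel first (see
    :func:`circoast.io.read_image`).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(
            f"expected a 2D single-channel image, got shape {image.shape}; "
            "select one channel (e.g. --channel G) before segmenting")
    lo, hi = _intensity_range(image)
    if not (lo <= threshold <= hi):
        raise ValueError(
            f"threshold {threshold} outside representable range [{lo}, {hi}]")
    return BinaryMask(image >= threshold, pixel_size=pixel_size)


def _intensity_range(image: np.ndarray) -> tuple[float, float]:
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return float(info.min), float(info.max)
    return -math.inf, math.inf


def disk_element(radius: float) -> np.ndarray:
    """Rasterized disk structuring element (odd-sided square bool array).

    Offset (dx, dy) from the center is inside iff dx^2 + dy^2 <= radius^2.
    """
    if not radius >= 0.5:
        raise ValueError("radius must be >= 0.5 (sub-pixel cell)")
    r_ext = int(math.floor(radius))
    dy, dx = np.mgrid[-r_ext:r_ext + 1, -r_ext:r_ext + 1]
    return (dx * dx + dy * dy) <= radius * radius


def _dilate_grid(grid: np.ndarray, radius: float) -> np.ndarray:
    """Dilate a boolean grid by the pixel-center disk of ``radius``.

    Implemented as a Euclidean distance-transform threshold, which is exact
    for the pixel-center disk test (the squared EDT of a boolean grid takes
    integer values) and much faster than explicit dilation for large disks.
    Dilation is evaluated within image bounds only.
    """
    if not grid.any():
        return np.zeros_like(grid)
    if grid.all():
        return np.ones_like(grid)
    d2 = np.rint(ndimage.distance_transform_edt(~grid) ** 2)
    return d2 <= radius * radius


def dilate_network(network: BinaryMask, cell: CellModel) -> BinaryMask:
    """Morphologically dilate the network mask by the cell radius."""
    return BinaryMask(_dilate_grid(network.grid, cell.radius),
                      pixel_size=network.pixel_size)


def compute_cdnf(network: BinaryMask, cell: CellModel) -> CdnfValue:
    """Cell-dilated network fraction of a network mask for a given cell size."""
    dilated = _dilate_grid(network.grid, cell.radius)
    return CdnfValue(int(dilated.sum()), int(dilated.size))


def pool_cdnf(values: list[CdnfValue]) -> CdnfValue:
    """Pool CDNF values across images (area-weighted pixel-count ratio)."""
    if not values:
        raise ValueError("cannot pool an empty list of CDNF values")
    return CdnfValue(sum(v.dilated_pixels for v in values),
                     sum(v.total_pixels for v in values))


def count_colocalized(centers: np.ndarray, dilated: BinaryMask) -> ColocObservation:
    """Count cell centers falling on the dilated network mask.

    ``centers`` is an (n, 2) array of integer (x, y) pixel coordinates
    (0-based, x = column, y = row).  A center on the dilated mask corresponds
    to a cell overlapping the raw network by at least one pixel.
    """
    centers = np.asarray(centers, dtype=int).reshape(-1, 2)
    if centers.shape[0] == 0:
        return ColocObservation(0, 0)
    x, y = centers[:, 0], centers[:, 1]
    bad = (x < 0) | (x >= dilated.width) | (y < 0) | (y >= dilated.height)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"center index {idx} at {tuple(centers[idx])} is "
                         "outside image bounds")
    c = int(dilated.grid[y, x].sum())
    return ColocObservation(int(centers.shape[0]), c)


def effective_cell_model(areas) -> CellModel:
    """Disk whose area equals the mean of the observed cell pixel areas.

    Used to mitigate miscounting when touching cells merge into single
    connected components: the merged components are larger, so the effective
    diameter grows with the mean area.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one cell area")
    if not (areas > 0).all():
        raise ValueError("cell areas must be positive")
    return CellModel(2.0 * math.sqrt(areas.mean() / math.pi))


_STRUCT8 = np.ones((3, 3), dtype=bool)


def quantify_connected_components(cell_mask: BinaryMask,
                                  return_centroids: bool = False):
    """Count 8-connected components of a cell mask and their mean pixel area.

    Models the error-prone quantification where any overlap (including
    diagonal touching) merges cells into a single counted object.  Returns
    ``(count, mean_area)`` with ``mean_area = nan`` when the mask is empty;
    with ``return_centroids=True`` also returns an (count, 2) array of
    rounded (x, y) component centroids.
    """
    labels, count = ndimage.label(cell_mask.grid, structure=_STRUCT8)
    if count == 0:
        out = (0, math.nan)
        return (*out, np.empty((0, 2), dtype=int)) if return_centroids else out
    mean_area = float(cell_mask.grid.sum()) / count
    if not return_centroids:
        return count, mean_area
    cy, cx = zip(*ndimage.center_of_mass(cell_mask.grid, labels,
                                         range(1, count + 1)))
    centroids = np.column_stack([np.rint(cx), np.rint(cy)]).astype(int)
    np.clip(centroids[:, 0], 0, cell_mask.width - 1, out=centroids[:, 0])
    np.clip(centroids[:, 1], 0, cell_mask.height - 1, out=centroids[:, 1])
    return count, mean_area, centroids


def stamp_cells(centers: np.ndarray, cell: CellModel, width: int,
                height: int) -> BinaryMask:
    """Render cells as pixelated disks into a binary mask (clipped at bounds)."""
    grid = np.zeros((height, width), dtype=bool)
    centers = np.asarray(centers, dtype=int).reshape(-1, 2)
    if centers.shape[0] == 0:
        return BinaryMask(grid)
    disk = disk_element(cell.radius)
    r = disk.shape[0] // 2
    for x, y in centers:
        y0, y1 = max(y - r, 0), min(y + r + 1, height)
        x0, x1 = max(x - r, 0), min(x + r + 1, width)
        grid[y0:y1, x0:x1] |= disk[y0 - (y - r):y1 - (y - r),
                                   x0 - (x - r):x1 - (x - r)]
    return BinaryMask(grid)
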