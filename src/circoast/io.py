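"""Reading and writing images, centroid tables and manifests.

Images are 8/16-bit grayscale or RGB TIFF/PNG; masks are written as 8-bit
0/255 images.  Centroid tables are CSV with an ``x,y`` header (0-based pixel
coordinates), cell-area tables CSV with ``area_px``, and the group manifest
is CSV with columns ``group,replicate,image_path,cells_path_or_count,
threshold``.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .imaging import BinaryMask

_CHANNELS = {"R": 0, "G": 1, "B": 2}


def read_image(path, channel: str | None = None) -> np.ndarray:
    """Read a grayscale or RGB image; ``channel`` selects R/G/B if RGB."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path} is multi-channel {arr.shape}; pass channel='R'|'G'|'B'")
        if channel.upper() not in _CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        arr = arr[..., _CHANNELS[channel.upper()]]
    elif arr.ndim != 2:
        raise ValueError(f"{path} has unsupported shape {arr.shape}")
    return arr


def write_mask(path, mask: BinaryMask) -> None:
    """Write a binary mask as an 8-bit 0/255 PNG/TIFF."""
    iio.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))


def read_mask(path, channel: str | None = None) -> BinaryMask:
    arr = read_image(path, channel)
    return BinaryMask(arr > 0)


def read_centroids(path) -> np.ndarray:
    """(n, 2) integer (x, y) array from a CSV with an ``x,y`` header."""
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: centroid CSV must have columns x,y "
                         f"(missing {sorted(missing)})")
    return df[["x", "y"]].to_numpy(dtype=int)


def write_centroids(path, centers: np.ndarray) -> None:
    pd.DataFrame(np.asarray(centers, dtype=int),
                 columns=["x", "y"]).to_csv(path, index=False)


def read_areas(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "area_px" not in df.columns:
        raise ValueError(f"{path}: area CSV must have column area_px")
    return df["area_px"].to_numpy(dtype=float)


MANIFEST_COLUMNS = ["group", "replicate", "image_path",
                    "cells_path_or_count", "threshold"]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"group": str, "replicate": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_manifest(path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
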