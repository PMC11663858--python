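"""Droplet segmentation and per-cell intensity scoring.

Implements the pixel-level readouts behind both quantification workflows:
thresholding the Nile Red green channel into a lipid-droplet mask, the
per-pixel Oil Red O positivity ratio R/(G+B) on transmitted-light RGB
images, linear auto-contrast normalization of the GFP channel to a 0-255
scale, and per-cell aggregation (area, droplet overlap, channel maxima)
over a label mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

logger = logging.getLogger(__name__)

__all__ = [
    "DropletMask",
    "CellRecord",
    "segment_droplets",
    "oro_ratio_image",
    "normalize_autocontrast",
    "per_cell_stats",
    "records_to_frame",
]


@dataclass
class DropletMask:
    """Binary lipid-droplet mask plus the threshold that produced it.

    The threshold is explicit state so the same manually chosen value can
    be reused across every well of an experiment.
    """

    mask: np.ndarray
    threshold: float
    min_droplet_area: int


@dataclass
class CellRecord:
    """Per-cell measurements aggregated over one label-mask instance."""

    label: int
    area: int
    n_droplet_px: int
    has_droplets: bool
    max_gfp_norm: float | None = None
    max_oro_ratio: float | None = None


def segment_droplets(
    green: np.ndarray,
    threshold: float | str = "auto",
    min_droplet_area: int = 4,
) -> DropletMask:
    """Threshold the Nile Red green channel into a droplet mask.

    ``mask = green >= threshold`` (the threshold value itself is included);
    connected components smaller than ``min_droplet_area`` px are removed
    (0 disables).  ``threshold="auto"`` uses Otsu; an explicit value must
    lie within the channel's bit-depth range.
    """
    green = np.asarray(green)
    if green.size == 0:
        raise ValueError("empty image")
    if threshold == "auto":
        if green.max() == green.min():
            return DropletMask(np.zeros(green.shape, dtype=bool),
                               float(green.max()) + 1.0, min_droplet_area)
        thr = float(threshold_otsu(green.astype(np.float64)))
    else:
        thr = float(threshold)
        if np.issubdtype(green.dtype, np.integer):
            top = float(np.iinfo(green.dtype).max)
            if not 0.0 <= thr <= top:
                raise ValueError(f"threshold {thr} outside [0, {top}] for dtype {green.dtype}")
    mask = green >= thr
    if min_droplet_area > 0:
        mask = remove_small_objects(mask, connectivity=1, max_size=min_droplet_area - 1)
    return DropletMask(mask=mask, threshold=thr, min_droplet_area=min_droplet_area)


def oro_ratio_image(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel Oil Red O positivity ratio R / (G + B).

    A pixel is Oil-Red-O-positive when the ratio strictly exceeds 1.
    The zero-denominator convention: R > 0 with G + B = 0 gives ``inf``
    (pure red is maximally positive); R = 0 gives ratio 0 (negative).
    Accepts (H, W, 3) or (3, H, W); raises on negative inputs.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or 3 not in (rgb.shape[0], rgb.shape[-1]):
        raise ValueError(f"expected an RGB image, got shape {rgb.shape}")
    if rgb.shape[-1] != 3:  # (3, H, W) -> (H, W, 3)
        rgb = np.moveaxis(rgb, 0, -1)
    if (rgb < 0).any():
        raise ValueError("RGB planes must be nonnegative")
    r = rgb[..., 0]
    denom = rgb[..., 1] + rgb[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = r / denom
    ratio = np.where(denom > 0, ratio, np.where(r > 0, np.inf, 0.0))
    return ratio


def normalize_autocontrast(channel: np.ndarray) -> np.ndarray:
    """Linearly rescale a channel so its maximum maps to 255.

    Returns floating-point values in [0, 255] (no integer rounding, so the
    gate at 127 is applied on the continuous scale).  An all-zero channel
    is returned unchanged with a warning — there is no signal to scale.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size == 0:
        raise ValueError("empty image")
    peak = channel.max()
    if peak == 0:
        logger.warning("auto-contrast on an all-zero channel: returning it unchanged")
        return channel.copy()
    return channel * (255.0 / peak)


def per_cell_stats(
    cells: np.ndarray,
    droplets: DropletMask | np.ndarray | None = None,
    gfp_norm: np.ndarray | None = None,
    oro_ratio: np.ndarray | None = None,
    droplet_overlap_min: int = 1,
) -> list[CellRecord]:
    """Aggregate per-cell measurements over a label mask.

    For each instance: pixel area, count of droplet-mask pixels inside the
    cell (``has_droplets`` when the count reaches ``droplet_overlap_min``),
    and the maximum of each provided intensity grid over the cell's pixels.
    Channels that are not provided yield ``None`` fields.
    """
    cells = np.asarray(cells)
    drop = droplets.mask if isinstance(droplets, DropletMask) else droplets
    for name, grid in (("droplets", drop), ("gfp_norm", gfp_norm), ("oro_ratio", oro_ratio)):
        if grid is not None and np.asarray(grid).shape != cells.shape:
            raise ValueError(f"{name} shape {np.asarray(grid).shape} != cells shape {cells.shape}")

    labels = np.unique(cells)
    labels = labels[labels > 0]
    if labels.size == 0:
        return []
    areas = ndi.sum_labels(np.ones_like(cells, dtype=np.int64), cells, index=labels)
    if drop is not None:
        overlaps = ndi.sum_labels(np.asarray(drop, dtype=np.int64), cells, index=labels)
    else:
        overlaps = np.zeros(labels.size)
    gfp_max = ndi.maximum(np.asarray(gfp_norm, dtype=np.float64), cells, index=labels) if gfp_norm is not None else None
    oro_max = ndi.maximum(np.asarray(oro_ratio, dtype=np.float64), cells, index=labels) if oro_ratio is not None else None

    records = []
    for i, lab in enumerate(labels):
        records.append(CellRecord(
            label=int(lab),
            area=int(areas[i]),
            n_droplet_px=int(overlaps[i]),
            has_droplets=bool(overlaps[i] >= droplet_overlap_min),
            max_gfp_norm=float(gfp_max[i]) if gfp_max is not None else None,
            max_oro_ratio=float(oro_max[i]) if oro_max is not None else None,
        ))
    return records


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Tabulate cell records (one row per cell, fixed column order)."""
    cols = ["label", "area", "n_droplet_px", "has_droplets", "max_gfp_norm", "max_oro_ratio"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
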