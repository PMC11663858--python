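"""Cell instance segmentation.

Two entry paths mirror the two imaging workflows:

* ``detect_nuclei`` + ``segment_cells_watershed`` — nuclei are detected as
  bright blobs in the DAPI channel and used as seeds for a watershed that
  partitions a foreground support into one region per nucleus (the rescue
  scoring workflow).
* ``segment_cells_from_lipid_red`` — a deterministic classical segmenter
  on the Nile Red red (total lipid) channel: global Otsu foreground, hole
  filling, debris removal, then a distance-transform watershed to split
  touching cells.  It fills the role of a trained instance-segmentation
  network behind the same input/output contract, so a learned model can be
  swapped in without touching downstream code.

A label mask is a 2-D ``int32`` grid: 0 is background, ``k > 0`` is cell
instance ``k``; regions are pairwise disjoint and connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "NucleusSet",
    "LipidRedParams",
    "detect_nuclei",
    "segment_cells_watershed",
    "segment_cells_from_lipid_red",
]


@dataclass
class NucleusSet:
    """Detected nucleus seeds: ``coords`` is (n, 2) integer (row, col)."""

    coords: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.coords)

    @staticmethod
    def empty() -> "NucleusSet":
        return NucleusSet(np.empty((0, 2), dtype=int), np.empty(0))


def detect_nuclei(
    dapi: np.ndarray,
    min_distance: float = 8.0,
    threshold: float | str = "auto",
    sigma: float = 2.0,
    min_area: int = 10,
) -> NucleusSet:
    """Detect nuclei as bright blobs in a DAPI image.

    The image is Gaussian-smoothed (``sigma``), thresholded (Otsu when
    ``threshold="auto"``), small components are discarded, and one seed is
    placed at each component's intensity-weighted centroid.  Seeds closer
    than ``min_distance`` are resolved by keeping the brighter one.  A
    constant image yields an empty seed set.
    """
    dapi = np.asarray(dapi, dtype=np.float64)
    if dapi.size == 0:
        raise ValueError("empty image")
    smooth = gaussian(dapi, sigma=sigma, preserve_range=True)
    if smooth.max() == smooth.min():
        return NucleusSet.empty()
    thr = float(threshold_otsu(smooth)) if threshold == "auto" else float(threshold)
    mask = smooth > thr
    mask = remove_small_objects(mask, connectivity=1, max_size=min_area - 1)
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return NucleusSet.empty()
    idx = np.arange(1, n + 1)
    centroids = np.asarray(ndi.center_of_mass(smooth, labels, idx))
    scores = np.asarray(ndi.mean(smooth, labels, idx))

    # enforce pairwise min_distance, keeping higher-score seeds first
    order = np.argsort(-scores, kind="stable")
    kept: list[int] = []
    for i in order:
        if all(np.hypot(*(centroids[i] - centroids[j])) >= min_distance for j in kept):
            kept.append(i)
    kept_idx = sorted(kept, key=lambda i: (centroids[i][0], centroids[i][1]))
    coords = np.rint(centroids[kept_idx]).astype(int)
    coords[:, 0] = np.clip(coords[:, 0], 0, dapi.shape[0] - 1)
    coords[:, 1] = np.clip(coords[:, 1], 0, dapi.shape[1] - 1)
    return NucleusSet(coords=coords, scores=scores[kept_idx])


def segment_cells_watershed(
    seeds: NucleusSet,
    support: np.ndarray | None,
    foreground_mask: np.ndarray,
) -> np.ndarray:
    """Partition a foreground among nucleus seeds by watershed flooding.

    ``support`` is the landscape flooded from the seeds (lower values are
    reached first).  When ``support`` is None the negated Euclidean
    distance transform of the foreground is used, which splits touching
    cells along the ridge between their nuclei.  Seeds falling outside the
    foreground are dropped with a warning; label ``k`` corresponds to the
    ``k``-th retained seed and contains it.
    """
    foreground_mask = np.asarray(foreground_mask, dtype=bool)
    out = np.zeros(foreground_mask.shape, dtype=np.int32)
    if len(seeds) == 0:
        return out
    if support is None:
        support = -ndi.distance_transform_edt(foreground_mask)
    support = np.asarray(support, dtype=np.float64)
    if support.shape != foreground_mask.shape:
        raise ValueError("support and foreground_mask shapes differ")

    markers = np.zeros(foreground_mask.shape, dtype=np.int32)
    next_label = 1
    for r, c in seeds.coords:
        if not foreground_mask[r, c]:
            logger.warning("seed at (%d, %d) outside foreground; dropped", r, c)
            continue
        markers[r, c] = next_label
        next_label += 1
    if next_label == 1:
        return out
    return watershed(support, markers=markers, mask=foreground_mask,
                     connectivity=1).astype(np.int32)


@dataclass(frozen=True)
class LipidRedParams:
    """Tunables of the classical lipid-red-channel segmenter."""

    threshold: float | str = "auto"   # Otsu by default
    min_area: int = 30                # debris removal, px
    peak_min_distance: int = 16       # distance-transform maxima separation, px
    smooth_sigma: float = 2.0         # smoothing of the distance transform


def segment_cells_from_lipid_red(
    lipid_red: np.ndarray,
    params: LipidRedParams | None = None,
) -> np.ndarray:
    """Instance segmentation of cells from the Nile Red red channel.

    Foreground by global threshold, holes filled, objects below
    ``min_area`` removed; instances are then split at the local maxima of
    the smoothed distance transform via watershed.  Fully deterministic.
    """
    p = params or LipidRedParams()
    img = np.asarray(lipid_red, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32)
    thr = float(threshold_otsu(img)) if p.threshold == "auto" else float(p.threshold)
    fg = img >= thr
    fg = ndi.binary_fill_holes(fg)
    fg = remove_small_objects(fg, connectivity=1, max_size=p.min_area - 1)
    if not fg.any():
        return np.zeros(img.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(fg)
    dist_s = gaussian(dist, sigma=p.smooth_sigma, preserve_range=True)
    comps = cc_label(fg, connectivity=1)
    peaks = peak_local_max(dist_s, min_distance=p.peak_min_distance,
                           labels=comps, exclude_border=False)
    # guarantee every foreground component keeps at least one marker
    have = set(comps[tuple(peaks.T)]) if len(peaks) else set()
    missing = [k for k in range(1, comps.max() + 1) if k not in have]
    if missing:
        extra = []
        masked = np.where(comps > 0, dist_s, -np.inf)
        for k in missing:
            flat = np.where(comps.ravel() == k, masked.ravel(), -np.inf)
            extra.append(np.unravel_index(int(np.argmax(flat)), comps.shape))
        peaks = np.vstack([peaks.reshape(-1, 2), np.asarray(extra, dtype=int)])

    order = np.lexsort((peaks[:, 1], peaks[:, 0]))  # scan order: lowest (row, col) first
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks[order].T)] = np.arange(1, len(order) + 1)
    return watershed(-dist_s, markers=markers, mask=fg, connectivity=1).astype(np.int32)
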