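"""Well-level quantification: differentiated-cell fractions and gating.

The headline readout of the whole pipeline is the percentage of
droplet-containing cells: cells whose instance region intersects the
lipid-droplet mask ("having" selection), divided by the total cell count.
For the rescue experiment, cells are additionally gated on the normalized
GFP maximum (transgene expression, strict > 127 on the 0-255 scale) and
the Oil Red O ratio maximum (strict > 1), giving four quadrant classes and
the double-positive count.  A field-sampling estimator reproduces manual
counting of randomly chosen fields of view, and fold changes are computed
on one-decimal percentages as they are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .lipid_scoring import CellRecord, DropletMask

__all__ = [
    "GateConfig",
    "QuantResult",
    "GateResult",
    "cells_having_droplets",
    "differentiated_fraction",
    "gate_cells",
    "scatter_table",
    "field_sample_estimate",
    "fold_change",
    "GATE_CLASSES",
]

GATE_CLASSES = ("GFP+ORO+", "GFP+ORO-", "GFP-ORO+", "GFP-ORO-")


@dataclass(frozen=True)
class GateConfig:
    """Thresholds for the per-cell gates (both comparisons are strict)."""

    gfp_threshold: float = 127.0      # on the auto-contrast 0-255 scale
    oro_ratio_threshold: float = 1.0  # R/(G+B) positivity line
    droplet_overlap_min: int = 1      # px of droplet mask inside a cell

    def __post_init__(self):
        if self.gfp_threshold < 0 or self.gfp_threshold > 255:
            raise ValueError("gfp_threshold must be in [0, 255]")
        if self.oro_ratio_threshold < 0:
            raise ValueError("oro_ratio_threshold must be nonnegative")
        if self.droplet_overlap_min < 1:
            raise ValueError("droplet_overlap_min must be >= 1")


@dataclass
class QuantResult:
    """Droplet-positive fraction of one well or condition."""

    condition: str
    n_total: int
    n_droplet_pos: int
    percent_droplet_pos: float
    n_gfp_pos: int | None = None
    n_double_pos: int | None = None


@dataclass
class GateResult:
    counts: dict[str, int]
    classes: list[str]          # per-record class, parallel to the input
    labels: list[int]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def cells_having_droplets(
    cells: np.ndarray,
    droplets: DropletMask | np.ndarray,
    overlap_min: int = 1,
) -> tuple[set[int], np.ndarray]:
    """Select cell labels whose region overlaps the droplet mask.

    A label is kept when at least ``overlap_min`` of its pixels are droplet
    pixels.  Returns the selected label set and a copy of the label mask
    with all other labels zeroed.
    """
    cells = np.asarray(cells)
    drop = droplets.mask if isinstance(droplets, DropletMask) else np.asarray(droplets, dtype=bool)
    if drop.shape != cells.shape:
        raise ValueError(f"droplet mask shape {drop.shape} != cell mask shape {cells.shape}")
    labels = np.unique(cells)
    labels = labels[labels > 0]
    if labels.size == 0:
        return set(), np.zeros_like(cells)
    overlap = ndi.sum_labels(drop.astype(np.int64), cells, index=labels)
    selected = {int(lab) for lab, ov in zip(labels, overlap) if ov >= overlap_min}
    filtered = np.where(np.isin(cells, sorted(selected)), cells, 0)
    return selected, filtered


def differentiated_fraction(n_pos: int, n_total: int) -> float:
    """Percentage of droplet-containing cells, 100 * n_pos / n_total."""
    if n_total <= 0:
        raise ValueError("differentiated fraction undefined: total cell count is zero")
    if not 0 <= n_pos <= n_total:
        raise ValueError(f"n_pos={n_pos} outside [0, {n_total}]")
    return 100.0 * n_pos / n_total


def gate_cells(records: list[CellRecord], gates: GateConfig | None = None) -> GateResult:
    """Classify cells into GFP x Oil Red O quadrants.

    GFP+ means the cell's normalized GFP maximum strictly exceeds the gate
    (default 127); ORO+ means its Oil Red O ratio maximum strictly exceeds
    1.  Every record falls in exactly one class, so the four counts always
    sum to the number of cells.
    """
    gates = gates or GateConfig()
    counts = {c: 0 for c in GATE_CLASSES}
    classes: list[str] = []
    labels: list[int] = []
    for rec in records:
        if rec.max_gfp_norm is None or rec.max_oro_ratio is None:
            raise ValueError(f"cell {rec.label} lacks GFP/ORO maxima required for gating")
        g = "GFP+" if rec.max_gfp_norm > gates.gfp_threshold else "GFP-"
        o = "ORO+" if rec.max_oro_ratio > gates.oro_ratio_threshold else "ORO-"
        cls = g + o
        counts[cls] += 1
        classes.append(cls)
        labels.append(rec.label)
    return GateResult(counts=counts, classes=classes, labels=labels)


def scatter_table(
    records: list[CellRecord],
    gates: GateConfig | None = None,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """One (GFP, ORO) point per cell, optionally drawn as a gated scatterplot.

    The plot shows the Oil Red O positivity line (horizontal, at the ratio
    threshold) and the GFP transgene gate (vertical); the upper-right
    quadrant holds the double-positive cells.
    """
    if not records:
        raise ValueError("no cell records to plot")
    gates = gates or GateConfig()
    gated = gate_cells(records, gates)
    table = pd.DataFrame({
        "label": gated.labels,
        "max_gfp_norm": [r.max_gfp_norm for r in records],
        "max_oro_ratio": [r.max_oro_ratio for r in records],
        "class": gated.classes,
    })
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        finite = table["max_oro_ratio"].replace(np.inf, np.nan)
        ymax = max(1.5, float(np.nanmax(finite)) * 1.1 if finite.notna().any() else 1.5)
        y = table["max_oro_ratio"].clip(upper=ymax)
        colors = {"GFP+ORO+": "tab:green", "GFP+ORO-": "tab:olive",
                  "GFP-ORO+": "tab:red", "GFP-ORO-": "tab:gray"}
        for cls in GATE_CLASSES:
            sel = table["class"] == cls
            ax.scatter(table.loc[sel, "max_gfp_norm"], y[sel], s=8,
                       c=colors[cls], label=f"{cls} (n={int(sel.sum())})")
        ax.axhline(gates.oro_ratio_threshold, color="red", lw=1)
        ax.axvline(gates.gfp_threshold, color="green", lw=1)
        ax.set_xlabel("max GFP intensity (normalized, 0-255)")
        ax.set_ylabel("max Oil Red O ratio R/(G+B)")
        ax.legend(fontsize=7, loc="upper left")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return table


def field_sample_estimate(
    cells: np.ndarray,
    records: list[CellRecord],
    n_fields: int,
    field_size: int | tuple[int, int],
    seed: int,
) -> tuple[float, pd.DataFrame]:
    """Estimate the droplet-positive percentage from random fields of view.

    ``n_fields`` rectangular fields are placed uniformly at random with
    periodic (wrap-around) boundaries, so every centroid has the same
    inclusion probability and the estimator carries no border bias; a
    field the size of the image is exhaustive.  A cell belongs to a field
    when its centroid does; a cell covered by several overlapping fields
    is counted once.  The estimate is the pooled percentage over the
    sampled cells.  Raises when no cell falls in any field.
    """
    cells = np.asarray(cells)
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    fh, fw = (field_size, field_size) if np.isscalar(field_size) else field_size
    H, W = cells.shape
    if fh > H or fw > W:
        raise ValueError(f"field {fh}x{fw} larger than image {H}x{W}")
    labels = np.array([r.label for r in records])
    pos = np.array([r.has_droplets for r in records], dtype=bool)
    centroids = np.asarray(ndi.center_of_mass(np.ones_like(cells), cells, index=labels)) \
        if len(labels) else np.empty((0, 2))

    rng = np.random.default_rng(seed)
    sampled: set[int] = set()
    rows = []
    for i in range(n_fields):
        r0 = int(rng.integers(0, H))
        c0 = int(rng.integers(0, W))
        inside = ((np.mod(centroids[:, 0] - r0, H) < fh) &
                  (np.mod(centroids[:, 1] - c0, W) < fw)) if len(labels) else np.array([], bool)
        rows.append({"field": i + 1, "row0": r0, "col0": c0,
                     "n_cells": int(inside.sum()), "n_droplet_pos": int((inside & pos).sum())})
        sampled.update(labels[inside].tolist())
    per_field = pd.DataFrame(rows)
    if not sampled:
        raise ValueError("no cells fell within the sampled fields; estimate undefined")
    sel = np.isin(labels, sorted(sampled))
    estimate = differentiated_fraction(int(pos[sel].sum()), int(sel.sum()))
    return estimate, per_field


def fold_change(percent_a: float, percent_b: float) -> float:
    """Ratio of two percentages, rounded half away from zero to one decimal."""
    if percent_b == 0:
        raise ValueError("fold change undefined: denominator percentage is zero")
    ratio = Decimal(repr(percent_a)) / Decimal(repr(percent_b))
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
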