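"""Synthetic multichannel fluorescence wells with per-cell ground truth.

Emulates imaging of a confluent mesenchymal stromal cell (MSC) monolayer
after adipogenic induction: a DAPI nuclei channel, the red and green Nile
Red emission channels (total vs. non-polar lipids), a GFP channel marking
lentivirally transduced cells, and a transmitted-light RGB image of Oil
Red O staining.  A controllable fraction of cells carries lipid droplets
(``adipocyte_fraction``), in one of two droplet-size regimes, and a
controllable fraction is GFP-positive.  Every generated well carries a
full per-cell ground truth (instance mask, droplet pixels, GFP state), so
the downstream segmentation and gating stages can be validated against a
known answer.

Geometry is deliberately simple: each cell is a randomly perturbed
ellipse around a circular nucleus, placed so that no cell crosses the
midline to its nearest neighbour.  This is not a physical model of cell
shape; it is the minimal geometry that exercises nuclei-seeded watershed
segmentation and per-cell intensity scoring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "IntensityModel",
    "SynthConfig",
    "GroundTruth",
    "SynthWell",
    "PackingError",
    "generate_well",
    "write_fixture",
    "read_fixture",
]

DROPLET_REGIMES = ("small", "large", "mixed")

TRUTH_COLUMNS = ["label", "row", "col", "is_adipocyte", "n_droplet_px", "gfp_on"]


class PackingError(RuntimeError):
    """Raised when the requested number of cells cannot be placed."""


@dataclass(frozen=True)
class IntensityModel:
    """Per-channel foreground/background mean levels, in raw intensity units.

    Fluorescence levels are on the grayscale bit-depth scale; the Oil Red O
    RGB levels are always 8-bit.  Droplet pixels in the RGB image satisfy
    R > G + B (ratio-positive); all other pixels satisfy R <= G + B.
    """

    background: float = 500.0
    nucleus: float = 20000.0
    cytoplasm: float = 10000.0       # Nile Red red emission over the whole cell
    droplet_green: float = 15000.0   # Nile Red green emission at droplets only
    gfp: float = 18000.0             # uniform bright cytoplasm of transduced cells
    oro_background: tuple[float, float, float] = (220.0, 220.0, 220.0)
    oro_cell: tuple[float, float, float] = (180.0, 160.0, 160.0)
    oro_droplet: tuple[float, float, float] = (200.0, 45.0, 45.0)

    @staticmethod
    def default(bit_depth: int) -> "IntensityModel":
        if bit_depth == 16:
            return IntensityModel()
        # 8-bit fluorescence: same contrast, rescaled by 256
        return IntensityModel(
            background=2.0, nucleus=78.0, cytoplasm=39.0,
            droplet_green=59.0, gfp=70.0,
        )


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic well.

    ``adipocyte_fraction`` and ``gfp_fraction`` are realised as exact
    rounded counts, not Bernoulli draws, so a well's ground-truth fraction
    equals the requested one up to rounding.  When
    ``gfp_suppresses_droplets`` is set, droplet-bearing cells are drawn
    only from the GFP-negative pool, emulating a rescue construct that
    blocks adipogenesis in transduced cells.
    """

    height: int = 1024
    width: int = 1024
    bit_depth: int = 16
    n_cells: int = 300
    adipocyte_fraction: float = 0.085
    droplet_regime: str = "small"
    gfp_fraction: float = 0.0
    gfp_suppresses_droplets: bool = False
    cell_radius_mean: float = 11.0
    cell_radius_sd: float = 1.5
    nucleus_radius: float = 4.0
    min_spacing: float = 30.0          # minimum distance between cell centres, px
    small_droplet_radius: tuple[float, float] = (2.0, 4.0)
    small_droplet_count: tuple[int, int] = (3, 8)
    large_droplet_radius_factor: float = 0.5
    intensity: IntensityModel | None = None
    noise_sd: float = 300.0            # additive Gaussian, fluorescence channels
    oro_noise_sd: float = 3.0          # additive Gaussian, 8-bit RGB planes
    seed: int = 0

    def levels(self) -> IntensityModel:
        return self.intensity if self.intensity is not None else IntensityModel.default(self.bit_depth)

    def validate(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("adipocyte_fraction", "gfp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.droplet_regime not in DROPLET_REGIMES:
            raise ValueError(f"droplet_regime must be one of {DROPLET_REGIMES}")
        if self.nucleus_radius < 1 or self.cell_radius_mean < 1:
            raise ValueError("radii must be >= 1 px")
        if self.noise_sd < 0 or self.oro_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        top = float(2 ** self.bit_depth - 1)
        lv = self.levels()
        for name in ("background", "nucleus", "cytoplasm", "droplet_green", "gfp"):
            v = getattr(lv, name)
            if not 0 <= v <= top:
                raise ValueError(f"intensity level {name}={v} outside [0, {top}]")


@dataclass
class GroundTruth:
    """Per-cell truth: instance mask, droplet pixels and cell attributes.

    ``table`` has one row per cell with columns
    ``label, row, col, is_adipocyte, n_droplet_px, gfp_on`` (row/col are the
    nucleus centre).  Droplet pixels of cell *k* are exactly
    ``droplet_mask & (cell_mask == k)`` — droplets never leave their cell.
    """

    table: pd.DataFrame
    cell_mask: np.ndarray
    droplet_mask: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.table)


@dataclass
class SynthWell:
    dapi: np.ndarray
    lipid_red: np.ndarray
    lipid_green: np.ndarray
    gfp: np.ndarray
    oro_rgb: np.ndarray        # (H, W, 3) uint8
    truth: GroundTruth
    config: SynthConfig


def _place_centres(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Sequential random placement with a hard minimum spacing."""
    if cfg.n_cells == 0:
        return np.empty((0, 2), dtype=float)
    # A centre needs ~pi*(s/2)^2 px at random sequential adsorption density ~0.55.
    demand = cfg.n_cells * np.pi * (cfg.min_spacing / 2.0) ** 2 / 0.54
    if demand > cfg.height * cfg.width:
        raise PackingError(
            f"cannot place {cfg.n_cells} cells with spacing {cfg.min_spacing} px "
            f"in a {cfg.height}x{cfg.width} image"
        )
    centres: list[np.ndarray] = []
    placed = np.empty((0, 2), dtype=float)
    attempts = 0
    max_attempts = 400 * cfg.n_cells
    while len(centres) < cfg.n_cells:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed only {len(centres)}/{cfg.n_cells} cells after "
                f"{max_attempts} attempts (spacing {cfg.min_spacing} px)"
            )
        attempts += 1
        cand = rng.uniform([0, 0], [cfg.height, cfg.width])
        if placed.size and np.min(np.hypot(*(placed - cand).T)) < cfg.min_spacing:
            continue
        centres.append(cand)
        placed = np.asarray(centres)
    return placed


def _disk_pixels(centre: np.ndarray, radius: float, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    r0 = max(int(np.floor(centre[0] - radius)), 0)
    r1 = min(int(np.ceil(centre[0] + radius)) + 1, shape[0])
    c0 = max(int(np.floor(centre[1] - radius)), 0)
    c1 = min(int(np.ceil(centre[1] + radius)) + 1, shape[1])
    if r1 <= r0 or c1 <= c0:  # disk entirely outside the image
        empty = np.empty(0, dtype=int)
        return empty, empty
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius ** 2
    return rr[inside], cc[inside]


def _exact_count(fraction: float, n: int) -> int:
    # round-half-away-from-zero of fraction*n, as a deterministic target count
    return int(np.floor(fraction * n + 0.5))


def generate_well(config: SynthConfig) -> SynthWell:
    """Generate one ground-truthed synthetic well.

    A pure function of the config (including its seed): identical configs
    yield bit-identical channels and truth tables.  Raises
    :class:`PackingError` when ``n_cells`` cannot fit at the requested
    spacing rather than silently truncating.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)
    lv = cfg.levels()

    centres = _place_centres(cfg, rng)
    n = len(centres)

    # Per-cell ellipse geometry.  Semi-axes are capped at min_spacing/2 - 1 so
    # no cell ever crosses the midline to a neighbour: every pixel of a cell is
    # strictly closer to its own nucleus than to any other, which makes the
    # nucleus-seeded proximity partition exact.
    cap = cfg.min_spacing / 2.0 - 1.0
    radii = np.clip(rng.normal(cfg.cell_radius_mean, cfg.cell_radius_sd, n),
                    cfg.nucleus_radius + 2.0, None)
    ax_a = np.minimum(radii * rng.uniform(0.85, 1.25, n), cap)
    ax_b = np.minimum(radii * rng.uniform(0.85, 1.25, n), cap)
    theta = rng.uniform(0.0, np.pi, n)

    cell_mask = np.zeros(shape, dtype=np.int32)
    claim = np.full(shape, np.inf, dtype=np.float64)  # best normalized ellipse distance
    for k in range(n):
        cy, cx = centres[k]
        a, b, th = ax_a[k], ax_b[k], theta[k]
        ext = max(a, b)
        r0 = max(int(np.floor(cy - ext)), 0)
        r1 = min(int(np.ceil(cy + ext)) + 1, cfg.height)
        c0 = max(int(np.floor(cx - ext)), 0)
        c1 = min(int(np.ceil(cx + ext)) + 1, cfg.width)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dy, dx = rr - cy, cc - cx
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        d = (u / a) ** 2 + (v / b) ** 2
        win = (d <= 1.0) & (d < claim[r0:r1, c0:c1])
        cell_mask[r0:r1, c0:c1][win] = k + 1
        claim[r0:r1, c0:c1][win] = d[win]

    # GFP and adipocyte assignment: exact rounded counts.
    gfp_on = np.zeros(n, dtype=bool)
    n_gfp = min(_exact_count(cfg.gfp_fraction, n), n)
    if n_gfp:
        gfp_on[rng.choice(n, size=n_gfp, replace=False)] = True
    is_adipo = np.zeros(n, dtype=bool)
    n_adipo = min(_exact_count(cfg.adipocyte_fraction, n), n)
    if cfg.gfp_suppresses_droplets:
        pool = np.flatnonzero(~gfp_on)
        n_adipo = min(n_adipo, len(pool))
        if n_adipo:
            is_adipo[rng.choice(pool, size=n_adipo, replace=False)] = True
    elif n_adipo:
        is_adipo[rng.choice(n, size=n_adipo, replace=False)] = True

    # Lipid droplets inside adipocyte cells.
    droplet_mask = np.zeros(shape, dtype=bool)
    for k in np.flatnonzero(is_adipo):
        cy, cx = centres[k]
        regime = cfg.droplet_regime
        if regime == "mixed":
            regime = "small" if rng.uniform() < 0.5 else "large"
        if regime == "large":
            rad = cfg.large_droplet_radius_factor * min(ax_a[k], ax_b[k])
            offs = [rng.uniform(-0.2, 0.2, 2) * min(ax_a[k], ax_b[k])]
            rads = [max(rad, 1.5)]
        else:
            lo, hi = cfg.small_droplet_count
            count = int(rng.integers(lo, hi + 1))
            rads = rng.uniform(*cfg.small_droplet_radius, count)
            offs = rng.uniform(-0.55, 0.55, (count, 2)) * min(ax_a[k], ax_b[k])
        placed_any = False
        for rad, off in zip(np.atleast_1d(rads), np.atleast_2d(offs)):
            rr, cc = _disk_pixels(np.array([cy, cx]) + off, float(rad), shape)
            keep = cell_mask[rr, cc] == k + 1
            if keep.any():
                droplet_mask[rr[keep], cc[keep]] = True
                placed_any = True
        if not placed_any:
            # guarantee >= 1 droplet pixel: fall back to the nucleus centre
            r, c = int(round(cy)), int(round(cx))
            r = min(max(r, 0), cfg.height - 1)
            c = min(max(c, 0), cfg.width - 1)
            droplet_mask[r, c] = True

    # Nuclei (disks at the cell centres; centres are >= min_spacing apart).
    nucleus_mask = np.zeros(shape, dtype=bool)
    for k in range(n):
        rr, cc = _disk_pixels(centres[k], cfg.nucleus_radius, shape)
        nucleus_mask[rr, cc] = True

    gfp_cells = np.isin(cell_mask, np.flatnonzero(gfp_on) + 1)

    top = float(2 ** cfg.bit_depth - 1)
    dtype = np.uint8 if cfg.bit_depth == 8 else np.uint16

    def render(fg_mask: np.ndarray, fg_level: float) -> np.ndarray:
        img = np.full(shape, lv.background, dtype=np.float64)
        img[fg_mask] = fg_level
        if cfg.noise_sd > 0:
            img += rng.normal(0.0, cfg.noise_sd, shape)
        return np.clip(np.rint(img), 0, top).astype(dtype)

    dapi = render(nucleus_mask, lv.nucleus)
    lipid_red = render(cell_mask > 0, lv.cytoplasm)
    lipid_green = render(droplet_mask, lv.droplet_green)
    gfp = render(gfp_cells, lv.gfp)

    oro = np.empty((*shape, 3), dtype=np.float64)
    cells = cell_mask > 0
    for p in range(3):
        plane = np.full(shape, lv.oro_background[p])
        plane[cells] = lv.oro_cell[p]
        plane[droplet_mask] = lv.oro_droplet[p]
        oro[..., p] = plane
    if cfg.oro_noise_sd > 0:
        oro += rng.normal(0.0, cfg.oro_noise_sd, oro.shape)
    oro_rgb = np.clip(np.rint(oro), 0, 255).astype(np.uint8)

    n_drop_px = np.zeros(n, dtype=int)
    if n:
        import scipy.ndimage as ndi
        n_drop_px = ndi.sum_labels(droplet_mask, cell_mask, index=np.arange(1, n + 1)).astype(int)
    table = pd.DataFrame({
        "label": np.arange(1, n + 1),
        "row": centres[:, 0] if n else np.array([], dtype=float),
        "col": centres[:, 1] if n else np.array([], dtype=float),
        "is_adipocyte": is_adipo,
        "n_droplet_px": n_drop_px,
        "gfp_on": gfp_on,
    })

    truth = GroundTruth(table=table, cell_mask=cell_mask, droplet_mask=droplet_mask)
    return SynthWell(dapi=dapi, lipid_red=lipid_red, lipid_green=lipid_green,
                     gfp=gfp, oro_rgb=oro_rgb, truth=truth, config=cfg)


def _config_to_dict(cfg: SynthConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    if d["intensity"] is not None:
        d["intensity"] = {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in d["intensity"].items()}
    return d


def write_fixture(well: SynthWell, directory: str | Path) -> dict[str, Path]:
    """Write a well to disk: one TIFF per channel, truth CSV, config YAML.

    Returns a manifest mapping output names to paths.  Arrays round-trip
    exactly through :func:`read_fixture`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    for name in ("dapi", "lipid_red", "lipid_green", "gfp"):
        path = directory / f"{name}.tif"
        tifffile.imwrite(path, getattr(well, name))
        manifest[name] = path
    path = directory / "oro_rgb.tif"
    tifffile.imwrite(path, well.oro_rgb, photometric="rgb")
    manifest["oro_rgb"] = path

    truth_path = directory / "truth.csv"
    well.truth.table.to_csv(truth_path, index=False)
    manifest["truth"] = truth_path

    cfg_path = directory / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(_config_to_dict(well.config), sort_keys=True))
    manifest["config"] = cfg_path
    return manifest


def read_fixture(directory: str | Path) -> dict[str, np.ndarray | pd.DataFrame]:
    """Read back the channels and truth table written by :func:`write_fixture`."""
    directory = Path(directory)
    out: dict[str, np.ndarray | pd.DataFrame] = {}
    for name in ("dapi", "lipid_red", "lipid_green", "gfp", "oro_rgb"):
        path = directory / f"{name}.tif"
        if path.exists():
            out[name] = tifffile.imread(path)
    truth = directory / "truth.csv"
    if truth.exists():
        out["truth"] = pd.read_csv(truth)
    return out
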