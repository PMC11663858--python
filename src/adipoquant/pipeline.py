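"""Batch orchestration of the two quantification workflows.

* Nile Red workflow: per well — segment cells from the red channel,
  threshold the green channel into droplets, select droplet-containing
  cells, compute the droplet-positive percentage; then summarize per
  condition and compare conditions with Kruskal-Wallis when the design
  allows.
* Rescue workflow: per well — detect nuclei in DAPI, watershed-partition
  the area around each nucleus, normalize the GFP channel, compute the Oil
  Red O ratio image, aggregate per-cell maxima, gate into GFP x ORO
  quadrants and export the scatter table/plot.

Experiments are described by a YAML config (see :class:`ExperimentConfig`);
all outputs are CSV/PNG plus a JSON run manifest echoing every parameter,
so a run is fully reproducible from its config.  Failures in one well are
isolated: the remaining wells still run and the manifest records the error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile
import yaml

from . import segmentation as seg
from . import lipid_scoring as ls
from . import quantification as quant
from . import stats as st

logger = logging.getLogger(__name__)

__all__ = [
    "WellSpec",
    "ExperimentConfig",
    "run_nilered_pipeline",
    "run_rescue_pipeline",
]


@dataclass
class WellSpec:
    name: str
    condition: str
    channels: dict[str, str]  # channel name -> TIFF path


@dataclass
class ExperimentConfig:
    wells: list[WellSpec]
    output_dir: str
    mode: str = "nilered"     # or "rescue"
    seed: int = 0
    params: dict = field(default_factory=dict)

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        wells = [WellSpec(name=w["name"], condition=w.get("condition", "default"),
                          channels={k: v for k, v in w.items() if k not in ("name", "condition")})
                 for w in raw["wells"]]
        return ExperimentConfig(wells=wells, output_dir=raw["output_dir"],
                                mode=raw.get("mode", "nilered"),
                                seed=int(raw.get("seed", 0)),
                                params=raw.get("params", {}))

    def validate(self, required_channels: tuple[str, ...]) -> None:
        for well in self.wells:
            for ch in required_channels:
                if ch not in well.channels:
                    raise ValueError(f"well {well.name!r}: missing channel {ch!r}")
                if not Path(well.channels[ch]).exists():
                    raise ValueError(f"well {well.name!r}: file not found: {well.channels[ch]}")


def _read(path: str) -> np.ndarray:
    return tifffile.imread(path)


def _write_manifest(outdir: Path, mode: str, config: ExperimentConfig,
                    params: dict, failures: dict[str, str]) -> Path:
    manifest = {
        "mode": mode,
        "seed": config.seed,
        "parameters": params,
        "wells": [dataclasses.asdict(w) for w in config.wells],
        "failed_wells": failures,
    }
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_nilered_pipeline(config: ExperimentConfig) -> dict[str, Path]:
    """Nile Red quantification over all wells of an experiment.

    Writes ``per_well.csv`` (one row per well: counts and percentage),
    ``condition_summary.csv`` (mean/SD of well percentages per condition),
    ``stats_report.csv`` (Kruskal-Wallis + Dunn over conditions, when >= 2
    conditions each have >= 2 wells) and ``run_manifest.json``.
    """
    config.validate(("lipid_red", "lipid_green"))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    seg_params = seg.LipidRedParams(
        threshold=p.get("cell_threshold", "auto"),
        min_area=int(p.get("min_cell_area", 30)),
        peak_min_distance=int(p.get("peak_min_distance", 16)),
    )
    droplet_threshold = p.get("droplet_threshold", "auto")
    min_droplet_area = int(p.get("min_droplet_area", 4))
    overlap_min = int(p.get("droplet_overlap_min", 1))

    rows, failures = [], {}
    for well in config.wells:
        try:
            red = _read(well.channels["lipid_red"])
            green = _read(well.channels["lipid_green"])
            cells = seg.segment_cells_from_lipid_red(red, seg_params)
            droplets = ls.segment_droplets(green, threshold=droplet_threshold,
                                           min_droplet_area=min_droplet_area)
            n_total = int(cells.max())
            selected, _ = quant.cells_having_droplets(cells, droplets, overlap_min=overlap_min)
            percent = quant.differentiated_fraction(len(selected), n_total)
            logger.info("well %s: %d/%d droplet-positive (%.1f%%), droplet threshold %.1f",
                        well.name, len(selected), n_total, percent, droplets.threshold)
            rows.append({"well": well.name, "condition": well.condition,
                         "n_total": n_total, "n_droplet_pos": len(selected),
                         "percent_droplet_pos": round(percent, 1),
                         "droplet_threshold": droplets.threshold})
        except Exception as exc:  # isolate per-well failures
            logger.error("well %s failed: %s", well.name, exc)
            failures[well.name] = str(exc)

    per_well = pd.DataFrame(rows, columns=["well", "condition", "n_total", "n_droplet_pos",
                                           "percent_droplet_pos", "droplet_threshold"])
    outputs = {"per_well": outdir / "per_well.csv"}
    per_well.to_csv(outputs["per_well"], index=False)

    if not per_well.empty:
        summary = per_well.groupby("condition", sort=True)["percent_droplet_pos"] \
            .agg(n_wells="count", mean_percent="mean", sd_percent="std").reset_index()
        outputs["condition_summary"] = outdir / "condition_summary.csv"
        summary.to_csv(outputs["condition_summary"], index=False)

        sizes = per_well.groupby("condition").size()
        if len(sizes) >= 2 and (sizes >= 2).all():
            kw = st.kruskal_wallis_multi(per_well, value="percent_droplet_pos",
                                         group="condition")
            report = kw.pairwise.copy()
            report.insert(0, "h_statistic", kw.h)
            report.insert(1, "p_global", kw.p_value)
            outputs["stats_report"] = outdir / "stats_report.csv"
            report.to_csv(outputs["stats_report"], index=False)

    outputs["manifest"] = _write_manifest(outdir, "nilered", config, {
        "cell_threshold": seg_params.threshold, "min_cell_area": seg_params.min_area,
        "peak_min_distance": seg_params.peak_min_distance,
        "droplet_threshold": droplet_threshold, "min_droplet_area": min_droplet_area,
        "droplet_overlap_min": overlap_min,
    }, failures)
    return outputs


def run_rescue_pipeline(config: ExperimentConfig) -> dict[str, Path]:
    """Rescue-experiment scoring over all wells of an experiment.

    Per well: nuclei-seeded watershed segmentation around each nucleus,
    GFP auto-contrast normalization, Oil Red O ratio image, per-cell
    maxima, quadrant gating.  Writes ``<well>_cells.csv`` (one row per
    cell), ``<well>_scatter.png``, ``gated_counts.csv`` (with the gate
    thresholds echoed in header comment lines) and ``run_manifest.json``.
    """
    config.validate(("dapi", "gfp", "oro_rgb"))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    gates = quant.GateConfig(
        gfp_threshold=float(p.get("gfp_threshold", 127.0)),
        oro_ratio_threshold=float(p.get("oro_ratio_threshold", 1.0)),
    )
    min_distance = float(p.get("nucleus_min_distance", 8.0))
    reach = float(p.get("cell_reach", 18.0))

    outputs: dict[str, Path] = {}
    count_rows, failures = [], {}
    for well in config.wells:
        try:
            dapi = _read(well.channels["dapi"])
            gfp = _read(well.channels["gfp"])
            oro = _read(well.channels["oro_rgb"])

            seeds = seg.detect_nuclei(dapi, min_distance=min_distance)
            # foreground: pixels within `reach` of a nucleus, partitioned by proximity
            seed_img = np.zeros(dapi.shape, dtype=bool)
            if len(seeds):
                seed_img[tuple(seeds.coords.T)] = True
                dist = ndi.distance_transform_edt(~seed_img)
            else:
                dist = np.full(dapi.shape, np.inf)
            fg = dist <= reach
            cells = seg.segment_cells_watershed(seeds, dist, fg)

            gfp_norm = ls.normalize_autocontrast(gfp)
            oro_ratio = ls.oro_ratio_image(oro)
            records = ls.per_cell_stats(cells, droplets=None,
                                        gfp_norm=gfp_norm, oro_ratio=oro_ratio)
            table = quant.scatter_table(records, gates,
                                        plot_path=outdir / f"{well.name}_scatter.png")
            table.to_csv(outdir / f"{well.name}_cells.csv", index=False)
            outputs[f"{well.name}_cells"] = outdir / f"{well.name}_cells.csv"
            outputs[f"{well.name}_scatter"] = outdir / f"{well.name}_scatter.png"

            gated = quant.gate_cells(records, gates)
            count_rows.append({"well": well.name, "condition": well.condition,
                               "n_total": gated.n_total, **gated.counts})
        except Exception as exc:
            logger.error("well %s failed: %s", well.name, exc)
            failures[well.name] = str(exc)

    counts = pd.DataFrame(count_rows)
    counts_path = outdir / "gated_counts.csv"
    with open(counts_path, "w") as fh:
        fh.write(f"# gfp_threshold={gates.gfp_threshold}\n")
        fh.write(f"# oro_ratio_threshold={gates.oro_ratio_threshold}\n")
        counts.to_csv(fh, index=False)
    outputs["gated_counts"] = counts_path

    outputs["manifest"] = _write_manifest(outdir, "rescue", config, {
        "gfp_threshold": gates.gfp_threshold,
        "oro_ratio_threshold": gates.oro_ratio_threshold,
        "nucleus_min_distance": min_distance, "cell_reach": reach,
    }, failures)
    return outputs
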