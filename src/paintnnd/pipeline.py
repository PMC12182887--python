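"""Config-driven orchestration of the full analysis graph.

For each condition (a ligand labeling strategy, a treatment, ...) and each
cell, the pipeline clusters both channels into protein positions and runs
the three NND analyses — receptor-receptor first-NND (oligomerization),
ligand-to-receptor cross-NND (co-localization) and ligand-ligand first-NND
(ligand clustering) — each against its own CSR null at that cell's measured
density. Per-condition Δ areas are aggregated as mean ± population standard
deviation and compared across conditions by one-way ANOVA. Every random
draw is seeded from the root seed, so a rerun with the same config is
byte-identical (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import spatial
from .clustering import ProteinPositionSet, cluster_channel
from .io import LocalizationTable, RegionOfInterest, read_localizations, read_roi
from .model import OligomerizationModel

__all__ = ["AnalysisSettings", "CellInputs", "RunConfig", "CellResult",
           "run_condition", "run_report", "load_config"]

logger = logging.getLogger("paintnnd")

#: The three per-cell NND analyses, in reporting order.
ANALYSES = ("receptor_receptor", "ligand_receptor", "ligand_ligand")


@dataclass
class AnalysisSettings:
    """Tunable parameters of the analysis graph (defaults as printed defaults).

    radius/min_locs: clustering; bin_size 5 nm and window 0-200 nm: NND
    histograms and Δ area; csr_n: molecules per simulated null.
    """

    radius: float = 10.0
    min_locs: int = 10
    bin_size: float = 5.0
    norm_range: tuple[float, float] = (0.0, 200.0)
    csr_n: int = 5_000_000
    use_z: bool = False
    seed: int = 0


@dataclass
class CellInputs:
    """One cell's aligned, drift-corrected input tables and ROI."""

    name: str
    receptor: LocalizationTable
    ligand: LocalizationTable
    roi: RegionOfInterest


@dataclass
class RunConfig:
    settings: AnalysisSettings
    conditions: dict[str, list[CellInputs]]
    output_dir: Path = Path("paintnnd_out")


@dataclass
class CellResult:
    """Per-cell Δ areas (and diagnostics) for the three NND analyses."""

    name: str
    delta_areas: dict[str, float]
    histograms: dict[str, spatial.Histogram]
    csr_histograms: dict[str, spatial.Histogram]
    densities: dict[str, float]
    n_positions: dict[str, int]
    seeds: dict[str, int]


def _cell_seed(root: int, condition_index: int, cell_index: int,
               analysis_index: int) -> int:
    """Deterministic child seed below 2^31 for one (cell, analysis)."""
    ss = np.random.SeedSequence([int(root), condition_index, cell_index,
                                 analysis_index])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def analyze_cell(
    cell: CellInputs,
    settings: AnalysisSettings,
    seeds: dict[str, int],
) -> CellResult:
    """Cluster both channels and run the three NND-vs-CSR analyses."""
    receptor = cluster_channel(cell.receptor, settings.radius, settings.min_locs,
                               use_z=settings.use_z)
    ligand = cluster_channel(cell.ligand, settings.radius, settings.min_locs,
                             use_z=settings.use_z)
    if len(receptor) < 2 or len(ligand) < 2:
        raise ValueError(
            f"cell {cell.name!r}: clustering left too few positions "
            f"(receptor {len(receptor)}, ligand {len(ligand)})")
    specs: dict[str, tuple[ProteinPositionSet, ProteinPositionSet | None]] = {
        "receptor_receptor": (receptor, None),
        "ligand_receptor": (ligand, receptor),
        "ligand_ligand": (ligand, None),
    }
    delta_areas, hists, csr_hists, densities, n_pos = {}, {}, {}, {}, {}
    for key, (query, reference) in specs.items():
        model = OligomerizationModel(
            query, roi=cell.roi, reference=reference,
            bin_size=settings.bin_size, norm_range=settings.norm_range,
            csr_n=settings.csr_n, label=cell.name)
        res = model.fit(seed=seeds[key])
        delta_areas[key] = res.delta_area
        hists[key] = res.histogram
        csr_hists[key] = res.csr_histogram
        densities[key] = res.density_um2
        n_pos[key] = res.nnd.n_query
    return CellResult(name=cell.name, delta_areas=delta_areas, histograms=hists,
                      csr_histograms=csr_hists, densities=densities,
                      n_positions=n_pos, seeds=dict(seeds))


def run_condition(
    cells: list[CellInputs],
    settings: AnalysisSettings,
    condition_index: int = 0,
) -> list[CellResult]:
    """Analyze every cell of one condition; failing cells are skipped and logged."""
    if not cells:
        raise ValueError("condition has no cells")
    results: list[CellResult] = []
    for j, cell in enumerate(cells):
        seeds = {key: _cell_seed(settings.seed, condition_index, j, k)
                 for k, key in enumerate(ANALYSES)}
        try:
            results.append(analyze_cell(cell, settings, seeds))
        except (ValueError, RuntimeError) as exc:
            logger.warning("skipping cell %s: %s", cell.name, exc)
    return results


def run_report(config: RunConfig) -> dict:
    """Full multi-condition run: per-cell Δ areas, aggregates, ANOVA, files.

    Returns the report dict and writes ``report.json``, ``delta_areas.csv``
    and per-analysis histogram CSVs under ``config.output_dir``.
    """
    s = config.settings
    report: dict = {
        "settings": {**dataclasses.asdict(s),
                     "norm_range": list(s.norm_range)},
        "conditions": {},
        "anova": {},
    }
    per_condition: dict[str, list[CellResult]] = {}
    for i, (label, cells) in enumerate(config.conditions.items()):
        per_condition[label] = run_condition(cells, s, condition_index=i)

    rows = []
    for label, results in per_condition.items():
        entry: dict = {"n_cells": len(results), "cells": {}}
        for res in results:
            entry["cells"][res.name] = {
                "delta_areas": res.delta_areas,
                "densities_um2": res.densities,
                "n_positions": res.n_positions,
                "seeds": res.seeds,
            }
            for key in ANALYSES:
                rows.append({"condition": label, "cell": res.name,
                             "analysis": key,
                             "delta_area": res.delta_areas[key]})
        for key in ANALYSES:
            vals = np.array([r.delta_areas[key] for r in results])
            if len(vals):
                entry[key] = {"mean": float(vals.mean()),
                              "std": float(vals.std()),
                              "values": vals.tolist()}
            curves = [r.histograms[key] for r in results]
            if curves:
                mean, std = spatial.aggregate_conditions(curves)
                entry.setdefault("curves", {})[key] = {
                    "bin_edges": curves[0].bin_edges.tolist(),
                    "mean": mean.tolist(), "std": std.tolist()}
        report["conditions"][label] = entry

    # Across-condition ANOVA per analysis, where >= 2 conditions have >= 2 cells.
    for key in ANALYSES:
        groups = {label: np.array([r.delta_areas[key] for r in results])
                  for label, results in per_condition.items()
                  if len(results) >= 2}
        if len(groups) >= 2:
            a = spatial.compare_conditions(groups)
            report["anova"][key] = {
                "F": a.f_statistic, "p": a.p_value, "stars": a.stars,
                "group_means": a.group_means, "group_stds": a.group_stds,
                "group_sizes": a.group_sizes}

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
    pd.DataFrame(rows).to_csv(outdir / "delta_areas.csv", index=False)
    logger.info("report written to %s (root seed %d)", outdir, s.seed)
    return report


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    Schema::

        seed: 1
        output_dir: out
        clustering: {radius: 10, min_locs: 10}
        histogram: {bin_size: 5, range: [0, 200]}
        csr: {n_molecules: 5000000}
        use_z: false
        conditions:
          ALFA-EGF:
            - name: cell1
              receptor: cell1_receptor.hdf5   # or .csv
              receptor_channel: receptor      # optional dataset name
              ligand: cell1_ligand.hdf5
              ligand_channel: ligand
              roi: cell1_roi.json
              pixel_size: null                # nm/px if tables are in pixels
    """
    path = Path(path)
    with open(path) as f:
        raw = yaml.safe_load(f)
    clustering = raw.get("clustering", {})
    hist = raw.get("histogram", {})
    settings = AnalysisSettings(
        radius=float(clustering.get("radius", 10.0)),
        min_locs=int(clustering.get("min_locs", 10)),
        bin_size=float(hist.get("bin_size", 5.0)),
        norm_range=tuple(hist.get("range", (0.0, 200.0))),
        csr_n=int(raw.get("csr", {}).get("n_molecules", 5_000_000)),
        use_z=bool(raw.get("use_z", False)),
        seed=int(raw.get("seed", 0)),
    )
    base = path.parent
    conditions: dict[str, list[CellInputs]] = {}
    for label, cells in raw["conditions"].items():
        loaded = []
        for spec in cells:
            px = spec.get("pixel_size")
            loaded.append(CellInputs(
                name=str(spec.get("name", f"cell{len(loaded)}")),
                receptor=read_localizations(base / spec["receptor"], pixel_size=px,
                                            channel_id=spec.get("receptor_channel")),
                ligand=read_localizations(base / spec["ligand"], pixel_size=px,
                                          channel_id=spec.get("ligand_channel")),
                roi=read_roi(base / spec["roi"]),
            ))
        conditions[label] = loaded
    return RunConfig(settings=settings, conditions=conditions,
                     output_dir=Path(raw.get("output_dir", "paintnnd_out")))
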