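"""End-to-end orchestration: read → QC → phenotype → CAA → IA → CNAA → quantify.

`run_pipeline` is a pure function of its configuration (plus the input
table): rerunning with the same config and inputs reproduces the summary
CSVs byte for byte.  Every run writes a machine-readable manifest recording
the configuration hash, package version, and the row counts at each stage,
so any number in the outputs can be traced to the exact inputs and
parameters that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import __version__
from .caa import CAAConfig, delineate_aggregates, infiltration_areas
from .cnaa import NeighborhoodConfig, neighborhoods, summarize_nnd, tag_regions
from .errors import ConfigError, DataError
from .io import CellTable, ColumnSchema, FOVWindow, QCConfig, apply_qc, pixels_to_microns, read_cell_table, write_cell_table
from .phenotype import HLACallConfig, PhenotypeRule, assign_phenotypes, call_hla1_status, default_rules
from .quantify import correlogram, fov_ratios, coefficient_of_variation, export_heatmap

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    ``input_csv`` may be None when ``cells`` is passed to
    :func:`run_pipeline` directly (e.g. a freshly generated synthetic
    table).
    """

    output_dir: str
    input_csv: str | None = None
    schema: ColumnSchema = field(default_factory=ColumnSchema)
    qc: QCConfig = field(default_factory=QCConfig)
    rules: list[PhenotypeRule] | None = None
    tumor_mask_marker: str = "S100"
    hla: HLACallConfig = field(default_factory=HLACallConfig)
    caa: CAAConfig = field(default_factory=CAAConfig)
    cnaa: NeighborhoodConfig = field(default_factory=NeighborhoodConfig)
    window_margin_um: float = 0.0
    correlogram_alpha: float = 0.05
    correlogram_min_n: int = 3
    seed: int = 0

    def config_hash(self) -> str:
        def default(o):
            try:
                return asdict(o)
            except TypeError:
                return repr(o)

        payload = json.dumps(asdict_safe(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def asdict_safe(obj) -> dict:
    out = {}
    for k, v in vars(obj).items():
        try:
            json.dumps(v)
            out[k] = v
        except TypeError:
            try:
                out[k] = asdict(v)
            except TypeError:
                out[k] = repr(v)
    return out


def _stage(manifest: dict, name: str, n_rows: int) -> None:
    manifest["stages"].append({"stage": name, "n_rows": int(n_rows)})


def run_pipeline(cfg: RunConfig, cells: CellTable | None = None) -> Path:
    """Run the full analysis chain and write all outputs to ``output_dir``.

    Outputs: ``cells_phenotyped.csv``, ``fov_ratios.csv`` and
    ``ia_ratios.csv`` (+ heat maps), ``aggregates.geojson`` and
    ``aggregate_summary.csv`` (with WKT polygons), ``neighborhoods.csv``,
    ``nnd_per_fov.csv`` / ``nnd_summary.csv``, ``correlogram.csv``, and
    ``manifest.json``.

    Any stage failure aborts with the stage name prepended to the error.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:
                raise type(e)(f"[stage {name}] {e}") from e

        return deco

    if cells is None:
        if cfg.input_csv is None:
            raise ConfigError("either input_csv or an in-memory cell table is required")
        cells = stage("read")(lambda: read_cell_table(cfg.input_csv, cfg.schema))
    _stage(manifest, "input", len(cells))

    if cells.unit == "px":
        if cfg.qc.pixel_size_um is None:
            raise ConfigError("input is in pixels but qc.pixel_size_um is not set")
        cells = stage("unit_conversion")(lambda: pixels_to_microns(cells, cfg.qc.pixel_size_um))

    cells_qc, qc_report = stage("qc")(lambda: apply_qc(cells, cfg.qc))
    manifest["qc_report"] = qc_report.as_dict()
    _stage(manifest, "qc", len(cells_qc))

    cells_ph = stage("phenotype")(
        lambda: assign_phenotypes(cells_qc, cfg.rules, tumor_mask_marker=cfg.tumor_mask_marker)
    )
    cells_ph = stage("hla_call")(lambda: call_hla1_status(cells_ph, cfg.hla))
    manifest["hla1_threshold"] = cells_ph.meta.get("hla1_threshold")
    _stage(manifest, "phenotype", len(cells_ph))
    write_cell_table(cells_ph, out / "cells_phenotyped.csv")

    # CAA + infiltration areas per FOV
    ia_by_fov: dict = {}
    agg_rows = []
    geo_features = []
    for fov in cells_ph.fov_ids:
        window = FOVWindow.from_cells(cells_ph, fov, margin=cfg.window_margin_um)
        aggs = stage("caa")(lambda: delineate_aggregates(cells_ph, window, cfg.caa, ("Tumor", "CD3")))
        ia = stage("ia")(
            lambda: infiltration_areas(aggs["Tumor"], aggs["CD3"])
            if (aggs["Tumor"] or aggs["CD3"])
            else None
        )
        for label, alist in aggs.items():
            for i, a in enumerate(alist):
                agg_rows.append({
                    "fov_id": fov, "class": label, "aggregate": i,
                    "n_squares": a.n_squares, "area_um2": a.area_um2,
                    "wkt": a.polygon.wkt if a.polygon is not None else "",
                })
                if a.polygon is not None and not a.polygon.is_empty:
                    geo_features.append({
                        "type": "Feature",
                        "properties": {"fov_id": str(fov), "class": label, "area_um2": a.area_um2},
                        "geometry": shapely.geometry.mapping(a.polygon),
                    })
        if ia is not None:
            ia_by_fov[fov] = ia
            agg_rows.append({
                "fov_id": fov, "class": "IA", "aggregate": 0,
                "n_squares": len(ia.squares), "area_um2": ia.area_um2,
                "wkt": ia.polygon.wkt,
            })
            if not ia.polygon.is_empty:
                geo_features.append({
                    "type": "Feature",
                    "properties": {
                        "fov_id": str(fov), "class": "IA", "area_um2": ia.area_um2,
                        "infiltration_fraction": ia.infiltration_fraction,
                    },
                    "geometry": shapely.geometry.mapping(ia.polygon),
                })
    agg_summary = pd.DataFrame(
        agg_rows, columns=["fov_id", "class", "aggregate", "n_squares", "area_um2", "wkt"]
    )
    agg_summary.to_csv(out / "aggregate_summary.csv", index=False)
    (out / "aggregates.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": geo_features}, indent=1)
    )
    _stage(manifest, "aggregates", len(agg_summary))

    # infiltration fractions
    ia_rows = []
    for fov, ia in ia_by_fov.items():
        ia_rows.append({
            "fov_id": fov,
            "ia_area_um2": ia.area_um2,
            "tumor_area_um2": ia.tumor_area_um2,
            "cd3_area_um2": ia.cd3_area_um2,
            "infiltration_fraction": ia.infiltration_fraction,
        })
    ia_table = pd.DataFrame(ia_rows, columns=["fov_id", "ia_area_um2", "tumor_area_um2", "cd3_area_um2", "infiltration_fraction"])
    if len(ia_table):
        fracs = ia_table["infiltration_fraction"].dropna()
        manifest["infiltration_fraction_mean"] = float(fracs.mean()) if len(fracs) else None
        manifest["infiltration_fraction_cv"] = coefficient_of_variation(fracs)
    ia_table.to_csv(out / "infiltration_areas.csv", index=False)

    # ratios: whole FOV and IA-restricted
    ratios = stage("quantify")(lambda: fov_ratios(cells_ph))
    ratios.to_csv(out / "fov_ratios.csv")
    export_heatmap(ratios, out / "fov_ratio_matrix.csv", out / "fov_ratio_heatmap.png")
    ia_polys = {fov: ia.polygon for fov, ia in ia_by_fov.items()}
    if ia_polys:
        ia_ratios = stage("quantify_ia")(lambda: fov_ratios(cells_ph, region=ia_polys))
        ia_ratios.to_csv(out / "ia_ratios.csv")
    _stage(manifest, "ratios", len(ratios))

    # correlogram across FOVs (per sample when sample ids exist)
    corr_frames = []
    if "sample_id" in cells_ph.data.columns:
        for sample, fovs in cells_ph.data.groupby("sample_id")["fov_id"]:
            sub = ratios.loc[ratios.index.isin(fovs.unique())]
            if len(sub) >= 2:
                c = correlogram(sub, cfg.correlogram_alpha, cfg.correlogram_min_n).to_frame()
                c.insert(0, "sample_id", sample)
                corr_frames.append(c)
    else:
        if len(ratios) >= 2:
            corr_frames.append(correlogram(ratios, cfg.correlogram_alpha, cfg.correlogram_min_n).to_frame())
    if corr_frames:
        pd.concat(corr_frames, ignore_index=True).to_csv(out / "correlogram.csv", index=False)

    # CNAA with region tagging against each FOV's IA
    records = stage("cnaa")(lambda: neighborhoods(cells_ph, cfg.cnaa))
    tagged = []
    for fov, grp in records.groupby("fov_id", sort=False):
        ia = ia_by_fov.get(fov)
        tagged.append(tag_regions(grp, ia) if ia is not None else grp)
    records = pd.concat(tagged, ignore_index=True) if tagged else records
    records.to_csv(out / "neighborhoods.csv", index=False)
    _stage(manifest, "neighborhoods", len(records))

    if len(records):
        keys = [k for k in ("sample_id", "region", "center_class") if k in records.columns]
        per_fov, summary = summarize_nnd(records, group_keys=keys)
        per_fov.to_csv(out / "nnd_per_fov.csv", index=False)
        summary.to_csv(out / "nnd_summary.csv", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return out
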