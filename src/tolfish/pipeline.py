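"""End-to-end orchestration: simulate → segment → detect → colocalize → report.

A run is driven by a flat YAML config (see :data:`DEFAULT_CONFIG`) and a
seed; for a fixed config+seed the outputs are byte-identical.  The same
analysis stages also run on externally supplied TIFF stacks (with an
optional label-mask TIFF) in analysis-only mode.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc, report, segment, simulate, spots
from .logic import Condition

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "condition": {"genotype": "WT_pWW0", "inducer": "M_XYLENE", "iptg": False, "rifampin": False},
    "simulate": {"n_fields": 2},      # plus any SimParams field by name
    "analyze": {
        "use_truth_mask": True,       # segment from phase contrast when False
        "l_dense": 0.5,
        "l_diffuse": 0.2,
        "normalize_scope": "cell",
        "d_coloc": 2.0,
        "d_adj": 8.0,
        "peripheral_mode": "contour",  # or "band" (fixed-width ring)
        "band_width_px": 2.0,
        "detection": {},              # DetectionParams overrides
        "dispersion": {"disc_radius": 4.0, "t_focal": 0.5},
    },
    "report": {"n_boot": 1000, "denominator": "all_cells"},
}


def load_config(path_or_dict) -> dict:
    """Load and schema-check a pipeline config, merged over the defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = copy.deepcopy(path_or_dict or {})
    if not isinstance(user, dict):
        raise ValueError("config must be a mapping")
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in user.items():
        if key not in cfg and key not in ("input", "mask"):
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            for k2, v2 in val.items():
                if key == "analyze" and k2 not in cfg["analyze"]:
                    raise ValueError(f"unknown analyze option {k2!r}")
                cfg[key][k2] = v2
        else:
            cfg[key] = val
    # validate eagerly so failures precede any computation
    Condition.from_dict(cfg["condition"])
    sim_kwargs = {k: v for k, v in cfg["simulate"].items() if k != "n_fields"}
    _sim_params(sim_kwargs)
    spots.DetectionParams(**cfg["analyze"].get("detection", {}))
    if not (0 < cfg["analyze"]["l_diffuse"] < cfg["analyze"]["l_dense"] < 1):
        raise ValueError("require 0 < l_diffuse < l_dense < 1")
    return cfg


def _sim_params(overrides: dict) -> simulate.SimParams:
    fields = {f.name for f in simulate.SimParams.__dataclass_fields__.values()}
    bad = set(overrides) - fields
    if bad:
        raise ValueError(f"unknown SimParams fields: {sorted(bad)}")
    overrides = {
        k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
    }
    return simulate.SimParams(**overrides)


@dataclass
class FieldResult:
    field_id: int
    foci: pd.DataFrame
    cells: pd.DataFrame
    dispersion: pd.DataFrame
    zones: dict                    # cell_id -> NucleoidZones


def analyze_field(
    stack: simulate.ImageStack,
    cfg_analyze: dict,
    field_id: int = 0,
    truth_labels: np.ndarray | None = None,
) -> FieldResult:
    """Run segmentation, detection, zoning and pairing on one image stack."""
    det = spots.DetectionParams(**cfg_analyze.get("detection", {}))
    l_dense = cfg_analyze.get("l_dense", 0.5)
    l_diffuse = cfg_analyze.get("l_diffuse", 0.2)
    disp_cfg = cfg_analyze.get("dispersion", {})

    mask = truth_labels if cfg_analyze.get("use_truth_mask", True) else None
    cells = segment.segment_cells(stack.channels["phase"], truth_mask=mask)

    # field-level background of the red channel (cell-free pixels), for the
    # dispersion presence test
    red_bg = None
    if "red" in stack.channels and cells:
        allmask = np.zeros(stack.shape, dtype=bool)
        for c in cells:
            allmask |= c.mask
        free = stack.channels["red"].astype(float)[~allmask]
        if free.size:
            med = float(np.median(free))
            red_bg = (med, 1.4826 * float(np.median(np.abs(free - med))))

    foci_rows, cell_rows, disp_rows = [], [], {}
    zones_by_cell = {}
    for cell in cells:
        cell_rows.append(
            {"field_id": field_id, "cell_id": cell.cell_id, "area_px2": cell.area}
        )
        norm = {
            ch: segment.normalize_channel(stack.channels[ch], cell)
            for ch in ("dapi", "red", "green")
            if ch in stack.channels
        }
        zones = segment.nucleoid_zones(norm["dapi"], cell, l_dense, l_diffuse)
        zones_by_cell[cell.cell_id] = zones

        detected = {}
        for ch in ("red", "green"):
            if ch not in norm:
                continue
            detected[ch] = spots.detect_foci(norm[ch], cell, det, channel=ch)

        red = detected.get("red", [])
        green = detected.get("green", [])
        pairs = coloc.pair_mrna_plasmid(
            red, green, cfg_analyze.get("d_coloc", 2.0), cfg_analyze.get("d_adj", 8.0)
        )
        for f, p in zip(red, pairs):
            zone = _zone_of(f, zones, cfg_analyze)
            foci_rows.append(
                {
                    "field_id": field_id,
                    "cell_id": cell.cell_id,
                    "channel": "red",
                    "x": f.x,
                    "y": f.y,
                    "peak": f.peak,
                    "integrated": f.integrated,
                    "zone": zone.value,
                    "pair_label": p.label.value,
                    "pair_distance": p.distance,
                }
            )
        for f in green:
            foci_rows.append(
                {
                    "field_id": field_id,
                    "cell_id": cell.cell_id,
                    "channel": "green",
                    "x": f.x,
                    "y": f.y,
                    "peak": f.peak,
                    "integrated": f.integrated,
                    "zone": None,
                    "pair_label": None,
                    "pair_distance": None,
                }
            )
        if "red" in norm:
            d = spots.dispersion_index(
                norm["red"],
                cell,
                red,
                disc_radius=disp_cfg.get("disc_radius", 4.0),
                t_focal=disp_cfg.get("t_focal", 0.5),
                raw_raster=stack.channels["red"],
                raw_background=red_bg,
                channel="red",
            )
            disp_rows[cell.cell_id] = {
                "field_id": field_id,
                "cell_id": cell.cell_id,
                "channel": "red",
                "focal_fraction": d.focal_fraction,
                "pattern": d.pattern.value,
            }

    cols = [
        "field_id", "cell_id", "channel", "x", "y", "peak",
        "integrated", "zone", "pair_label", "pair_distance",
    ]
    return FieldResult(
        field_id=field_id,
        foci=pd.DataFrame(foci_rows, columns=cols),
        cells=pd.DataFrame(cell_rows, columns=["field_id", "cell_id", "area_px2"]),
        dispersion=pd.DataFrame(
            list(disp_rows.values()),
            columns=["field_id", "cell_id", "channel", "focal_fraction", "pattern"],
        ),
        zones=zones_by_cell,
    )


def _zone_of(focus, zones, cfg_analyze):
    if cfg_analyze.get("peripheral_mode", "contour") == "band":
        return _zone_band(focus, zones, cfg_analyze.get("band_width_px", 2.0))
    return coloc.classify_focus_zone(focus, zones)


def _zone_band(focus, zones, band_width):
    """Alternative peripheral definition: fixed-width ring around the dense contour."""
    from shapely.geometry import Point

    pt = Point(focus.x, focus.y)
    dense = zones.dense_union()
    if dense is None:
        return coloc.classify_focus_zone(focus, zones)
    if dense.covers(pt):
        return coloc.ZoneCategory.NUCLEOID_OVERLAP
    if dense.distance(pt) <= band_width:
        return coloc.ZoneCategory.PERIPHERAL
    return coloc.ZoneCategory.NUCLEOID_FREE


def run_pipeline(config, outdir) -> Path:
    """Execute the configured pipeline and write tables + manifest to ``outdir``.

    Simulation mode (default) generates ``simulate.n_fields`` fields for the
    configured condition; analysis-only mode (config keys ``input`` and
    optionally ``mask`` pointing at TIFF files) skips generation.  Outputs:
    foci.csv (the per-focus record table), cells.csv, dispersion.csv,
    summary.csv (long format) and manifest.json.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    cond = Condition.from_dict(cfg["condition"])

    results = []
    if "input" in cfg:
        stack = simulate.read_field(cfg["input"])
        labels = None
        if cfg.get("mask"):
            import tifffile

            labels = tifffile.imread(cfg["mask"]).astype(np.int32)
        results.append(analyze_field(stack, cfg["analyze"], 0, labels))
    else:
        sim_kwargs = {k: v for k, v in cfg["simulate"].items() if k != "n_fields"}
        params = _sim_params(sim_kwargs)
        n_fields = int(cfg["simulate"].get("n_fields", 1))
        for i, (stack, truth) in enumerate(
            simulate.generate_fields(params, cond, seed, n_fields)
        ):
            results.append(analyze_field(stack, cfg["analyze"], i, truth.labels))

    foci = pd.concat([r.foci for r in results], ignore_index=True)
    cells = pd.concat([r.cells for r in results], ignore_index=True)
    disp = pd.concat([r.dispersion for r in results], ignore_index=True)
    # unique cell key across fields
    for df in (foci, cells, disp):
        if len(df):
            df["cell_uid"] = df["field_id"].astype(int) * 100000 + df["cell_id"].astype(int)

    foci.to_csv(outdir / "foci.csv", index=False)
    cells.to_csv(outdir / "cells.csv", index=False)
    disp.to_csv(outdir / "dispersion.csv", index=False)

    stats = report.summarize(
        foci.rename(columns={"cell_uid": "cell_id", "cell_id": "cell_local"})
        if len(foci)
        else foci,
        cells=cells.rename(columns={"cell_uid": "cell_id", "cell_id": "cell_local"})
        if len(cells)
        else None,
        dispersion=disp.rename(columns={"cell_uid": "cell_id", "cell_id": "cell_local"})
        if len(disp)
        else None,
        n_boot=int(cfg["report"].get("n_boot", 1000)),
        seed=seed,
        denominator=cfg["report"].get("denominator", "all_cells"),
    )
    report.summary_table(stats).to_csv(outdir / "summary.csv", index=False)

    manifest = {
        "seed": seed,
        "condition": cond.to_dict(),
        "config": _jsonable(cfg),
        "n_fields": len(results),
        "n_cells": int(len(cells)),
        "n_foci": int(len(foci)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
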