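"""End-to-end orchestration: fixtures -> composites -> labels -> model ->
boundaries -> assessment, with deterministic per-stage seeding and a
hashed artifact manifest.

A single global seed is expanded into per-stage seeds through
``numpy.random.SeedSequence(global_seed).spawn`` order (fixtures,
compositing, labelling, learning, segmentation, assessment), so any stage
re-run with its own seed reproduces its slice of the full run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import date as _date, timedelta
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import assessment as assess_mod
from . import boundaries, labeling, learning, synthetic
from .compositing import SeasonWindow, composite_tile, expected_composite_count
from .grids import CellRef, GridSpec, primary_cells_of
from .raster_io import write_raster

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "ConfigError"]

REQUIRED_BLOCKS = (
    "grid",
    "seasons",
    "fixtures",
    "labeling",
    "learning",
    "segmentation",
    "assessment",
)

STAGES = (
    "fixtures",
    "compositing",
    "labeling",
    "learning",
    "segmentation",
    "assessment",
)


class ConfigError(ValueError):
    """The pipeline configuration is missing or malformed."""


@dataclass
class PipelineConfig:
    raw: dict[str, Any]
    seed: int

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]


def load_config(source) -> PipelineConfig:
    """Load and validate a YAML config (path, file object or dict)."""
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text)
    missing = [b for b in REQUIRED_BLOCKS if b not in raw]
    if missing:
        raise ConfigError(f"config missing required blocks: {missing}")
    return PipelineConfig(raw=raw, seed=int(raw.get("seed", 0)))


def stage_seeds(global_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(STAGES, children)
    }


def _season_windows(cfg: PipelineConfig) -> dict[str, SeasonWindow]:
    out = {}
    for label, block in cfg["seasons"].items():
        start, end = block["start"], block["end"]
        if isinstance(start, str):
            start = _date.fromisoformat(start)
        if isinstance(end, str):
            end = _date.fromisoformat(end)
        out[label] = SeasonWindow(label, start, end)
    return out


def _season_dates(window: SeasonWindow, n: int) -> list[_date]:
    span = (window.end - window.start).days
    return [window.start + timedelta(days=round(i * span / max(n - 1, 1)))
            for i in range(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Run every stage on a synthetic domain and write all artifacts.

    Returns the manifest (also written as ``manifest.json``): per-stage
    seeds, artifact hashes and the headline numbers of each stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    global_seed = config.seed if seed is None else int(seed)
    seeds = stage_seeds(global_seed)
    manifest: dict[str, Any] = {"seed": global_seed, "stage_seeds": seeds,
                                "artifacts": {}, "summary": {}}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    # ---- grid & fixtures ---------------------------------------------------
    g = config["grid"]
    grid = GridSpec(
        pixel_size=float(g.get("pixel_size", 0.000025)),
        n_tiles_x=int(g.get("n_tiles_x", 1)),
        n_tiles_y=int(g.get("n_tiles_y", 1)),
    )
    n_tx, n_ty = grid.n_tiles_x, grid.n_tiles_y
    bounds = grid.domain_bounds()
    px_per_deg = round(1.0 / grid.pixel_size)
    W = round((bounds[2] - bounds[0]) * px_per_deg)
    H = round((bounds[3] - bounds[1]) * px_per_deg)

    fx = config["fixtures"]
    lp = synthetic.LandscapeParams(**fx.get("landscape", {}))
    landscape = synthetic.make_landscape(seeds["fixtures"], bounds, lp,
                                         tile_size=grid.tile_size)
    windows = _season_windows(config)
    n_dates = int(fx.get("n_dates_per_season", 6))
    dates = sorted(
        d for wname in windows for d in _season_dates(windows[wname], n_dates)
    )
    atmos = synthetic.AtmosphereParams(
        cloud_fraction=float(fx.get("cloud_fraction", 0.3)),
        shadow_fraction=float(fx.get("shadow_fraction", 0.1)),
        noise_sigma=float(fx.get("noise_sigma", 0.01)),
    )
    stack = synthetic.render_time_series(
        landscape, dates, atmos, bounds, (H, W), seeds["fixtures"] + 1
    )
    cover, _ = synthetic.rasterize_cover(landscape, bounds, (H, W))
    truth = cover == synthetic.COVERS.index("cropland")
    truth_path = write_raster(out / "truth_cover.tif", cover, bounds)
    record("truth_cover", truth_path)

    # ---- compositing -------------------------------------------------------
    composites = {}
    for label, window in windows.items():
        comp = composite_tile(stack.dates, stack.data, window)
        composites[label] = comp
        path = write_raster(
            out / f"composite_{label}.tif", comp.data, bounds,
            band_names=("blue", "green", "red", "nir"),
        )
        record(f"composite_{label}", path)
    manifest["summary"]["composites"] = expected_composite_count(
        n_tx * n_ty, len(windows)
    )

    # ---- labelling ---------------------------------------------------------
    lb = config["labeling"]
    skills = [float(s) for s in lb.get("skills", (1.0, 0.7, 0.6, 0.5))]
    specs = [
        synthetic.LabellerSpec.from_skill(s, seed=seeds["labeling"] + i)
        for i, s in enumerate(skills)
    ]
    rng = np.random.default_rng(seeds["labeling"])
    cells: list[CellRef] = []
    for tr in range(n_ty):
        for tc in range(n_tx):
            cells.extend(primary_cells_of(CellRef("tile", tc, tr), grid))
    cells = sorted(set(cells), key=lambda c: (c.row, c.col))
    order = list(rng.permutation(len(cells)))
    ln = config["learning"]
    n_val = int(ln.get("validation_cells", 50))
    n_start = int(ln.get("starter_cells", 40))
    val_cells = [cells[i] for i in order[:n_val]]
    starter = [cells[i] for i in order[n_val : n_val + n_start]]
    pool = [cells[i] for i in order[n_val + n_start :]]

    # QA: score each labeller against the expert reference on a few cells
    ref_spec = synthetic.LabellerSpec(skill=1.0, seed=seeds["labeling"] + 999)
    qa_cells = [cells[i] for i in order[-int(lb.get("qa_cells", 4)):]]
    beta = tuple(lb.get("beta", labeling.DEFAULT_BETA))
    profiles: dict[str, labeling.LabellerProfile] = {}
    truth_polys = landscape.cropland_polygons
    for i, sp in enumerate(specs):
        prof = labeling.LabellerProfile(f"labeller_{i}")
        for qc in qa_cells:
            cand = labeling.Annotation(
                prof.labeller_id, qc,
                synthetic.simulate_labeller(truth_polys, sp, qc, grid),
            )
            ref = labeling.Annotation(
                "expert", qc,
                synthetic.simulate_labeller(truth_polys, ref_spec, qc, grid),
            )
            s = labeling.score_assignment(cand, ref, grid, beta)
            prof.add_score("aoi", s.score)
        profiles[prof.labeller_id] = prof
    weights = [
        labeling.labeller_weight(profiles[f"labeller_{i}"], "aoi")
        for i in range(len(specs))
    ]
    manifest["summary"]["labeller_weights"] = weights
    scores_path = out / "labeller_scores.csv"
    pd.DataFrame(
        [
            {"labeller_id": pid, "aoi": aoi, "assignment": k, "score": s}
            for pid, prof in profiles.items()
            for aoi, scores in prof.history.items()
            for k, s in enumerate(scores)
        ]
    ).to_csv(scores_path, index=False)
    record("labeller_scores", scores_path)

    n_cell_px = round(grid.primary_size / grid.pixel_size)
    cell_windows = {}
    for c in cells:
        top = H - (c.row + 1) * n_cell_px
        left = c.col * n_cell_px
        cell_windows[c] = (
            slice(top, top + n_cell_px),
            slice(left, left + n_cell_px),
        )

    label_raster = np.zeros((H, W), dtype=bool)
    risk_by_cell: dict[str, float] = {}
    labelled_cells: set[CellRef] = set()

    def consensus_provider(cell: CellRef) -> np.ndarray:
        if cell not in labelled_cells:
            masks = [
                labeling.rasterize_annotation(
                    synthetic.simulate_labeller(truth_polys, sp, cell, grid),
                    cell, grid,
                )
                for sp in specs
            ]
            cl = labeling.merge_consensus(masks, weights, cell=cell)
            label_raster[cell_windows[cell]] = cl.classes
            risk_by_cell[cell.cell_id] = cl.risk
            labelled_cells.add(cell)
        return label_raster

    # ---- learning ----------------------------------------------------------
    features = learning.extract_features(
        composites["growing"].data, composites["dry"].data
    )
    al_cfg = learning.ActiveLearningConfig(
        starter_cells=n_start,
        cells_per_iteration=int(ln.get("cells_per_iteration", 20)),
        max_iterations=int(ln.get("max_iterations", 3)),
        pixels_per_cell=int(ln.get("pixels_per_cell", 40)),
        f1_gain_tol=float(ln.get("f1_gain_tol", 0.005)),
    )
    logs, p_map, model = learning.run_active_loop(
        features,
        cell_windows,
        consensus_provider,
        starter,
        pool,
        val_cells,
        lambda c: truth,
        al_cfg,
        seed=seeds["learning"],
        selection="active",
    )
    p_path = write_raster(out / "cropland_probability.tif", p_map, bounds)
    record("cropland_probability", p_path)
    cl_path = write_raster(
        out / "consensus_labels.tif", label_raster.astype(np.uint8), bounds
    )
    record("consensus_labels", cl_path)
    risk_path = out / "consensus_risk.csv"
    pd.DataFrame(
        sorted(risk_by_cell.items()), columns=["cell_id", "bayes_risk"]
    ).to_csv(risk_path, index=False)
    record("consensus_risk", risk_path)
    log_df = pd.DataFrame(
        [
            {"iteration": l.iteration, "n_training_cells": l.n_training_cells,
             **l.metrics}
            for l in logs
        ]
    )
    log_path = out / "iteration_log.csv"
    log_df.to_csv(log_path, index=False)
    record("iteration_log", log_path)
    manifest["summary"]["final_metrics"] = logs[-1].metrics
    manifest["summary"]["mean_bayes_risk"] = (
        float(np.mean(list(risk_by_cell.values()))) if risk_by_cell else None
    )

    # ---- segmentation ------------------------------------------------------
    sg = config["segmentation"]
    params = boundaries.SegmentationParams(
        n_segments=int(sg.get("n_segments", 6400)),
        merge_threshold=float(sg.get("merge_threshold", 0.05)),
        compactness=float(sg.get("compactness", 0.01)),
    )
    tile_px = round(grid.tile_size / grid.pixel_size)
    per_tile = []
    for tr in range(n_ty):
        for tc in range(n_tx):
            top = H - (tr + 1) * tile_px
            left = tc * tile_px
            rows = slice(top, top + tile_px)
            colsl = slice(left, left + tile_px)
            tb = CellRef("tile", tc, tr).bounds(grid)
            fields, _ = boundaries.delineate_tile(
                composites["dry"].data[:, rows, colsl],
                p_map[rows, colsl],
                tb,
                grid.pixel_size,
                tile_id=f"tile_{tc}_{tr}",
                params=params,
            )
            per_tile.append(fields)
    fields = boundaries.merge_tile_seams(per_tile, grid.pixel_size)
    gj_path = out / "field_boundaries.geojson"
    gj_path.write_text(json.dumps(fields.to_geojson()))
    record("field_boundaries", gj_path)
    summaries = boundaries.summarize_fields(fields, grid, level="tile")
    manifest["summary"]["n_fields"] = len(fields)
    manifest["summary"]["total_field_area_ha"] = fields.total_area_ha()

    # ---- assessment --------------------------------------------------------
    am = config["assessment"]
    a_seed = seeds["assessment"]
    a_rng = np.random.default_rng(a_seed)
    map_class = np.where(np.nan_to_num(p_map, nan=0.0) > 0.5, "crop", "noncrop")
    n_pts = int(am.get("n_reference_points", 400))
    flat_map = map_class.ravel()
    flat_truth = np.where(truth.ravel(), "crop", "noncrop")
    w_crop = float((flat_map == "crop").mean())
    strata_weights = {"crop": w_crop, "noncrop": 1.0 - w_crop}
    recs = []
    for cls in ("crop", "noncrop"):
        idx = np.flatnonzero(flat_map == cls)
        if idx.size == 0:
            continue
        take = a_rng.choice(idx, size=min(n_pts // 2, idx.size), replace=False)
        for t in take:
            recs.append({"map_class": cls, "ref_class": flat_truth[t]})
    pts = pd.DataFrame(recs)
    area_km2 = (
        (bounds[2] - bounds[0]) * (bounds[3] - bounds[1])
        * (boundaries.M_PER_DEG / 1000) ** 2
        * np.cos(np.radians((bounds[1] + bounds[3]) / 2))
    )
    matrix = assess_mod.build_area_matrix(
        pts, strata_weights, classes=("noncrop", "crop"), area_total=float(area_km2)
    )
    report = assess_mod.accuracy_metrics(matrix)
    est = assess_mod.estimate_area(matrix)

    # segmentation bias check at validation cells: digitized (true) polygons
    # vs segmented fields
    val_stats = {"dig_sizes": [], "dig_counts": [], "seg_sizes": [], "seg_counts": []}
    from shapely.geometry import box as _box

    for c in val_cells:
        cb = _box(*c.bounds(grid))
        dig = [p for p in truth_polys if p.intersects(cb)]
        seg = [f for f in fields if f.geometry.intersects(cb)]
        val_stats["dig_counts"].append(len(dig))
        val_stats["seg_counts"].append(len(seg))
        val_stats["dig_sizes"].extend(boundaries.area_ha(p) for p in dig)
        val_stats["seg_sizes"].extend(f.area_ha for f in seg)
    map_sizes = [f.area_ha for f in fields]
    bias = None
    if val_stats["seg_sizes"] and val_stats["dig_sizes"]:
        bias = assess_mod.adjust_field_stats(
            map_mean_size=float(np.mean(map_sizes)) if map_sizes else 0.0,
            map_count=float(len(fields)),
            digitized_mean_size=float(np.mean(val_stats["dig_sizes"])),
            segmented_mean_size=float(np.mean(val_stats["seg_sizes"])),
            digitized_count=float(np.mean(val_stats["dig_counts"])) or 1.0,
            segmented_count=float(np.mean(val_stats["seg_counts"])) or 1.0,
        )
    assessment_out = {
        "overall_accuracy": report.overall,
        "overall_margin": report.overall_margin,
        "users": report.users,
        "producers": report.producers,
        "adjusted_proportions": est.proportions,
        "adjusted_areas_km2": est.areas,
        "area_margins_km2": est.area_margins,
        "field_bias": (
            {
                "size_ratio": bias.size_ratio,
                "count_ratio": bias.count_ratio,
                "adjusted_mean_size_ha": bias.adjusted_mean_size,
                "adjusted_count": bias.adjusted_count,
            }
            if bias
            else None
        ),
        "per_tile_field_summary": summaries,
    }
    a_path = out / "assessment.json"
    a_path.write_text(json.dumps(assessment_out, indent=1))
    record("assessment", a_path)
    manifest["summary"]["assessment"] = {
        "overall_accuracy": report.overall,
        "adjusted_crop_proportion": est.proportions["crop"],
    }

    m_path = out / "manifest.json"
    m_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
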