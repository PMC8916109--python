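"""Shared fixtures: demo grids, a reference landscape, and the heavier
simulation experiments (computed once per session and reused by both the
module property tests and the acceptance suite)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from fieldmapper import boundaries as bd
from fieldmapper import learning as ln
from fieldmapper import synthetic as syn
from fieldmapper.grids import GridSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_grid() -> GridSpec:
    """Coarse-pixel demo grid: 20x20-px primary cells, 200x200-px tiles."""
    return GridSpec(pixel_size=0.00025, n_tiles_x=1, n_tiles_y=1)


@pytest.fixture(scope="session")
def landscape(demo_grid):
    return syn.make_landscape(
        11, (0.0, 0.0, 0.05, 0.05), syn.LandscapeParams(), tile_size=0.05
    )


@pytest.fixture(scope="session")
def area_coverage():
    """95% CI coverage of the adjusted-area estimator over 100 synthetic
    map + stratified-sample replicates (returns the covered count)."""
    import pandas as pd

    from fieldmapper.assessment import build_area_matrix, estimate_area

    covered = 0
    n_rep, n_pts, N = 100, 500, 200 * 200
    for rep in range(n_rep):
        rng = np.random.default_rng(rep)
        true_frac = rng.uniform(0.15, 0.4)
        truth = rng.random(N) < true_frac
        mapped = truth.copy()
        mapped[truth & (rng.random(N) < 0.25)] = False  # omission
        mapped[~truth & (rng.random(N) < 0.07)] = True  # commission
        flat_map = np.where(mapped, "crop", "noncrop")
        flat_ref = np.where(truth, "crop", "noncrop")
        recs = []
        for cls in ("crop", "noncrop"):
            idx = np.flatnonzero(flat_map == cls)
            take = rng.choice(idx, size=min(n_pts // 2, idx.size), replace=False)
            recs += [{"map_class": cls, "ref_class": flat_ref[t]} for t in take]
        w_crop = float(mapped.mean())
        m = build_area_matrix(
            pd.DataFrame(recs), {"crop": w_crop, "noncrop": 1 - w_crop},
            classes=("noncrop", "crop"),
        )
        est = estimate_area(m)
        lo = est.proportions["crop"] - est.proportion_margins["crop"]
        hi = est.proportions["crop"] + est.proportion_margins["crop"]
        covered += lo <= truth.mean() <= hi
    return covered


@pytest.fixture(scope="session")
def selection_experiment():
    """Active vs random site selection, 10 seeds (shared, ~2 min)."""
    cfg = ln.ExperimentConfig(n_seeds=10)
    return ln.run_selection_experiment(cfg, base_seed=0)


@pytest.fixture(scope="session")
def label_quality_experiment():
    """Consensus vs best vs worst labeller training sets, 10 seeds."""
    cfg = ln.ExperimentConfig(n_seeds=10)
    return ln.run_label_quality_experiment(cfg, base_seed=0)


@pytest.fixture(scope="session")
def segmentation_recovery():
    """Field recovery on 5 synthetic worlds with a well-trained classifier.

    Returns per-seed dicts with raster IoU of recovered vs true cropland
    and the recovered/true field-count ratio.
    """
    out = []
    for seed in range(5):
        world = ln.make_demo_world(seed, n_tiles=(1, 1))
        rng = np.random.default_rng(seed)
        cells = list(world.cells)
        rng.shuffle(cells)
        X, y = [], []
        for c in cells[:60]:
            r, cc = ln._cell_pixels(world.windows[c], 100, rng)
            X.append(world.features[:, r, cc].T)
            y.append(world.truth[r, cc])
        Xb, yb = ln.assemble_training(np.concatenate(X), np.concatenate(y), 0)
        model = ln.fit_classifier(Xb, yb, seed=0)
        p = ln.predict_probabilities(model, world.features)
        fields, merged = bd.delineate_tile(
            world.composites["dry"], p, world.bounds, world.grid.pixel_size,
            "tile", bd.SegmentationParams(n_segments=256),
        )
        kept = np.zeros_like(world.truth)
        for lab in np.unique(merged):
            mask = merged == lab
            if np.nanmean(p[mask]) > 0.5:
                kept |= mask
        iou = float((kept & world.truth).sum() / (kept | world.truth).sum())
        n_true = sum(1 for _, c in world.landscape.polygons if c == "cropland")
        out.append(
            {
                "seed": seed,
                "iou": iou,
                "count_ratio": len(fields) / n_true,
                "n_fields": len(fields),
                "n_true": n_true,
            }
        )
    return out
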