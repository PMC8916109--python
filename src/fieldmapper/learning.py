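"""Cropland classification with balanced random forests and active learning.

The feature stack holds 24 bands per tile: the 8 raw bands of the two
seasonal composites (growing, dry x blue, green, red, NIR), their means in
an 11x11 moving window, and their population standard deviations in a 5x5
window (reflect padding at edges).  A random forest (60 trees, depth 15)
is trained on a class-balanced pixel sample; its soft output is the
fraction of trees voting cropland.

Active learning ranks unlabelled primary cells by the certainty statistic

    Q = sum over a sampled pixel subset of (p - 0.5)^2

(low Q = uncertain cell) and draws the next labelling batch at random from
the most uncertain 30% of the ranking, to limit spatial autocorrelation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from . import synthetic
from .compositing import SeasonalComposite
from .grids import CellRef, GridSpec, primary_cells_of
from .labeling import merge_consensus, rasterize_annotation

__all__ = [
    "RFHyperParams",
    "CroplandModel",
    "IterationLog",
    "ActiveLearningConfig",
    "extract_features",
    "assemble_training",
    "fit_classifier",
    "predict_probabilities",
    "evaluate",
    "site_uncertainty",
    "select_active_sites",
    "run_active_loop",
    "run_experiments",
    "DemoWorld",
    "make_demo_world",
    "ExperimentConfig",
]

N_FEATURES = 24
MEAN_WINDOW = 11
STD_WINDOW = 5


def _as_bands(composite) -> np.ndarray:
    data = composite.data if isinstance(composite, SeasonalComposite) else composite
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or data.shape[0] != 4:
        raise ValueError("composite must have shape (4, H, W)")
    return data


def extract_features(growing, dry) -> np.ndarray:
    """24-band feature stack from a co-registered seasonal composite pair.

    Band order: 8 raw (growing B,G,R,NIR then dry B,G,R,NIR), 8 moving
    means (11x11), 8 moving population standard deviations (5x5), each in
    raw-band order.  Purely deterministic.
    """
    g = _as_bands(growing)
    d = _as_bands(dry)
    if g.shape != d.shape:
        raise ValueError("seasonal composites are not co-registered")
    raw = np.concatenate([g, d], axis=0)  # (8, H, W)
    means = np.stack(
        [ndimage.uniform_filter(b, size=MEAN_WINDOW, mode="reflect") for b in raw]
    )
    m1 = np.stack(
        [ndimage.uniform_filter(b, size=STD_WINDOW, mode="reflect") for b in raw]
    )
    m2 = np.stack(
        [ndimage.uniform_filter(b * b, size=STD_WINDOW, mode="reflect") for b in raw]
    )
    stds = np.sqrt(np.clip(m2 - m1 * m1, 0.0, None))
    return np.concatenate([raw, means, stds], axis=0)


def assemble_training(
    features: np.ndarray, labels: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Downsample the majority class to the minority count (seeded)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(bool)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, k) aligned with labels")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    if n_pos == n_neg:
        return X, y
    maj = y if n_pos > n_neg else ~y
    k = min(n_pos, n_neg)
    maj_idx = np.flatnonzero(maj)
    keep = rng.choice(maj_idx, size=k, replace=False)
    idx = np.sort(np.concatenate([np.flatnonzero(~maj), keep]))
    return X[idx], y[idx]


@dataclass(frozen=True)
class RFHyperParams:
    n_trees: int = 60
    max_depth: int = 15


@dataclass
class CroplandModel:
    """A trained forest plus the state needed to reproduce it exactly."""

    forest: RandomForestClassifier
    hyper: RFHyperParams
    seed: int
    n_training: int


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    hyper: RFHyperParams = RFHyperParams(),
    seed: int = 0,
) -> CroplandModel:
    """Fit the random forest; identical data + seed reproduce predictions."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(bool)
    if len(X) == 0 or len(np.unique(y)) < 2:
        raise ValueError("training sample must be non-empty with both classes")
    forest = RandomForestClassifier(
        n_estimators=hyper.n_trees,
        max_depth=hyper.max_depth,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return CroplandModel(forest=forest, hyper=hyper, seed=seed, n_training=len(X))


def predict_probabilities(
    model: CroplandModel,
    features: np.ndarray,
    nodata_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Fraction-of-trees cropland vote per pixel (multiples of 1/n_trees).

    ``features`` may be a flat (n, 24) table or a (24, H, W) stack; the
    output matches (a flat vector or an (H, W) map).  Nodata pixels
    propagate as NaN.
    """
    X = np.asarray(features, dtype=float)
    map_shape = None
    if X.ndim == 3:
        if X.shape[0] != model.forest.n_features_in_:
            raise ValueError("feature band count does not match training")
        map_shape = X.shape[1:]
        X = X.reshape(X.shape[0], -1).T
    elif X.ndim != 2 or X.shape[1] != model.forest.n_features_in_:
        raise ValueError("feature count does not match training")
    valid = np.ones(len(X), dtype=bool)
    if nodata_mask is not None:
        valid = ~np.asarray(nodata_mask, dtype=bool).ravel()
    valid &= np.isfinite(X).all(axis=1)
    p = np.full(len(X), np.nan)
    if valid.any():
        votes = np.zeros(int(valid.sum()))
        Xv = X[valid]
        pos = list(model.forest.classes_).index(True)
        for tree in model.forest.estimators_:
            votes += tree.predict(Xv) == model.forest.classes_[pos]
        p[valid] = votes / len(model.forest.estimators_)
    return p.reshape(map_shape) if map_shape else p


def evaluate(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Binary accuracy, AUC, F1 (harmonic precision/recall mean), and FPR."""
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels).astype(bool).ravel()
    ok = np.isfinite(p)
    p, y = p[ok], y[ok]
    if len(y) == 0 or len(np.unique(y)) < 2:
        raise ValueError("validation set must be non-empty with both classes")
    pred = p > threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {
        "accuracy": (tp + tn) / len(y),
        "auc": float(roc_auc_score(y, p)),
        "f1": f1,
        "fpr": fp / (fp + tn) if fp + tn else 0.0,
    }


def site_uncertainty(
    probabilities: np.ndarray, n_sample: int = 1000, seed: int = 0
) -> float:
    """Certainty statistic Q over a seeded random pixel subset of a cell.

    Q = sum (p - 0.5)^2; bounded by 0 <= Q <= 0.25 * n; *low* Q marks the
    cells the classifier finds hardest.
    """
    p = np.asarray(probabilities, dtype=float).ravel()
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("cell has no valid predictions")
    if n_sample < p.size:
        rng = np.random.default_rng(seed)
        p = rng.choice(p, size=n_sample, replace=False)
    return float(np.sum((p - 0.5) ** 2))


def select_active_sites(
    scores: Sequence[tuple[object, float]],
    k: int,
    seed: int = 0,
    top_fraction: float = 0.3,
) -> list[object]:
    """Draw k cells at random from the most-uncertain (lowest-Q) fraction."""
    if not scores:
        raise ValueError("empty candidate pool")
    ranked = sorted(scores, key=lambda t: t[1])
    pool_n = math.ceil(top_fraction * len(ranked))
    pool = [c for c, _ in ranked[:pool_n]]
    rng = np.random.default_rng(seed)
    if k >= len(pool):
        rng.shuffle(pool)
        return pool
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


@dataclass
class IterationLog:
    iteration: int
    n_training_cells: int
    metrics: dict[str, float]
    selected: list = dc_field(default_factory=list)


@dataclass(frozen=True)
class ActiveLearningConfig:
    """Knobs of the retrain-select-label loop.

    ``starter_cells`` and ``cells_per_iteration`` default to the production
    settings (500 starter labels per cluster, 100 new cells per iteration);
    demo-scale runs pass smaller values.
    """

    starter_cells: int = 500
    cells_per_iteration: int = 100
    max_iterations: int = 3
    f1_gain_tol: float = 0.005
    pixels_per_cell: int = 50
    n_sample_uncertainty: int = 1000
    top_fraction: float = 0.3
    hyper: RFHyperParams = RFHyperParams()
    threshold: float = 0.5


def _cell_pixels(window, pixels_per_cell, rng) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = window
    rr = np.arange(rows.start, rows.stop)
    cc = np.arange(cols.start, cols.stop)
    rg, cg = np.meshgrid(rr, cc, indexing="ij")
    flat_r, flat_c = rg.ravel(), cg.ravel()
    if pixels_per_cell and pixels_per_cell < flat_r.size:
        idx = rng.choice(flat_r.size, size=pixels_per_cell, replace=False)
        return flat_r[idx], flat_c[idx]
    return flat_r, flat_c


def run_active_loop(
    features: np.ndarray,
    cell_windows: Mapping[object, tuple[slice, slice]],
    label_provider: Callable[[object], np.ndarray],
    initial_cells: Sequence[object],
    pool_cells: Sequence[object],
    validation_cells: Sequence[object],
    validation_provider: Callable[[object], np.ndarray],
    config: ActiveLearningConfig = ActiveLearningConfig(),
    seed: int = 0,
    selection: str = "active",
) -> tuple[list[IterationLog], np.ndarray, CroplandModel]:
    """Iterative train -> evaluate -> rank uncertainty -> label loop.

    ``features`` is the (24, H, W) stack of the whole working area;
    ``cell_windows`` maps cell keys to (row slice, col slice) windows;
    ``label_provider`` returns a cell's training mask (e.g. a consensus
    label) and ``validation_provider`` the validation mask.  ``selection``
    is "active" (lowest-Q 30% pool) or "random" (the control arm).
    Stops after ``max_iterations`` extra batches, on pool exhaustion, or
    when the validation F1 gain drops below ``f1_gain_tol``.
    """
    rng = np.random.default_rng(seed)
    labelled = list(initial_cells)
    pool = [c for c in pool_cells if c not in set(labelled)]

    # providers return full-working-area rasters, indexed like ``features``
    val_X, val_y = [], []
    for c in validation_cells:
        r, cc = _cell_pixels(cell_windows[c], config.pixels_per_cell, rng)
        val_X.append(features[:, r, cc].T)
        val_y.append(validation_provider(c)[r, cc])
    val_X = np.concatenate(val_X)
    val_y = np.concatenate(val_y)

    logs: list[IterationLog] = []
    model = None
    p_map = None
    prev_f1 = None
    for it in range(config.max_iterations + 1):
        train_X, train_y = [], []
        for c in labelled:
            r, cc = _cell_pixels(
                cell_windows[c], config.pixels_per_cell,
                np.random.default_rng((seed, hash(str(c)) % (2**31), 3)),
            )
            train_X.append(features[:, r, cc].T)
            train_y.append(label_provider(c)[r, cc])
        Xb, yb = assemble_training(
            np.concatenate(train_X), np.concatenate(train_y), seed=seed + it
        )
        model = fit_classifier(Xb, yb, config.hyper, seed=seed)
        p_map = predict_probabilities(model, features)
        metrics = evaluate(
            predict_probabilities(model, val_X), val_y, config.threshold
        )
        log = IterationLog(it, len(labelled), metrics)
        logs.append(log)

        if it == config.max_iterations or not pool:
            break
        if prev_f1 is not None and metrics["f1"] - prev_f1 < config.f1_gain_tol:
            break
        prev_f1 = metrics["f1"]

        if selection == "active":
            scores = []
            for c in pool:
                r, cc = cell_windows[c]
                scores.append(
                    (c, site_uncertainty(p_map[r, cc],
                                         config.n_sample_uncertainty,
                                         seed=seed + it))
                )
            chosen = select_active_sites(
                scores, config.cells_per_iteration, seed=seed + it,
                top_fraction=config.top_fraction,
            )
        elif selection == "random":
            k = min(config.cells_per_iteration, len(pool))
            idx = rng.choice(len(pool), size=k, replace=False)
            chosen = [pool[i] for i in idx]
        else:
            raise ValueError(f"unknown selection mode {selection!r}")
        log.selected = list(chosen)
        labelled.extend(chosen)
        pool = [c for c in pool if c not in set(chosen)]
    return logs, p_map, model


# ---------------------------------------------------------------------------
# demo-scale simulation world
# ---------------------------------------------------------------------------

#: demo grid: same tile/primary sizes as production, 10x coarser pixels, so a
#: primary cell is 20x20 px and a tile 200x200 px — tractable for simulation
DEMO_GRID = GridSpec(pixel_size=0.00025, n_tiles_x=2, n_tiles_y=2)


@dataclass
class DemoWorld:
    """A synthetic working area with features, truth and cell windows."""

    grid: GridSpec
    landscape: synthetic.SyntheticLandscape
    features: np.ndarray  # (24, H, W)
    truth: np.ndarray  # (H, W) bool cropland
    cover: np.ndarray  # (H, W) int8 COVERS index
    cells: list[CellRef]
    windows: dict[CellRef, tuple[slice, slice]]
    bounds: tuple[float, float, float, float]
    composites: dict[str, np.ndarray]  # clean seasonal endmembers (4, H, W)

    def truth_mask(self, cell: CellRef) -> np.ndarray:
        """Full-raster view: callers index it with the cell window."""
        return self.truth


def make_demo_world(
    seed: int,
    n_tiles: tuple[int, int] = (2, 2),
    landscape_params: synthetic.LandscapeParams = synthetic.LandscapeParams(),
    noise_sigma: float = 0.02,
    grid: GridSpec | None = None,
) -> DemoWorld:
    """Build a small fully-truthed world for simulation experiments.

    The clean seasonal endmember composites (plus sensor-level Gaussian
    noise) stand in for the compositing stage, whose fidelity is tested
    separately against its own oracle.
    """
    if grid is None:
        grid = GridSpec(
            pixel_size=0.00025, n_tiles_x=n_tiles[0], n_tiles_y=n_tiles[1]
        )
    rng = np.random.default_rng(seed)
    lon1 = grid.origin_lon + n_tiles[0] * grid.tile_size
    lat1 = grid.origin_lat + n_tiles[1] * grid.tile_size
    bounds = (grid.origin_lon, grid.origin_lat, lon1, lat1)
    landscape = synthetic.make_landscape(seed, bounds, landscape_params,
                                         tile_size=grid.tile_size)
    px_per_deg = round(1.0 / grid.pixel_size)
    W = round((lon1 - bounds[0]) * px_per_deg)
    H = round((lat1 - bounds[1]) * px_per_deg)
    comps = synthetic.truth_composites(landscape, bounds, (H, W))
    growing = comps["growing"] + rng.normal(0, noise_sigma, comps["growing"].shape)
    dry = comps["dry"] + rng.normal(0, noise_sigma, comps["dry"].shape)
    features = extract_features(growing, dry)
    cover, _ = synthetic.rasterize_cover(landscape, bounds, (H, W))
    truth = cover == synthetic.COVERS.index("cropland")

    cells: list[CellRef] = []
    for tr in range(n_tiles[1]):
        for tc in range(n_tiles[0]):
            cells.extend(primary_cells_of(CellRef("tile", tc, tr), grid))
    cells = sorted(set(cells), key=lambda c: (c.row, c.col))
    n_px = round(grid.primary_size / grid.pixel_size)
    windows = {}
    for c in cells:
        # row 0 of the raster is the northern edge
        top = H - (c.row + 1) * n_px
        left = c.col * n_px
        windows[c] = (slice(top, top + n_px), slice(left, left + n_px))
    return DemoWorld(
        grid=grid,
        landscape=landscape,
        features=features,
        truth=truth,
        cover=cover,
        cells=cells,
        windows=windows,
        bounds=bounds,
        composites=comps,
    )


def _labeller_masks(
    world: DemoWorld, cell: CellRef, specs: Sequence[synthetic.LabellerSpec]
) -> list[np.ndarray]:
    """Each simulated labeller's rasterized annotation of one cell."""
    truth_polys = world.landscape.cropland_polygons
    masks = []
    for sp in specs:
        annots = synthetic.simulate_labeller(truth_polys, sp, cell, world.grid)
        masks.append(rasterize_annotation(annots, cell, world.grid))
    return masks


@dataclass(frozen=True)
class ExperimentConfig:
    """Controlled-comparison settings (active vs random; label quality)."""

    n_seeds: int = 10
    n_tiles: tuple[int, int] = (2, 2)
    skills: tuple[float, ...] = (1.0, 0.7, 0.6, 0.5)
    starter_cells: int = 16
    cells_per_iteration: int = 16
    max_iterations: int = 3
    validation_cells: int = 60
    pixels_per_cell: int = 40
    training_cells_quality: int = 60
    landscape_params: synthetic.LandscapeParams = synthetic.LandscapeParams()


def _split_cells(world: DemoWorld, cfg: ExperimentConfig, rng):
    cells = list(world.cells)
    rng.shuffle(cells)
    val = cells[: cfg.validation_cells]
    rest = cells[cfg.validation_cells:]
    return val, rest


def run_label_quality_experiment(
    config: ExperimentConfig = ExperimentConfig(), base_seed: int = 0
) -> dict:
    """Consensus vs best-labeller vs worst-labeller training sets.

    For each seed, one set of training cells is labelled by all simulated
    labellers; three models are trained — on the worst labeller's masks, the
    best labeller's masks, and the weighted consensus — and evaluated
    against the ground truth.  Returns per-variant mean metrics.
    """
    variants = ("worst", "best", "consensus")
    results: dict[str, list[dict[str, float]]] = {v: [] for v in variants}
    for s in range(config.n_seeds):
        seed = base_seed + s
        world = make_demo_world(seed, config.n_tiles, config.landscape_params)
        rng = np.random.default_rng(seed)
        val_cells, rest = _split_cells(world, config, rng)
        train_cells = rest[: config.training_cells_quality]
        specs = [
            synthetic.LabellerSpec.from_skill(sk, seed=seed * 100 + i)
            for i, sk in enumerate(config.skills)
        ]
        weights = list(config.skills)  # QA-derived weights track skill
        i_best = int(np.argmax(config.skills))
        i_worst = int(np.argmin(config.skills))

        masks = {c: _labeller_masks(world, c, specs) for c in train_cells}
        providers = {
            "worst": lambda c: masks[c][i_worst],
            "best": lambda c: masks[c][i_best],
            "consensus": lambda c: merge_consensus(masks[c], weights).classes,
        }
        val_y, val_X = [], []
        for c in val_cells:
            r, cc = _cell_pixels(world.windows[c], config.pixels_per_cell, rng)
            val_X.append(world.features[:, r, cc].T)
            val_y.append(world.truth[r, cc])
        val_X = np.concatenate(val_X)
        val_y = np.concatenate(val_y)

        for v in variants:
            X, y = [], []
            for c in train_cells:
                r, cc = _cell_pixels(
                    world.windows[c], config.pixels_per_cell,
                    np.random.default_rng((seed, c.col, c.row)),
                )
                X.append(world.features[:, r, cc].T)
                win = world.windows[c]
                cell_mask = providers[v](c)
                y.append(cell_mask[r - win[0].start, cc - win[1].start])
            try:
                Xb, yb = assemble_training(
                    np.concatenate(X), np.concatenate(y), seed=seed
                )
            except ValueError:  # a variant produced one-class labels
                results[v].append({"accuracy": 0.0, "auc": 0.5, "f1": 0.0, "fpr": 1.0})
                continue
            model = fit_classifier(Xb, yb, seed=seed)
            p = predict_probabilities(model, val_X)
            results[v].append(evaluate(p, val_y))
    summary = {
        v: {k: float(np.mean([m[k] for m in ms])) for k in ms[0]}
        for v, ms in results.items()
    }
    summary["per_seed_f1"] = {
        v: [m["f1"] for m in results[v]] for v in variants
    }
    return summary


def run_selection_experiment(
    config: ExperimentConfig = ExperimentConfig(), base_seed: int = 0
) -> dict:
    """Active (uncertainty-ranked) vs random site selection, matched budgets."""
    out: dict[str, list[float]] = {"active": [], "random": []}
    starts: list[float] = []
    deltas: list[dict[str, float]] = []
    for s in range(config.n_seeds):
        seed = base_seed + s
        world = make_demo_world(seed, config.n_tiles, config.landscape_params)
        rng = np.random.default_rng(seed)
        val_cells, rest = _split_cells(world, config, rng)
        initial = rest[: config.starter_cells]
        pool = rest[config.starter_cells:]
        al_cfg = ActiveLearningConfig(
            starter_cells=config.starter_cells,
            cells_per_iteration=config.cells_per_iteration,
            max_iterations=config.max_iterations,
            f1_gain_tol=-1.0,  # run all iterations in the comparison
            pixels_per_cell=config.pixels_per_cell,
            n_sample_uncertainty=1000,
        )
        finals = {}
        for mode in ("active", "random"):
            logs, _, _ = run_active_loop(
                world.features,
                world.windows,
                lambda c: world.truth,
                initial,
                pool,
                val_cells,
                lambda c: world.truth,
                al_cfg,
                seed=seed,
                selection=mode,
            )
            out[mode].append(logs[-1].metrics["f1"])
            finals[mode] = logs[-1].metrics
            if mode == "active":
                starts.append(logs[0].metrics["f1"])
        deltas.append(
            {k: finals["active"][k] - finals["random"][k] for k in finals["active"]}
        )
    return {
        "active_f1": out["active"],
        "active_f1_start": starts,
        "random_f1": out["random"],
        "mean_active_f1": float(np.mean(out["active"])),
        "mean_random_f1": float(np.mean(out["random"])),
        "mean_delta": {
            k: float(np.mean([d[k] for d in deltas])) for k in deltas[0]
        },
    }


def run_experiments(
    config: ExperimentConfig = ExperimentConfig(), base_seed: int = 0
) -> dict:
    """Both controlled comparisons: selection strategy and label quality."""
    return {
        "selection": run_selection_experiment(config, base_seed),
        "label_quality": run_label_quality_experiment(config, base_seed),
    }
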