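"""Annotation scoring, consensus labels and task scheduling.

Each labelling *assignment* is one labeller's set of digitized field
polygons for one primary grid cell.  Assignments against expert reference
polygons are scored with a five-component quality score

    score = b0*I + b1*O + b2*F + b3*E + b4*C,   sum(b) = 1

where I is inside-the-cell (balanced) pixel accuracy, O the accuracy of
polygon area spilling outside the cell, F a fragmentation ratio, E a
boundary-matching term and C thematic-class agreement.  A labeller's
running mean score within an AOI becomes their weight; four assignments of
a training cell are fused per pixel into a consensus probability

    p(field) = sum_i w_i * y_i / sum_i w_i

with a 0.5 classification threshold (ties -> non-field), and the cell's
Bayes risk mean(1 - |2p - 1|) summarizes inter-labeller disagreement
(0 = unanimous everywhere, 1 = complete disagreement).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .grids import CellRef, GridSpec, raster_window

__all__ = [
    "DEFAULT_BETA",
    "Annotation",
    "AssignmentScore",
    "LabellerProfile",
    "ConsensusLabel",
    "Task",
    "TaskQueue",
    "QueueExhausted",
    "rasterize_annotation",
    "score_assignment",
    "labeller_weight",
    "merge_consensus",
    "bayes_risk",
]

#: default score weights (I, O, F, E, C); inside-cell agreement dominates
DEFAULT_BETA = (0.3, 0.1, 0.2, 0.2, 0.2)

FIELD_CLASS = "annual cropland"


@dataclass
class Annotation:
    """One labeller's polygons for one primary cell."""

    labeller_id: str
    cell: CellRef
    polygons: list[tuple[Polygon, str]]

    def cleaned(self) -> list[tuple[Polygon, str]]:
        out = []
        for k, (g, c) in enumerate(self.polygons):
            if not g.is_valid:
                g = shapely.make_valid(g)
            if g.is_empty:
                continue
            if g.geom_type == "MultiPolygon":
                for part in g.geoms:
                    out.append((part, c))
            elif g.geom_type == "Polygon":
                out.append((g, c))
            else:
                raise ValueError(f"polygon {k} invalid after cleaning: {g.geom_type}")
        return out


@dataclass(frozen=True)
class AssignmentScore:
    inside: float
    outside: float
    fragmentation: float
    edge: float
    categorical: float
    beta: tuple[float, ...] = DEFAULT_BETA

    @property
    def components(self) -> tuple[float, ...]:
        return (
            self.inside,
            self.outside,
            self.fragmentation,
            self.edge,
            self.categorical,
        )

    @property
    def score(self) -> float:
        return float(np.dot(self.beta, self.components))


@dataclass
class LabellerProfile:
    """Per-AOI history of assignment scores for one labeller."""

    labeller_id: str
    history: dict[str, list[float]] = field(default_factory=dict)

    def add_score(self, aoi: str, score: float) -> None:
        self.history.setdefault(aoi, []).append(score)


def labeller_weight(profile: LabellerProfile, aoi: str) -> float:
    """Mean QA score within the AOI; 0.5 prior with no history."""
    scores = profile.history.get(aoi, [])
    if not scores:
        return 0.5
    return float(np.mean(scores))


@dataclass
class ConsensusLabel:
    """Fused per-pixel field probability for one primary cell."""

    cell: CellRef | None
    probability: np.ndarray  # (H, W) in [0, 1]
    classes: np.ndarray  # (H, W) bool, True = field
    risk: float


def rasterize_annotation(
    polygons: Sequence[tuple[Polygon, str]] | Sequence[Polygon],
    cell: CellRef,
    spec: GridSpec,
) -> np.ndarray:
    """Binary mask of an annotation over the cell window (pixel-center rule).

    Row 0 is the northernmost pixel row.  Invalid geometries are cleaned
    first; a geometry that cannot be repaired raises, naming its index.
    """
    geoms: list[Polygon] = []
    for k, item in enumerate(polygons):
        g = item[0] if isinstance(item, tuple) else item
        if not g.is_valid:
            g = shapely.make_valid(g)
        if g.is_empty:
            continue
        if g.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"polygon {k} invalid after cleaning")
        geoms.append(g)
    n_cols, n_rows = raster_window(cell, spec)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    if not geoms:
        return mask
    lon0, lat0, lon1, lat1 = cell.bounds(spec)
    px = spec.pixel_size
    lons = lon0 + (np.arange(n_cols) + 0.5) * px
    lats = lat1 - (np.arange(n_rows) + 0.5) * px
    lon_g, lat_g = np.meshgrid(lons, lats)
    union = unary_union(geoms)
    inside = shapely.contains_xy(union, lon_g.ravel(), lat_g.ravel())
    return inside.reshape(n_rows, n_cols)


def _balanced_accuracy(cand: np.ndarray, ref: np.ndarray) -> float:
    """Balanced accuracy with the degenerate-class convention: a class with
    no reference pixels contributes 1 if the candidate also lacks it."""
    pos = ref.sum()
    neg = ref.size - pos
    if pos == 0:
        sens = 1.0 if cand.sum() == 0 else 0.0
    else:
        sens = float((cand & ref).sum() / pos)
    if neg == 0:
        spec_ = 1.0 if (~cand).sum() == 0 else 0.0
    else:
        spec_ = float((~cand & ~ref).sum() / neg)
    return 0.5 * (sens + spec_)


def _match_by_iou(
    cand: list[tuple[Polygon, str]], ref: list[tuple[Polygon, str]]
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching on descending polygon IoU."""
    pairs = []
    for i, (cg, _) in enumerate(cand):
        for j, (rg, _) in enumerate(ref):
            inter = cg.intersection(rg).area
            if inter <= 0:
                continue
            iou = inter / (cg.area + rg.area - inter)
            pairs.append((iou, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_c: set[int] = set()
    used_r: set[int] = set()
    out = []
    for iou, i, j in pairs:
        if i in used_c or j in used_r:
            continue
        used_c.add(i)
        used_r.add(j)
        out.append((i, j, iou))
    return out


def _boundary_iou(cg: Polygon, rg: Polygon, dilate: float) -> float:
    cb = cg.boundary.buffer(dilate)
    rb = rg.boundary.buffer(dilate)
    inter = cb.intersection(rb).area
    union = cb.union(rb).area
    return inter / union if union > 0 else 1.0


def score_assignment(
    candidate: Annotation,
    reference: Annotation,
    spec: GridSpec,
    beta: Sequence[float] = DEFAULT_BETA,
    edge_dilate_px: float = 2.0,
) -> AssignmentScore:
    """Score a candidate annotation against a reference for the same cell.

    Components (each in [0, 1]):

    * I — balanced accuracy of the rasterized candidate vs reference masks
      within the cell window;
    * O — 1 minus the fraction of candidate area outside the cell that is
      unsupported by reference area outside the cell (1 if none spills);
    * F — min/max ratio of polygon counts (1 when both are 0);
    * E — area-weighted mean, over IoU-matched polygon pairs, of the IoU of
      their boundaries dilated by ``edge_dilate_px`` pixels;
    * C — fraction of matched candidate polygons with the reference's class.
    """
    if candidate.cell != reference.cell:
        raise ValueError("candidate and reference target different cells")
    beta = tuple(float(b) for b in beta)
    if len(beta) != 5 or abs(sum(beta) - 1.0) > 1e-9:
        raise ValueError("beta must have 5 entries summing to 1")

    cand = candidate.cleaned()
    ref = reference.cleaned()
    cell = candidate.cell

    cand_mask = rasterize_annotation(cand, cell, spec)
    ref_mask = rasterize_annotation(ref, cell, spec)
    inside = _balanced_accuracy(cand_mask, ref_mask)

    cell_box = box(*cell.bounds(spec))
    cand_out = unary_union([g for g, _ in cand]).difference(cell_box) if cand else None
    if cand_out is None or cand_out.area <= 0:
        outside = 1.0
    else:
        ref_out = (
            unary_union([g for g, _ in ref]).difference(cell_box)
            if ref
            else Polygon()
        )
        unsupported = cand_out.difference(ref_out).area
        outside = 1.0 - unsupported / cand_out.area

    n_c, n_r = len(cand), len(ref)
    if n_c == 0 and n_r == 0:
        frag = 1.0
    elif min(n_c, n_r) == 0:
        frag = 0.0
    else:
        frag = min(n_c, n_r) / max(n_c, n_r)

    matches = _match_by_iou(cand, ref)
    dilate = edge_dilate_px * spec.pixel_size
    if n_c == 0 and n_r == 0:
        edge = 1.0
        cat = 1.0
    elif not matches:
        edge = 0.0
        cat = 1.0  # nothing matched to compare classes on
    else:
        weights = np.array([cand[i][0].area for i, _, _ in matches])
        bious = np.array(
            [_boundary_iou(cand[i][0], ref[j][0], dilate) for i, j, _ in matches]
        )
        edge = float(np.average(bious, weights=weights)) if weights.sum() else 0.0
        cat = float(
            np.mean([cand[i][1] == ref[j][1] for i, j, _ in matches])
        )
    clamp = lambda v: float(min(1.0, max(0.0, v)))  # shave float round-off
    return AssignmentScore(
        clamp(inside), clamp(outside), clamp(frag), clamp(edge), clamp(cat), beta
    )


def merge_consensus(
    masks: Sequence[np.ndarray],
    weights: Sequence[float],
    cell: CellRef | None = None,
) -> ConsensusLabel:
    """Fuse binary assignment masks into a consensus probability.

    ``p = sum_i w_i y_i / sum_i w_i`` per pixel; class is ``p > 0.5`` (the
    tie p = 0.5 falls to non-field, conservative toward the majority
    non-crop class).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    if w.sum() <= 0:
        raise ValueError("at least one weight must be positive")
    stack = np.stack([np.asarray(m, dtype=float) for m in masks])
    if len(stack) != len(w):
        raise ValueError("one weight per mask required")
    p = np.tensordot(w, stack, axes=(0, 0)) / w.sum()
    classes = p > 0.5
    return ConsensusLabel(cell=cell, probability=p, classes=classes, risk=bayes_risk(p))


def bayes_risk(probability: np.ndarray | "ConsensusLabel") -> float:
    """Mean per-pixel disagreement ``1 - |2p - 1|`` over the cell.

    0 iff every pixel is unanimous (p in {0, 1}); 1 iff every pixel sits at
    p = 0.5.  Invariant to relabelling field <-> non-field.
    """
    p = (
        probability.probability
        if isinstance(probability, ConsensusLabel)
        else np.asarray(probability, dtype=float)
    )
    return float(np.mean(1.0 - np.abs(2.0 * p - 1.0)))


class QueueExhausted(Exception):
    """No task remains that the labeller can be given."""


@dataclass
class Task:
    task_id: str
    kind: str  # "accuracy_assessment" | "training_validation"
    cell: CellRef
    required_assignments: int
    submissions: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return len(self.submissions) >= self.required_assignments


class TaskQueue:
    """Scheduler interleaving hidden QA tasks among mapping tasks.

    Every 6th assignment served to a labeller is an accuracy-assessment
    task (1 QA per 5 mapped); the returned payload does not reveal the task
    type field to the labeller-facing side.  Training tasks need 4 distinct
    labellers; QA tasks need 1; a labeller never receives the same training
    task twice.
    """

    def __init__(
        self,
        training_cells: Sequence[CellRef],
        qa_cells: Sequence[CellRef],
        qa_rate: float = 1 / 5,
        assignments_per_training_task: int = 4,
    ) -> None:
        if not 0 <= qa_rate <= 1:
            raise ValueError("qa_rate must be in [0, 1]")
        self.qa_rate = qa_rate
        self.training: list[Task] = [
            Task(f"train_{c.cell_id}", "training_validation", c,
                 assignments_per_training_task)
            for c in training_cells
        ]
        self.qa: deque[Task] = deque(
            Task(f"qa_{c.cell_id}", "accuracy_assessment", c, 1) for c in qa_cells
        )
        self._served: dict[str, int] = {}
        self._seen: dict[str, set[str]] = {}
        self.completed: list[Task] = []

    def _interval(self) -> int:
        # 1 QA per (1/qa_rate) mapped => QA every (1/qa_rate + 1)th serving
        return round(1.0 / self.qa_rate) + 1 if self.qa_rate > 0 else 0

    def schedule_next(self, labeller_id: str) -> Task:
        served = self._served.get(labeller_id, 0)
        interval = self._interval()
        want_qa = interval > 0 and (served + 1) % interval == 0 and self.qa
        if want_qa:
            task = self.qa.popleft()
        else:
            seen = self._seen.setdefault(labeller_id, set())
            task = next(
                (
                    t
                    for t in self.training
                    if not t.complete and t.task_id not in seen
                ),
                None,
            )
            if task is None:
                if self.qa:
                    task = self.qa.popleft()
                else:
                    raise QueueExhausted(f"no tasks left for {labeller_id}")
            else:
                seen.add(task.task_id)
        self._served[labeller_id] = served + 1
        return task

    def submit(self, task: Task, labeller_id: str) -> bool:
        """Record a completed assignment; True when the task just completed
        (for training tasks: time to trigger consensus merging)."""
        task.submissions.append(labeller_id)
        if task.complete and task not in self.completed:
            self.completed.append(task)
            if task.kind == "training_validation":
                try:
                    self.training.remove(task)
                except ValueError:
                    pass
            return True
        return False


def build_consensus(
    annotations: Sequence[Annotation],
    profiles: Mapping[str, LabellerProfile],
    aoi: str,
    spec: GridSpec,
) -> ConsensusLabel:
    """Rasterize one cell's assignments and fuse them with labeller weights."""
    if not annotations:
        raise ValueError("no annotations to merge")
    cell = annotations[0].cell
    masks = [rasterize_annotation(a.cleaned(), cell, spec) for a in annotations]
    weights = [
        labeller_weight(profiles.get(a.labeller_id, LabellerProfile(a.labeller_id)), aoi)
        for a in annotations
    ]
    return merge_consensus(masks, weights, cell=cell)
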