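"""Field-boundary delineation from composites and cropland probabilities.

Five steps per tile, applied to the dry-season composite (boundaries are
most visible then) and the classifier's probability map:

1. *Edge synthesis* — mean-shift filter the composite, then sum the Sobel
   gradient magnitudes of the green, red and NIR bands (each min-max
   scaled to [0, 1] per tile) and of the probability map.
2. *Compact watershed* — over-segment the edge image from a regular marker
   grid (6,400 segments per full-resolution tile, so mean segment size is
   well below the expected field size).
3. *Region-graph merging* — greedily merge the most similar adjacent
   regions (Euclidean distance between per-band normalized means) while
   the globally smallest edge weight stays below 0.05.
4. *Probability filtering* — vectorize the merged regions and keep those
   whose mean cropland probability strictly exceeds 0.5.
5. *Refinement* — drop interior rings, smooth boundaries with Visvalingam
   effective-area simplification, and union polygons that overlap across
   tile seams.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union
from skimage.filters import sobel
from skimage.segmentation import watershed

from .grids import GridSpec, cell_for_point

__all__ = [
    "SegmentationParams",
    "FieldPolygon",
    "FieldPolygonSet",
    "mean_shift_filter",
    "compute_edge_image",
    "initial_watershed",
    "merge_regions",
    "filter_by_probability",
    "refine_polygons",
    "merge_tile_seams",
    "summarize_fields",
    "delineate_tile",
    "area_ha",
    "visvalingam",
]

#: metres per degree of latitude (mean-Earth-radius arc)
M_PER_DEG = 111194.9


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation settings (per-tile)."""

    n_segments: int = 6400
    compactness: float = 0.01
    merge_threshold: float = 0.05
    #: absorb post-merge regions smaller than this fraction of the mean
    #: initial segment size into their most similar neighbour (0 = off)
    min_region_fraction: float = 0.5
    mean_shift_spatial: int = 3
    mean_shift_range: float = 0.1
    mean_shift_iters: int = 10
    simplify_tolerance_px: float = 0.5
    probability_threshold: float = 0.5


def _minmax(band: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(band), np.nanmax(band)
    if hi - lo <= 0:
        return np.zeros_like(band)
    return (band - lo) / (hi - lo)


def mean_shift_filter(
    bands: np.ndarray,
    spatial_radius: int = 3,
    range_radius: float = 0.1,
    max_iter: int = 10,
    tol: float = 1e-4,
) -> np.ndarray:
    """Iterative local mean-shift smoothing of a (C, H, W) image.

    Each pixel moves to the mean of the neighbours (within the spatial
    radius) whose joint-band Euclidean distance is below the range radius;
    edges flatten while interiors smooth.  Converges or stops after
    ``max_iter`` passes.
    """
    v = np.asarray(bands, dtype=float).copy()
    c, h, w = v.shape
    r = spatial_radius
    offsets = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]
    r2 = range_radius**2
    for _ in range(max_iter):
        pad = np.pad(v, ((0, 0), (r, r), (r, r)), mode="edge")
        num = np.zeros_like(v)
        den = np.zeros((h, w))
        for dy, dx in offsets:
            shifted = pad[:, r + dy : r + dy + h, r + dx : r + dx + w]
            close = ((shifted - v) ** 2).sum(axis=0) <= r2
            num += shifted * close
            den += close
        new = num / den  # den >= 1: the pixel itself always qualifies
        if np.max(np.abs(new - v)) < tol:
            v = new
            break
        v = new
    return v


def compute_edge_image(
    dry_composite: np.ndarray,
    probability: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    return_filtered: bool = False,
):
    """Combined edge image: Sobel magnitudes of mean-shifted G, R, NIR and
    of the probability map, summed.  Zero wherever all sources are flat.

    With ``return_filtered`` also returns the mean-shifted [0, 1]-scaled
    G/R/NIR bands, which later feed the region-graph colour means."""
    data = np.asarray(dry_composite, dtype=float)
    if data.ndim != 3 or data.shape[0] != 4:
        raise ValueError("dry composite must have shape (4, H, W)")
    prob = np.asarray(probability, dtype=float)
    if prob.shape != data.shape[1:]:
        raise ValueError("probability map shape mismatch with composite")
    grn = np.stack([_minmax(data[i]) for i in (1, 2, 3)])
    filtered = mean_shift_filter(
        grn,
        spatial_radius=params.mean_shift_spatial,
        range_radius=params.mean_shift_range,
        max_iter=params.mean_shift_iters,
    )
    edges = np.zeros_like(prob)
    for b in filtered:
        edges += sobel(b)
    edges += sobel(np.nan_to_num(prob, nan=0.5))
    if return_filtered:
        return edges, filtered
    return edges


def _marker_grid(n_segments: int, shape: tuple[int, int]) -> np.ndarray:
    """Regular r x c marker-label image with r*c == n_segments and r/c as
    close as possible to the raster aspect ratio."""
    h, w = shape
    best = None
    for r in range(1, n_segments + 1):
        if n_segments % r:
            continue
        c = n_segments // r
        if r > h or c > w:
            continue
        score = abs(math.log((r / c) / (h / w)))
        if best is None or score < best[0]:
            best = (score, r, c)
    if best is None:
        raise ValueError("n_segments cannot be arranged within the raster")
    _, r, c = best
    markers = np.zeros(shape, dtype=np.int32)
    rows = ((np.arange(r) + 0.5) * h / r).astype(int)
    cols = ((np.arange(c) + 0.5) * w / c).astype(int)
    lab = 1
    for i in rows:
        for j in cols:
            markers[i, j] = lab
            lab += 1
    return markers


def initial_watershed(
    edges: np.ndarray,
    n_segments: int = 6400,
    compactness: float = 0.01,
) -> np.ndarray:
    """Compact watershed over the edge image from regular grid markers.

    Returns an int label image partitioning the raster into exactly
    ``n_segments`` non-empty regions (labels 1..n).
    """
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.isfinite(edges)):
        raise ValueError("edge image must be finite")
    if n_segments > edges.size:
        raise ValueError("n_segments exceeds the pixel count")
    markers = _marker_grid(n_segments, edges.shape)
    return watershed(edges, markers=markers, compactness=compactness)


def _region_adjacency(labels: np.ndarray) -> set[tuple[int, int]]:
    pairs = set()
    a, b = labels[:, :-1].ravel(), labels[:, 1:].ravel()
    diff = a != b
    pairs.update(zip(np.minimum(a, b)[diff].tolist(), np.maximum(a, b)[diff].tolist()))
    a, b = labels[:-1, :].ravel(), labels[1:, :].ravel()
    diff = a != b
    pairs.update(zip(np.minimum(a, b)[diff].tolist(), np.maximum(a, b)[diff].tolist()))
    return pairs


def merge_regions(
    labels: np.ndarray,
    bands: np.ndarray,
    threshold: float = 0.05,
    min_region_px: int = 0,
) -> np.ndarray:
    """Greedy region-adjacency-graph merging.

    Node colour = per-band mean of the min-max-normalized bands; edge
    weight = Euclidean distance between node colours.  The globally
    minimum-weight edge is merged while it stays below ``threshold``
    (ties broken by the smallest (min label, max label) pair); a merged
    node's colour is the pixel-count-weighted mean.

    ``min_region_px`` > 0 adds a final absorption pass: any region smaller
    than that many pixels is merged into its most similar neighbour
    regardless of the threshold, which removes the thin boundary-straddling
    slivers the watershed leaves between fields.
    """
    labels = np.asarray(labels)
    bands = np.asarray(bands, dtype=float)
    if bands.ndim == 2:
        bands = bands[None]
    norm = np.stack([_minmax(b) for b in bands])
    flat = labels.ravel()
    max_lab = int(flat.max())
    counts = np.bincount(flat, minlength=max_lab + 1).astype(float)
    sums = np.stack(
        [np.bincount(flat, weights=b.ravel(), minlength=max_lab + 1) for b in norm]
    )  # (C, max_lab+1)
    alive = counts > 0
    means = np.where(alive[None], sums / np.maximum(counts[None], 1), 0.0)

    neighbors: dict[int, set[int]] = {}
    for a, b in _region_adjacency(labels):
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)

    version = {int(l): 0 for l in np.unique(flat)}
    parent = {int(l): int(l) for l in np.unique(flat)}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def weight(a: int, b: int) -> float:
        return float(np.linalg.norm(means[:, a] - means[:, b]))

    heap: list[tuple[float, int, int, int, int]] = []
    for a, nbrs in neighbors.items():
        for b in nbrs:
            if a < b:
                heapq.heappush(heap, (weight(a, b), a, b, version[a], version[b]))

    def do_merge(a: int, b: int) -> None:
        """Merge node b into node a (a < b), updating graph state."""
        parent[b] = a
        total = counts[a] + counts[b]
        means[:, a] = (means[:, a] * counts[a] + means[:, b] * counts[b]) / total
        counts[a] = total
        counts[b] = 0
        version[a] = version.get(a, 0) + 1
        version.pop(b, None)
        nbrs = (neighbors.pop(b) | neighbors[a]) - {a, b}
        neighbors[a] = nbrs
        for c in nbrs:
            neighbors[c].discard(b)
            neighbors[c].add(a)
            lo, hi = (a, c) if a < c else (c, a)
            heapq.heappush(
                heap, (weight(lo, hi), lo, hi, version[lo], version[hi])
            )

    while heap:
        w, a, b, va, vb = heapq.heappop(heap)
        if version.get(a) != va or version.get(b) != vb:
            continue
        if find(a) != a or find(b) != b or b not in neighbors.get(a, ()):
            continue
        if w >= threshold:
            break
        do_merge(a, b)

    if min_region_px > 0:
        changed = True
        while changed:
            changed = False
            small = sorted(
                (
                    l
                    for l in list(neighbors)
                    if find(l) == l
                    and 0 < counts[l] < min_region_px
                    and neighbors.get(l)
                ),
                key=lambda l: (counts[l], l),
            )
            for s in small:
                if find(s) != s or not neighbors.get(s):
                    continue
                nb = min(
                    neighbors[s],
                    key=lambda c: (weight(min(s, c), max(s, c)), c),
                )
                a, b = (s, nb) if s < nb else (nb, s)
                do_merge(a, b)
                changed = True
    roots = np.array([find(int(l)) if int(l) in parent else int(l) for l in
                      range(max_lab + 1)])
    return roots[labels]


def area_ha(geom, lat: float | None = None) -> float:
    """Approximate polygon area in hectares from lon/lat coordinates,
    using a latitude-dependent equal-area local scaling."""
    if lat is None:
        lat = geom.centroid.y
    m2 = geom.area * M_PER_DEG**2 * math.cos(math.radians(lat))
    return m2 / 1e4


@dataclass
class FieldPolygon:
    field_id: str
    geometry: Polygon
    area_ha: float
    mean_prob: float
    tiles: tuple[str, ...]


@dataclass
class FieldPolygonSet:
    fields: list[FieldPolygon] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fields)

    def __iter__(self):
        return iter(self.fields)

    def total_area_ha(self) -> float:
        return sum(f.area_ha for f in self.fields)

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": shapely.geometry.mapping(f.geometry),
                    "properties": {
                        "field_id": f.field_id,
                        "area_ha": f.area_ha,
                        "mean_prob": f.mean_prob,
                        "tile_id": ",".join(f.tiles),
                    },
                }
                for f in self.fields
            ],
        }


def _region_polygon(mask: np.ndarray, bounds, shape) -> Polygon:
    """Exact polygon of a pixel region: union of its pixel squares."""
    lon0, lat0, lon1, lat1 = bounds
    h, w = shape
    px_x = (lon1 - lon0) / w
    px_y = (lat1 - lat0) / h
    rr, cc = np.nonzero(mask)
    boxes = [
        box(
            lon0 + c * px_x,
            lat1 - (r + 1) * px_y,
            lon0 + (c + 1) * px_x,
            lat1 - r * px_y,
        )
        for r, c in zip(rr, cc)
    ]
    geom = unary_union(boxes)
    if geom.geom_type == "MultiPolygon":
        geom = max(geom.geoms, key=lambda g: g.area)
    return geom


def filter_by_probability(
    labels: np.ndarray,
    probability: np.ndarray,
    bounds: tuple[float, float, float, float],
    tile_id: str = "tile",
    threshold: float = 0.5,
) -> FieldPolygonSet:
    """Vectorize regions and retain those with mean probability strictly
    above the threshold."""
    labels = np.asarray(labels)
    prob = np.asarray(probability, dtype=float)
    out = FieldPolygonSet()
    k = 0
    for lab in np.unique(labels):
        mask = labels == lab
        with np.errstate(invalid="ignore"):
            mp = float(np.nanmean(prob[mask]))
        if not (mp > threshold):
            continue
        geom = _region_polygon(mask, bounds, labels.shape)
        out.fields.append(
            FieldPolygon(
                field_id=f"{tile_id}_f{k}",
                geometry=geom,
                area_ha=area_ha(geom),
                mean_prob=mp,
                tiles=(tile_id,),
            )
        )
        k += 1
    return out


def _triangle_area(a, b, c) -> float:
    return 0.5 * abs(
        (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
    )


def visvalingam(coords: Sequence[tuple[float, float]], threshold: float) -> list:
    """Visvalingam-Whyatt ring simplification.

    Repeatedly removes the vertex whose effective (triangle) area is the
    smallest, while that area is below ``threshold``.  ``coords`` is a
    closed ring (first == last); the closing vertex is preserved.
    """
    pts = [tuple(p) for p in coords[:-1]]
    while len(pts) > 3:
        n = len(pts)
        areas = [
            _triangle_area(pts[(i - 1) % n], pts[i], pts[(i + 1) % n])
            for i in range(n)
        ]
        i_min = int(np.argmin(areas))
        if areas[i_min] >= threshold:
            break
        pts.pop(i_min)
    return pts + [pts[0]]


def refine_polygons(
    fields: FieldPolygonSet,
    pixel_size: float,
    tolerance_px: float = 0.5,
) -> FieldPolygonSet:
    """Remove interior rings and Visvalingam-smooth each field boundary.

    The effective-area tolerance defaults to half a pixel's area.  A
    polygon collapsing below 3 vertices is dropped.
    """
    tol = tolerance_px * pixel_size**2
    out = FieldPolygonSet()
    for f in fields:
        ring = visvalingam(list(f.geometry.exterior.coords), tol)
        if len(ring) < 4:  # closed ring needs >= 3 distinct vertices
            continue
        geom = Polygon(ring)
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
            if geom.geom_type == "MultiPolygon":
                geom = max(geom.geoms, key=lambda g: g.area)
            if geom.is_empty or geom.geom_type != "Polygon":
                continue
        out.fields.append(
            replace(f, geometry=geom, area_ha=area_ha(geom))
        )
    return out


def merge_tile_seams(
    per_tile: Sequence[FieldPolygonSet],
    pixel_size: float,
) -> FieldPolygonSet:
    """Union fields from different tiles whose 1-pixel-buffered geometries
    intersect (fields split across a seam become one polygon).  Idempotent:
    a second application changes nothing."""
    fields = [f for s in per_tile for f in s]
    n = len(fields)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    buffered = [f.geometry.buffer(pixel_size) for f in fields]
    tree = shapely.STRtree(buffered)
    for i in range(n):
        for j in tree.query(buffered[i], predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            if set(fields[i].tiles) != set(fields[j].tiles):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = FieldPolygonSet()
    for root, members in sorted(groups.items()):
        if len(members) == 1:
            out.fields.append(fields[members[0]])
            continue
        geom = unary_union([fields[i].geometry for i in members])
        if geom.geom_type == "MultiPolygon":
            geom = unary_union(
                [g.buffer(pixel_size / 2) for g in geom.geoms]
            ).buffer(-pixel_size / 2)
            if geom.geom_type == "MultiPolygon":
                geom = max(geom.geoms, key=lambda g: g.area)
        areas = np.array([fields[i].geometry.area for i in members])
        probs = np.array([fields[i].mean_prob for i in members])
        tiles = tuple(sorted({t for i in members for t in fields[i].tiles}))
        out.fields.append(
            FieldPolygon(
                field_id=fields[members[0]].field_id,
                geometry=geom,
                area_ha=area_ha(geom),
                mean_prob=float(np.average(probs, weights=areas)),
                tiles=tiles,
            )
        )
    return out


def summarize_fields(
    fields: FieldPolygonSet,
    spec: GridSpec,
    level: str = "tile",
) -> dict[str, dict[str, float]]:
    """Per-cell mean field size (ha) and count, assigning by centroid."""
    out: dict[str, dict[str, float]] = {}
    for f in fields:
        c = f.geometry.centroid
        cell = cell_for_point(c.x, c.y, level, spec)
        rec = out.setdefault(cell.cell_id, {"count": 0, "_area": 0.0})
        rec["count"] += 1
        rec["_area"] += f.area_ha
    for rec in out.values():
        rec["mean_size_ha"] = rec.pop("_area") / rec["count"]
    return out


def delineate_tile(
    dry_composite: np.ndarray,
    probability: np.ndarray,
    bounds: tuple[float, float, float, float],
    pixel_size: float,
    tile_id: str = "tile",
    params: SegmentationParams = SegmentationParams(),
) -> tuple[FieldPolygonSet, np.ndarray]:
    """All five per-tile steps; returns (refined fields, merged labels)."""
    edges, filtered = compute_edge_image(
        dry_composite, probability, params, return_filtered=True
    )
    segs = initial_watershed(edges, params.n_segments, params.compactness)
    min_px = int(
        params.min_region_fraction * segs.size / max(params.n_segments, 1)
    )
    merged = merge_regions(segs, filtered, params.merge_threshold, min_px)
    fields = filter_by_probability(
        merged, probability, bounds, tile_id, params.probability_threshold
    )
    refined = refine_polygons(fields, pixel_size, params.simplify_tolerance_px)
    return refined, merged
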