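"""Seeded synthetic landscapes, scene stacks and labellers.

Every downstream stage (compositing, labelling, classification,
segmentation, assessment) is exercised against data from this module, which
always ships its own ground truth: the true field polygons, the clean
(atmosphere- and noise-free) imagery, and the true cover raster.

The landscape is a Poisson-point Voronoi tessellation — contiguous,
irregular field mosaics — with a hard-core thinning step whose per-point
lognormal radii spread the field-size distribution.  Three cover types are
rendered: annual cropland, natural vegetation, and bare/sparsely-vegetated
ground.  Cropland and vegetation are nearly identical in the growing
season, while cropland and bare ground converge in the dry season, so the
two classes are separable mainly through the *seasonal contrast* — the
rationale for two-season features.  A per-field "condition" coefficient
mixes each field's spectrum toward the opposing class, producing a
continuum of easy to ambiguous fields.

The atmosphere model is deliberately simple: binary cloud/shadow disk masks
with additive brightening (clouds, strongest in blue) and multiplicative
NIR darkening (shadows), plus i.i.d. Gaussian noise.  It is sufficient to
exercise the haze and shadow compositing weights, not a radiative-transfer
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from typing import Sequence

import numpy as np
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .grids import CellRef, GridSpec

__all__ = [
    "COVERS",
    "DEFAULT_SPECTRA",
    "LandscapeParams",
    "AtmosphereParams",
    "LabellerSpec",
    "SyntheticLandscape",
    "SceneStack",
    "make_landscape",
    "rasterize_cover",
    "truth_composites",
    "render_time_series",
    "season_mix",
    "simulate_labeller",
]

COVERS = ("vegetation", "cropland", "bare")

#: per-cover, per-season mean reflectance (blue, green, red, NIR)
DEFAULT_SPECTRA: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "cropland": {
        "growing": (0.045, 0.075, 0.055, 0.46),
        "dry": (0.100, 0.140, 0.200, 0.24),
    },
    "vegetation": {
        "growing": (0.045, 0.080, 0.060, 0.44),
        "dry": (0.070, 0.100, 0.100, 0.36),
    },
    "bare": {
        "growing": (0.090, 0.120, 0.150, 0.28),
        "dry": (0.110, 0.150, 0.210, 0.26),
    },
}

#: which cover an ambiguous field of each class drifts toward
_CONFUSER = {"cropland": "vegetation", "vegetation": "cropland", "bare": "cropland"}


@dataclass(frozen=True)
class LandscapeParams:
    """Field mosaic generator settings.

    ``fields_per_tile`` is the Poisson intensity per 0.05-degree tile area;
    ``size_sigma`` is the lognormal spread of the hard-core thinning radii
    (larger -> more unequal field sizes); ``max_mix`` bounds the per-field
    spectral drift toward the opposing class (0 = perfectly separable
    covers).  The drift is concentrated along a randomly oriented *ecotone*
    band of relative width ``ecotone_width`` — fields inside the band
    intergrade with the surrounding cover, fields far from it stay close to
    their pure spectra, emulating the transition zones where classifiers
    struggle most.
    """

    cropland_fraction: float = 0.3
    fields_per_tile: float = 64.0
    size_sigma: float = 0.45
    bare_fraction: float = 0.25
    max_mix: float = 0.7
    ecotone_width: float = 0.12

    def __post_init__(self) -> None:
        for name in ("cropland_fraction", "bare_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fields_per_tile <= 0:
            raise ValueError("fields_per_tile must be positive")


@dataclass(frozen=True)
class AtmosphereParams:
    """Cloud/shadow/noise injection settings for rendered scenes."""

    cloud_fraction: float = 0.3
    shadow_fraction: float = 0.1
    noise_sigma: float = 0.01
    cloud_radius_px: float = 10.0
    cloud_brightening: float = 0.35
    cloud_blue_extra: float = 0.10
    shadow_nir_factor: float = 0.25
    shadow_vis_factor: float = 0.8


@dataclass(frozen=True)
class LabellerSpec:
    """A simulated labeller of controllable skill.

    ``jitter_px`` is the per-vertex Gaussian displacement (in pixels),
    ``omission_rate`` the chance of skipping a true field, and
    ``commission_rate`` drives spurious polygons.  ``from_skill`` derives
    all three from a single skill scalar in [0, 1] (1 = perfect).
    """

    skill: float = 1.0
    jitter_px: float = 0.0
    omission_rate: float = 0.0
    commission_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("skill", "omission_rate", "commission_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_skill(cls, skill: float, seed: int = 0) -> "LabellerSpec":
        return cls(
            skill=skill,
            jitter_px=4.0 * (1.0 - skill),
            omission_rate=0.5 * (1.0 - skill),
            commission_rate=0.5 * (1.0 - skill),
            seed=seed,
        )


@dataclass
class SyntheticLandscape:
    """A generated field mosaic with full ground truth."""

    polygons: list[tuple[Polygon, str]]
    mix: np.ndarray  # per-polygon spectral mixing coefficient in [0, 1)
    domain: tuple[float, float, float, float]
    params: LandscapeParams
    seed: int
    spectra: dict[str, dict[str, tuple[float, float, float, float]]] = field(
        default_factory=lambda: DEFAULT_SPECTRA
    )

    @property
    def cropland_polygons(self) -> list[Polygon]:
        return [g for g, c in self.polygons if c == "cropland"]

    @property
    def realized_cropland_fraction(self) -> float:
        total = sum(g.area for g, _ in self.polygons)
        crop = sum(g.area for g in self.cropland_polygons)
        return crop / total if total else 0.0


@dataclass
class SceneStack:
    """Daily rendered scenes plus the clean truth they were derived from."""

    dates: list[_date]
    data: np.ndarray  # (n_dates, 4, H, W) with atmosphere + noise
    clean: np.ndarray  # (n_dates, 4, H, W) noise- and atmosphere-free
    cloud_mask: np.ndarray  # (n_dates, H, W) bool
    shadow_mask: np.ndarray  # (n_dates, H, W) bool

    def clean_mean(self) -> np.ndarray:
        """Unweighted mean of the clean stack — the compositing oracle."""
        return self.clean.mean(axis=0)


def _bounded_voronoi(points: np.ndarray, domain) -> list[Polygon]:
    """Voronoi cells clipped exactly to the rectangular domain.

    Points are mirrored across all four domain edges so every interior cell
    is finite; cells are then clipped to the domain rectangle.
    """
    lon0, lat0, lon1, lat1 = domain
    mirrored = [points]
    for axis, lo, hi in ((0, lon0, lon1), (1, lat0, lat1)):
        for edge in (lo, hi):
            m = points.copy()
            m[:, axis] = 2 * edge - m[:, axis]
            mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    rect = box(lon0, lat0, lon1, lat1)
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:  # pragma: no cover - mirroring prevents this
            continue
        poly = Polygon(vor.vertices[region]).intersection(rect)
        if not poly.is_empty and poly.area > 0:
            cells.append(poly if isinstance(poly, Polygon) else unary_union(poly))
    return cells


def make_landscape(
    seed: int,
    domain: tuple[float, float, float, float],
    params: LandscapeParams = LandscapeParams(),
    tile_size: float = 0.05,
) -> SyntheticLandscape:
    """Generate a deterministic field mosaic over a rectangular domain.

    Field seeds are a Poisson point process thinned by a hard-core rule with
    lognormal radii; surviving points induce a Voronoi tessellation clipped
    to the domain.  Cells are assigned to cropland greedily (largest shuffle
    order first) until the target area fraction is reached, then the rest
    split between vegetation and bare ground.
    """
    lon0, lat0, lon1, lat1 = domain
    if not (lon1 > lon0 and lat1 > lat0):
        raise ValueError("empty domain")
    rng = np.random.default_rng(seed)
    area = (lon1 - lon0) * (lat1 - lat0)
    intensity = params.fields_per_tile / tile_size**2
    # oversample, then thin to roughly the requested density
    n_cand = max(4, rng.poisson(1.8 * intensity * area))
    pts = np.column_stack(
        [rng.uniform(lon0, lon1, n_cand), rng.uniform(lat0, lat1, n_cand)]
    )
    mean_spacing = 1.0 / np.sqrt(intensity)
    radii = rng.lognormal(mean=0.0, sigma=params.size_sigma, size=n_cand)
    radii *= 0.45 * mean_spacing
    keep: list[int] = []
    for i in rng.permutation(n_cand):
        ok = True
        for j in keep:
            if np.hypot(*(pts[i] - pts[j])) < (radii[i] + radii[j]) / 2:
                ok = False
                break
        if ok:
            keep.append(int(i))
    pts = pts[keep]
    if len(pts) < 4:
        extra = np.column_stack(
            [rng.uniform(lon0, lon1, 4), rng.uniform(lat0, lat1, 4)]
        )
        pts = np.vstack([pts, extra])

    cells = _bounded_voronoi(pts, domain)
    order = rng.permutation(len(cells))
    target = params.cropland_fraction * area
    assigned: list[tuple[Polygon, str]] = []
    crop_area = 0.0
    for idx in order:
        poly = cells[idx]
        if params.cropland_fraction > 0 and crop_area < target:
            assigned.append((poly, "cropland"))
            crop_area += poly.area
        else:
            cover = "bare" if rng.random() < params.bare_fraction else "vegetation"
            assigned.append((poly, cover))
    # ecotone band: project field centroids on a random direction; fields
    # inside a band around a random transition locus take a strong but
    # *consistent* shift toward the opposing cover (hard until labelled,
    # then learnable), while the background carries only mild ambiguity
    direction = rng.uniform(0, np.pi)
    u = np.array([np.cos(direction), np.sin(direction)])
    cents = np.array([[g.centroid.x, g.centroid.y] for g, _ in assigned])
    span = np.array([lon1 - lon0, lat1 - lat0])
    t = ((cents - [lon0, lat0]) / span) @ u / u.sum()  # in [0, 1]
    t0 = rng.uniform(0.3, 0.7)
    in_band = np.abs(t - t0) < max(params.ecotone_width, 1e-6) / 2
    mix = 0.3 * params.max_mix * rng.beta(2.0, 5.0, size=len(assigned))
    mix[in_band] = params.max_mix * rng.uniform(0.85, 1.0, int(in_band.sum()))
    return SyntheticLandscape(
        polygons=assigned, mix=mix, domain=domain, params=params, seed=seed
    )


def _pixel_centers(bounds, shape) -> tuple[np.ndarray, np.ndarray]:
    """Meshgrid of pixel-center lon/lat for a raster window (row 0 = north)."""
    lon0, lat0, lon1, lat1 = bounds
    h, w = shape
    px_x = (lon1 - lon0) / w
    px_y = (lat1 - lat0) / h
    lons = lon0 + (np.arange(w) + 0.5) * px_x
    lats = lat1 - (np.arange(h) + 0.5) * px_y
    return np.meshgrid(lons, lats)


def rasterize_cover(
    landscape: SyntheticLandscape, bounds, shape
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the mosaic onto a window.

    Returns ``(cover, poly_index)`` where ``cover`` holds COVERS indices per
    pixel (pixel-center rule) and ``poly_index`` the owning polygon's index
    (-1 where no polygon covers the center, e.g. just outside the domain —
    such pixels are treated as vegetation).
    """
    lon_g, lat_g = _pixel_centers(bounds, shape)
    pts = shapely.points(lon_g.ravel(), lat_g.ravel())
    cover = np.zeros(lon_g.size, dtype=np.int8)
    poly_index = np.full(lon_g.size, -1, dtype=np.int64)
    tree = shapely.STRtree([g for g, _ in landscape.polygons])
    q = tree.query(pts, predicate="intersects")
    # later polygons win on shared boundaries; ownership is unique a.e.
    poly_index[q[0]] = q[1]
    for k, (_, cov) in enumerate(landscape.polygons):
        sel = poly_index == k
        cover[sel] = COVERS.index(cov)
    return cover.reshape(shape), poly_index.reshape(shape)


def _field_spectra(landscape: SyntheticLandscape) -> dict[str, np.ndarray]:
    """Per-polygon 4-band spectra for each season, after confusion mixing."""
    out = {}
    for season in ("growing", "dry"):
        rows = []
        for k, (_, cov) in enumerate(landscape.polygons):
            own = np.array(landscape.spectra[cov][season])
            other = np.array(landscape.spectra[_CONFUSER[cov]][season])
            m = landscape.mix[k]
            rows.append((1 - m) * own + m * other)
        out[season] = np.array(rows)  # (n_polys, 4)
    return out


def _spectral_image(
    landscape: SyntheticLandscape,
    bounds,
    shape,
    season_weight: float,
    poly_index: np.ndarray | None = None,
    spectra: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Clean (4, H, W) image interpolated between growing (0) and dry (1)."""
    if poly_index is None:
        _, poly_index = rasterize_cover(landscape, bounds, shape)
    if spectra is None:
        spectra = _field_spectra(landscape)
    n = len(landscape.polygons)
    per_poly = (1 - season_weight) * spectra["growing"] + season_weight * spectra[
        "dry"
    ]  # (n, 4)
    # background (no polygon) pixels take the pure vegetation spectrum
    bg = (1 - season_weight) * np.array(
        landscape.spectra["vegetation"]["growing"]
    ) + season_weight * np.array(landscape.spectra["vegetation"]["dry"])
    table = np.vstack([per_poly, bg[None]])  # index n = background
    idx = np.where(poly_index >= 0, poly_index, n)
    img = table[idx.ravel()].reshape(*shape, 4)
    return np.moveaxis(img, -1, 0)


def season_mix(d: _date) -> float:
    """Seasonal interpolation weight: 0 at peak growing season (mid July),
    1 at the height of the dry season (mid January)."""
    doy = d.timetuple().tm_yday
    return 0.5 - 0.5 * np.cos(2 * np.pi * (doy - 196) / 365.25)


def truth_composites(
    landscape: SyntheticLandscape, bounds, shape
) -> dict[str, np.ndarray]:
    """Clean season-endmember images: the parameter-recovery ground truth."""
    return {
        "growing": _spectral_image(landscape, bounds, shape, 0.0),
        "dry": _spectral_image(landscape, bounds, shape, 1.0),
    }


def _disk_mask(rng, shape, target_fraction: float, radius: float) -> np.ndarray:
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if target_fraction <= 0:
        return mask
    n_disks = max(1, round(target_fraction * h * w / (np.pi * radius**2)))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_disks):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = radius * rng.uniform(0.6, 1.4)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def render_time_series(
    landscape: SyntheticLandscape,
    dates: Sequence[_date],
    atmosphere: AtmosphereParams,
    bounds,
    shape,
    seed: int,
) -> SceneStack:
    """Render a dated scene stack over one window.

    Per date: reflectance = seasonally interpolated cover spectrum +
    Gaussian noise; injected cloud disks brighten all bands (blue most);
    shadow disks depress NIR.  The clean (pre-atmosphere, pre-noise) stack
    rides along as the compositing oracle.
    """
    if len(dates) == 0:
        raise ValueError("at least one date is required")
    rng = np.random.default_rng(seed)
    h, w = shape
    n = len(dates)
    clean = np.empty((n, 4, h, w))
    data = np.empty_like(clean)
    cloud = np.zeros((n, h, w), dtype=bool)
    shadow = np.zeros((n, h, w), dtype=bool)
    _, poly_index = rasterize_cover(landscape, bounds, shape)
    spectra = _field_spectra(landscape)
    for t, d in enumerate(dates):
        img = _spectral_image(
            landscape, bounds, shape, season_mix(d), poly_index, spectra
        )
        clean[t] = img
        cm = _disk_mask(rng, shape, atmosphere.cloud_fraction, atmosphere.cloud_radius_px)
        sm = _disk_mask(
            rng, shape, atmosphere.shadow_fraction, atmosphere.cloud_radius_px
        )
        sm &= ~cm  # shadow only where not overwritten by cloud
        out = img + rng.normal(0.0, atmosphere.noise_sigma, size=img.shape)
        out = np.where(cm[None], out + atmosphere.cloud_brightening, out)
        out[0] = np.where(cm, out[0] + atmosphere.cloud_blue_extra, out[0])
        out[:3] = np.where(sm[None], out[:3] * atmosphere.shadow_vis_factor, out[:3])
        out[3] = np.where(sm, out[3] * atmosphere.shadow_nir_factor, out[3])
        data[t] = np.clip(out, 0.0, None)
        cloud[t] = cm
        shadow[t] = sm
    return SceneStack(
        dates=list(dates), data=data, clean=clean, cloud_mask=cloud, shadow_mask=shadow
    )


def _jitter_polygon(poly: Polygon, sigma: float, rng) -> Polygon | None:
    if sigma <= 0:
        return poly
    coords = np.asarray(poly.exterior.coords)[:-1]
    coords = coords + rng.normal(0.0, sigma, size=coords.shape)
    if len(coords) < 3:
        return None
    cand = shapely.make_valid(Polygon(coords))
    if cand.is_empty:
        return None
    if cand.geom_type != "Polygon":
        parts = [g for g in getattr(cand, "geoms", []) if g.geom_type == "Polygon"]
        if not parts:
            return None
        cand = max(parts, key=lambda g: g.area)
    return cand


def simulate_labeller(
    truth_polygons: Sequence[Polygon],
    spec: LabellerSpec,
    cell: CellRef,
    grid: GridSpec,
    extent_px: float = 4.0,
) -> list[tuple[Polygon, str]]:
    """One labeller's digitization of the cropland fields in a primary cell.

    True field polygons intersecting the (slightly buffered) cell window
    are vertex-jittered, randomly omitted, and supplemented with spurious
    commission polygons.  Deterministic in (spec.seed, cell).
    """
    rng = np.random.default_rng((spec.seed, cell.col, cell.row, 7))
    lon0, lat0, lon1, lat1 = cell.bounds(grid)
    px = grid.pixel_size
    window = box(lon0 - extent_px * px, lat0 - extent_px * px,
                 lon1 + extent_px * px, lat1 + extent_px * px)
    sigma = spec.jitter_px * px
    out: list[tuple[Polygon, str]] = []
    for poly in truth_polygons:
        if not poly.intersects(window):
            continue
        clipped = poly.intersection(window)
        parts = (
            [clipped]
            if clipped.geom_type == "Polygon"
            else [g for g in getattr(clipped, "geoms", []) if g.geom_type == "Polygon"]
        )
        for part in parts:
            if part.area <= 0:
                continue
            if rng.random() < spec.omission_rate:
                continue
            jittered = _jitter_polygon(part, sigma, rng)
            if jittered is not None and jittered.area > 0:
                out.append((jittered, "annual cropland"))
    n_comm = rng.poisson(spec.commission_rate * max(1, len(out)))
    for _ in range(n_comm):
        cx = rng.uniform(lon0, lon1)
        cy = rng.uniform(lat0, lat1)
        r = rng.uniform(2.0, 6.0) * px
        out.append((Point(cx, cy).buffer(r, quad_segs=4), "annual cropland"))
    return out
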