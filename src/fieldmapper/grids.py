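"""Nested geographic grids for tiled cropland mapping.

Three nested levels share one origin: coarse *tiles* (default 0.05°) that
composites are built on, *primary* cells (default 0.005°) that are presented
to labellers and scored for active-learning uncertainty, and *pixels*
(default 0.000025°, ~2.8 m at the equator) matching the native image
resolution.  All cells use half-open intervals ``[lo, lo + size)`` with the
origin at the domain's south-west corner and row indices increasing
northward, so every point belongs to exactly one cell per level.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GridSpec",
    "CellRef",
    "AOI",
    "GridDomainError",
    "GridContractError",
    "cell_for_point",
    "primary_cells_of",
    "raster_window",
    "partition_aois",
    "cells_to_csv",
    "cells_from_csv",
]

LEVELS = ("tile", "primary")


class GridDomainError(ValueError):
    """A point falls outside the configured grid domain."""


class GridContractError(ValueError):
    """An operation precondition on grid structure was violated."""


def _is_integer_multiple(a: float, b: float, tol: float = 1e-9) -> bool:
    r = a / b
    return abs(r - round(r)) < tol and round(r) >= 1


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the nested lon/lat grid.

    Sizes are in decimal degrees.  ``tile_size`` must be an exact integer
    multiple of ``primary_size``, which must be an exact integer multiple of
    ``pixel_size``.  ``n_tiles_x``/``n_tiles_y`` optionally bound the domain;
    when ``None`` the grid extends indefinitely north/east of the origin.
    """

    origin_lon: float = 0.0
    origin_lat: float = 0.0
    tile_size: float = 0.05
    primary_size: float = 0.005
    pixel_size: float = 0.000025
    n_tiles_x: int | None = None
    n_tiles_y: int | None = None

    def __post_init__(self) -> None:
        if min(self.tile_size, self.primary_size, self.pixel_size) <= 0:
            raise GridContractError("grid sizes must be positive")
        if not _is_integer_multiple(self.tile_size, self.primary_size):
            raise GridContractError(
                "tile_size must be an integer multiple of primary_size"
            )
        if not _is_integer_multiple(self.primary_size, self.pixel_size):
            raise GridContractError(
                "primary_size must be an integer multiple of pixel_size"
            )

    def size(self, level: str) -> float:
        if level == "tile":
            return self.tile_size
        if level == "primary":
            return self.primary_size
        raise GridContractError(f"unknown level {level!r}")

    @property
    def primaries_per_tile_axis(self) -> int:
        return round(self.tile_size / self.primary_size)

    def domain_bounds(self) -> tuple[float, float, float, float] | None:
        """(lon0, lat0, lon1, lat1) of the bounded domain, or None."""
        if self.n_tiles_x is None or self.n_tiles_y is None:
            return None
        return (
            self.origin_lon,
            self.origin_lat,
            self.origin_lon + self.n_tiles_x * self.tile_size,
            self.origin_lat + self.n_tiles_y * self.tile_size,
        )


@dataclass(frozen=True)
class CellRef:
    """A cell at one grid level, addressed by (level, col, row).

    Columns count eastward and rows northward from the grid origin.  Bounds
    are half-open: ``[lon0, lon0+s) x [lat0, lat0+s)``.
    """

    level: str
    col: int
    row: int

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise GridContractError(f"level must be one of {LEVELS}")
        if self.col < 0 or self.row < 0:
            raise GridContractError("col/row must be non-negative")

    def bounds(self, spec: GridSpec) -> tuple[float, float, float, float]:
        s = spec.size(self.level)
        lon0 = spec.origin_lon + self.col * s
        lat0 = spec.origin_lat + self.row * s
        return (lon0, lat0, lon0 + s, lat0 + s)

    def center(self, spec: GridSpec) -> tuple[float, float]:
        lon0, lat0, lon1, lat1 = self.bounds(spec)
        return ((lon0 + lon1) / 2, (lat0 + lat1) / 2)

    @property
    def cell_id(self) -> str:
        return f"{self.level}_{self.col}_{self.row}"

    @staticmethod
    def from_id(cell_id: str) -> "CellRef":
        level, col, row = cell_id.rsplit("_", 2)
        return CellRef(level, int(col), int(row))


def cell_for_point(lon: float, lat: float, level: str, spec: GridSpec) -> CellRef:
    """Return the half-open cell at ``level`` containing (lon, lat)."""
    if lon < spec.origin_lon or lat < spec.origin_lat:
        raise GridDomainError(f"point ({lon}, {lat}) lies south/west of the origin")
    dom = spec.domain_bounds()
    if dom is not None and (lon >= dom[2] or lat >= dom[3]):
        raise GridDomainError(f"point ({lon}, {lat}) lies outside the domain")
    s = spec.size(level)
    col = math.floor((lon - spec.origin_lon) / s)
    row = math.floor((lat - spec.origin_lat) / s)
    return CellRef(level, col, row)


def primary_cells_of(tile: CellRef, spec: GridSpec) -> list[CellRef]:
    """All primary cells nested in ``tile``, row-major from the south-west."""
    if tile.level != "tile":
        raise GridContractError("primary_cells_of expects a tile-level cell")
    k = spec.primaries_per_tile_axis
    cells = []
    for dr in range(k):
        for dc in range(k):
            cells.append(CellRef("primary", tile.col * k + dc, tile.row * k + dr))
    return cells


def raster_window(cell: CellRef, spec: GridSpec) -> tuple[int, int]:
    """Pixel window (n_cols, n_rows) aligned to a cell's bounds.

    A default primary cell is 200x200 pixels (40,000 pixels), a default tile
    2000x2000.
    """
    s = spec.size(cell.level)
    if not _is_integer_multiple(s, spec.pixel_size):
        raise GridContractError("pixel_size does not divide the cell size exactly")
    n = round(s / spec.pixel_size)
    return (n, n)


@dataclass
class AOI:
    """A named mapping region: a set of tiles processed with one model."""

    name: str
    tiles: list[CellRef] = field(default_factory=list)


def partition_aois(
    tiles: Sequence[CellRef], grouping: Mapping[str, str]
) -> list[AOI]:
    """Partition tiles into named AOIs via a tile_id -> aoi_id mapping.

    Every tile must be covered by the grouping; each tile lands in exactly
    one AOI.  AOIs are returned sorted by name.
    """
    missing = [t.cell_id for t in tiles if t.cell_id not in grouping]
    if missing:
        raise GridContractError(f"grouping does not cover tiles: {missing}")
    by_name: dict[str, AOI] = {}
    for t in tiles:
        name = grouping[t.cell_id]
        by_name.setdefault(name, AOI(name)).tiles.append(t)
    return [by_name[k] for k in sorted(by_name)]


def cells_to_csv(cells: Iterable[CellRef], spec: GridSpec, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["level", "col", "row", "lon0", "lat0"])
        for c in cells:
            lon0, lat0, _, _ = c.bounds(spec)
            w.writerow([c.level, c.col, c.row, repr(lon0), repr(lat0)])


def cells_from_csv(path: str) -> list[CellRef]:
    out = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            out.append(CellRef(rec["level"], int(rec["col"]), int(rec["row"])))
    return out
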