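"""Cell Aggregation Algorithm (CAA): quadrat counts, percentile seeding,
layer-wise growth, and polygon delineation of cell aggregates.

The algorithm, borrowed from quadrat methods in spatial ecology, works on one
field of view:

1. subdivide the analysis window into a grid of equal squares;
2. count the cells of each class in each square;
3. take the distribution of per-square counts (zeros included);
4. squares with counts strictly above a chosen percentile of that
   distribution (default 95) become *seeds* — centers of aggregates;
5. grow each seed outward one layer of adjacent squares at a time, adding
   adjacent squares holding at least ``growth_cutoff`` cells;
6. stop when no adjacent square qualifies;
7. contain the member squares — joint and disjoint — in a (multi-)polygon.

Intersecting the tumor-cell aggregate with the CD3+ T-cell aggregate of the
same FOV yields the *infiltration area* (IA): the part of the tumor
effectively infiltrated by T cells.  Because both aggregates live on the
same grid, IA areas are exact multiples of the square area.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import box as shapely_box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import ConfigError, DataError
from .io import CellTable, FOVWindow

__all__ = [
    "CAAConfig",
    "GridCounts",
    "Aggregate",
    "InfiltrationArea",
    "grid_counts",
    "seed_squares",
    "grow_aggregates",
    "aggregates_to_polygons",
    "delineate_aggregates",
    "infiltration_areas",
    "cells_in_region",
    "region_mask",
]


@dataclass(frozen=True)
class CAAConfig:
    """Parameters of the aggregation algorithm.

    square_size_um
        Grid square side, μm (default 50).
    seed_percentile
        Percentile of the per-square count distribution above which a square
        seeds an aggregate (strict inequality; linear-interpolation
        quantile).
    growth_cutoff
        Minimum cell count for a square to be absorbed during growth.
        ``"auto"`` uses the median of the nonzero per-square counts of the
        class being grown.
    connectivity
        8 (edge or corner adjacency, the full surrounding layer; default)
        or 4 (edge adjacency only).
    """

    square_size_um: float = 50.0
    seed_percentile: float = 95.0
    growth_cutoff: int | str = "auto"
    connectivity: int = 8

    def __post_init__(self):
        if self.square_size_um <= 0:
            raise ConfigError("square_size_um must be > 0")
        if not (0 < self.seed_percentile < 100):
            raise ConfigError("seed_percentile must be in (0, 100)")
        if isinstance(self.growth_cutoff, str):
            if self.growth_cutoff != "auto":
                raise ConfigError("growth_cutoff must be a nonnegative integer or 'auto'")
        elif self.growth_cutoff < 0:
            raise ConfigError("growth_cutoff must be >= 0")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")


@dataclass
class GridCounts:
    """Per-class quadrat counts over one FOV window.

    ``counts[label]`` is an ``(n_rows, n_cols)`` integer matrix; row ``r``,
    column ``c`` covers ``[x0 + c·s, x0 + (c+1)·s) × [y0 + r·s, y0 + (r+1)·s)``
    (the last row/column is closed so window-edge cells are kept).
    """

    fov_id: object
    x0: float
    y0: float
    square_size_um: float
    n_rows: int
    n_cols: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_squares(self) -> int:
        return self.n_rows * self.n_cols

    def square_polygon(self, row: int, col: int) -> BaseGeometry:
        s = self.square_size_um
        return shapely_box(self.x0 + col * s, self.y0 + row * s, self.x0 + (col + 1) * s, self.y0 + (row + 1) * s)

    def same_grid(self, other: "GridCounts") -> bool:
        return (
            self.fov_id == other.fov_id
            and self.x0 == other.x0
            and self.y0 == other.y0
            and self.square_size_um == other.square_size_um
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
        )


@dataclass
class Aggregate:
    """One grown cell aggregate: a set of grid squares and its polygon."""

    label: str
    fov_id: object
    squares: frozenset[tuple[int, int]]
    grid: GridCounts
    polygon: BaseGeometry | None = None

    @property
    def n_squares(self) -> int:
        return len(self.squares)

    @property
    def area_um2(self) -> float:
        return len(self.squares) * self.grid.square_size_um ** 2


@dataclass
class InfiltrationArea:
    """Intersection of the tumor and CD3 aggregates of one FOV.

    ``infiltration_fraction`` = IA area / total tumor aggregate area;
    ``None`` when the FOV has no tumor aggregate.
    """

    fov_id: object
    polygon: BaseGeometry
    squares: frozenset[tuple[int, int]]
    area_um2: float
    tumor_area_um2: float
    cd3_area_um2: float
    grid: GridCounts

    @property
    def infiltration_fraction(self) -> float | None:
        if self.tumor_area_um2 == 0:
            return None
        return self.area_um2 / self.tumor_area_um2


def grid_counts(
    cells: CellTable,
    window: FOVWindow,
    cfg: CAAConfig,
    classes: Sequence[str],
) -> GridCounts:
    """Quadrat counts of each cell class over the FOV window.

    Binning is half-open ``[edge, next_edge)`` with the final row/column
    closed, so a cell on an interior edge falls in the right/upper square
    and cells on the window's far edge are not lost.  Cells outside the
    window raise :class:`DataError` (the window is the study area).
    """
    from .phenotype import class_mask

    sub = cells.for_fov(window.fov_id)
    s = cfg.square_size_um
    n_cols = max(1, math.ceil((window.width - 1e-12) / s))
    n_rows = max(1, math.ceil((window.height - 1e-12) / s))
    x_edges = window.x_min + s * np.arange(n_cols + 1)
    y_edges = window.y_min + s * np.arange(n_rows + 1)

    xy = sub.coords()
    if len(sub) and not window.contains(xy[:, 0], xy[:, 1]).all():
        raise DataError(f"cells outside window for FOV {window.fov_id!r}")

    counts: dict[str, np.ndarray] = {}
    for label in classes:
        m = class_mask(sub, label)
        pts = xy[m]
        if len(pts) == 0:
            counts[label] = np.zeros((n_rows, n_cols), dtype=int)
            continue
        # histogram2d: half-open bins, last bin closed — exactly the contract
        h, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=[y_edges, x_edges])
        # clip cells beyond the last edge (window wider than n*s) into last bin
        counts[label] = h.astype(int)
        beyond_x = pts[:, 0] > x_edges[-1]
        beyond_y = pts[:, 1] > y_edges[-1]
        if beyond_x.any() or beyond_y.any():  # pragma: no cover - edges cover window
            raise DataError("internal: grid edges do not cover window")
    return GridCounts(window.fov_id, float(window.x_min), float(window.y_min), s, n_rows, n_cols, counts)


def seed_squares(grid: GridCounts, label: str, cfg: CAAConfig) -> set[tuple[int, int]]:
    """Squares whose count is strictly above the ``seed_percentile`` quantile
    of the per-square count distribution (all squares, zeros included;
    linear-interpolation quantile)."""
    c = grid.counts[label]
    q = np.percentile(c.ravel(), cfg.seed_percentile)
    rows, cols = np.where(c > q)
    return {(int(r), int(ccol)) for r, ccol in zip(rows, cols)}


def resolve_cutoff(grid: GridCounts, label: str, cfg: CAAConfig) -> int | None:
    """Numeric growth cutoff; ``None`` when 'auto' finds no nonzero counts."""
    if cfg.growth_cutoff != "auto":
        return int(cfg.growth_cutoff)
    nz = grid.counts[label][grid.counts[label] > 0]
    if nz.size == 0:
        return None
    return int(np.median(nz))


def _neighbors(r: int, c: int, n_rows: int, n_cols: int, connectivity: int):
    if connectivity == 8:
        offs = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
    else:
        offs = ((-1, 0), (1, 0), (0, -1), (0, 1))
    for dr, dc in offs:
        rr, cc = r + dr, c + dc
        if 0 <= rr < n_rows and 0 <= cc < n_cols:
            yield rr, cc


def grow_aggregates(
    grid: GridCounts,
    label: str,
    seeds: Iterable[tuple[int, int]] | None = None,
    cfg: CAAConfig | None = None,
) -> list[Aggregate]:
    """Grow aggregates from seed squares by layer-wise absorption.

    From each seed, adjacent squares (4- or 8-connectivity) holding at least
    ``growth_cutoff`` cells are added, one layer at a time, until no adjacent
    square qualifies.  Seeds are always retained even when below the cutoff
    (they define the aggregate center).  Aggregates that meet are merged, so
    the result equals the connected components of
    ``{count >= cutoff} ∪ seeds`` that contain at least one seed — a set
    characterisation independent of seed processing order.
    """
    if cfg is None:
        cfg = CAAConfig()
    if seeds is None:
        seeds = seed_squares(grid, label, cfg)
    seeds = set(seeds)
    for r, c in seeds:
        if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
            raise DataError(f"seed {(r, c)} outside grid")
    cutoff = resolve_cutoff(grid, label, cfg)
    if cutoff is None:
        return []
    counts = grid.counts[label]
    eligible = counts >= cutoff

    visited: set[tuple[int, int]] = set()
    aggregates: list[Aggregate] = []
    for seed in sorted(seeds):
        if seed in visited:
            continue
        component = set()
        queue = deque([seed])
        visited.add(seed)
        while queue:
            r, c = queue.popleft()
            component.add((r, c))
            for rr, cc in _neighbors(r, c, grid.n_rows, grid.n_cols, cfg.connectivity):
                if (rr, cc) in visited:
                    continue
                if eligible[rr, cc] or (rr, cc) in seeds:
                    visited.add((rr, cc))
                    queue.append((rr, cc))
        aggregates.append(Aggregate(label=label, fov_id=grid.fov_id, squares=frozenset(component), grid=grid))
    return aggregates


def aggregates_to_polygons(aggs: Sequence[Aggregate]) -> list[Aggregate]:
    """Fill each aggregate's polygon with the planar union of its member
    squares (multi-part when squares touch only at corners or not at all).
    ``area_um2`` remains exactly ``n_squares × s²`` by construction."""
    for agg in aggs:
        boxes = [agg.grid.square_polygon(r, c) for r, c in sorted(agg.squares)]
        agg.polygon = unary_union(boxes) if boxes else shapely.Polygon()
    return list(aggs)


def delineate_aggregates(
    cells: CellTable,
    window: FOVWindow,
    cfg: CAAConfig,
    classes: Sequence[str],
) -> dict[str, list[Aggregate]]:
    """Full CAA for one FOV: grid → seeds → growth → polygons, per class."""
    grid = grid_counts(cells, window, cfg, classes)
    out: dict[str, list[Aggregate]] = {}
    for label in classes:
        aggs = grow_aggregates(grid, label, seed_squares(grid, label, cfg), cfg)
        out[label] = aggregates_to_polygons(aggs)
    return out


def _union_squares(aggs: Sequence[Aggregate]) -> frozenset[tuple[int, int]]:
    squares: set[tuple[int, int]] = set()
    for a in aggs:
        squares |= a.squares
    return frozenset(squares)


def infiltration_areas(
    tumor_aggs: Sequence[Aggregate],
    cd3_aggs: Sequence[Aggregate],
) -> InfiltrationArea:
    """Intersect the tumor and CD3 aggregate unions of one FOV into the IA.

    Both aggregate lists must come from the same FOV grid.  Areas are
    computed on the shared grid (square-set intersection), so
    ``IA area ≤ min(tumor area, CD3 area)`` holds exactly and the
    infiltration fraction is grid-exact.
    """
    aggs = list(tumor_aggs) + list(cd3_aggs)
    if not aggs:
        raise DataError("no aggregates supplied")
    grid = aggs[0].grid
    fovs = {a.fov_id for a in aggs}
    if len(fovs) != 1:
        raise DataError(f"aggregates from different FOVs: {sorted(map(repr, fovs))}")
    for a in aggs:
        if not grid.same_grid(a.grid):
            raise DataError("aggregates from mismatched grids")

    t_sq = _union_squares(tumor_aggs)
    c_sq = _union_squares(cd3_aggs)
    ia_sq = frozenset(t_sq & c_sq)
    s2 = grid.square_size_um ** 2
    boxes = [grid.square_polygon(r, c) for r, c in sorted(ia_sq)]
    poly = unary_union(boxes) if boxes else shapely.Polygon()
    return InfiltrationArea(
        fov_id=grid.fov_id,
        polygon=poly,
        squares=ia_sq,
        area_um2=len(ia_sq) * s2,
        tumor_area_um2=len(t_sq) * s2,
        cd3_area_um2=len(c_sq) * s2,
        grid=grid,
    )


def region_mask(cells: CellTable, polygon: BaseGeometry) -> np.ndarray:
    """Boundary-inclusive point-in-polygon mask for the cell centroids."""
    if polygon is None or polygon.is_empty:
        return np.zeros(len(cells), dtype=bool)
    pts = shapely.points(cells.coords())
    return shapely.covers(polygon, pts)


def cells_in_region(cells: CellTable, polygon: BaseGeometry) -> CellTable:
    """Cells whose centroid lies inside or on the boundary of ``polygon``.
    The complement (``cells.subset(~region_mask(...))``) gives the outside
    cells; together they partition the table."""
    return cells.subset(region_mask(cells, polygon))
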