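"""Planar land cover, streams, patches and geometric movement covariates.

Everything downstream (point-scale buffers, step-selection covariates,
connectivity, home-range metrics) is computed on a categorical raster of
forest / pasture / other-matrix cells in planar metric coordinates
(UTM-like; the ingest layer is responsible for any reprojection).

Grid convention: ``grid[row, col]`` with the origin ``(x0, y0)`` at the
lower-left corner of the raster, rows increasing with y.  The center of
cell ``(row, col)`` sits at ``(x0 + (col + 0.5) * res, y0 + (row + 0.5) * res)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, MultiLineString, Point

# land-cover class codes
FOREST = 1
PASTURE = 2
OTHER_MATRIX = 3
CLASS_CODES = (FOREST, PASTURE, OTHER_MATRIX)

#: grid cells per hectare conversion
M2_PER_HA = 1e4


class LandscapeError(ValueError):
    """Invalid geometry or land-cover input."""


class EmptyBufferError(LandscapeError):
    """A query buffer has no supporting cells inside the map extent."""


@dataclass(frozen=True)
class LandCoverMap:
    """Categorical land-cover grid in planar meters.

    Parameters
    ----------
    grid
        2-D integer array of class codes (FOREST / PASTURE / OTHER_MATRIX).
    resolution
        Cell edge length in meters (> 0).
    origin
        (x0, y0) of the lower-left map corner, meters.
    """

    grid: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.size == 0:
            raise LandscapeError("grid must be a non-empty 2-D array")
        if self.resolution <= 0:
            raise LandscapeError("resolution must be > 0")
        bad = ~np.isin(g, CLASS_CODES)
        if bad.any():
            codes = sorted(set(np.unique(g[bad]).tolist()))
            raise LandscapeError(f"unknown land-cover class codes: {codes}")
        object.__setattr__(self, "grid", np.ascontiguousarray(g, dtype=np.int8))

    # -- extent ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.grid.shape[0]

    @property
    def ncols(self) -> int:
        return self.grid.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.resolution, y0 + self.nrows * self.resolution)

    @property
    def landscape_area(self) -> float:
        """Total map area in m² (forest + matrix)."""
        return self.grid.size * self.resolution**2

    # -- coordinate <-> cell mapping ------------------------------------
    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        row, col = self._cells_of(np.asarray([x]), np.asarray([y]))
        if row[0] < 0:
            raise LandscapeError(f"point ({x}, {y}) outside map extent {self.bounds}")
        return int(row[0]), int(col[0])

    def _cells_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized point->cell lookup; (-1, -1) marks out-of-extent points."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x, float) - x0) / self.resolution).astype(np.int64)
        row = np.floor((np.asarray(y, float) - y0) / self.resolution).astype(np.int64)
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        row = np.where(ok, row, -1)
        col = np.where(ok, col, -1)
        return row, col

    def contains(self, x, y) -> np.ndarray | bool:
        row, _ = self._cells_of(np.atleast_1d(x), np.atleast_1d(y))
        ok = row >= 0
        return ok if np.ndim(x) else bool(ok[0])

    def class_at(self, x, y) -> np.ndarray | int:
        """Land-cover code at point(s); raises if any point is outside."""
        xs, ys = np.atleast_1d(x), np.atleast_1d(y)
        row, col = self._cells_of(xs, ys)
        if (row < 0).any():
            raise LandscapeError("query point outside map extent")
        vals = self.grid[row, col]
        return vals if np.ndim(x) else int(vals[0])

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.resolution, y0 + (row + 0.5) * self.resolution)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row) cell-center coordinates."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.resolution
        ys = y0 + (np.arange(self.nrows) + 0.5) * self.resolution
        return xs, ys

    def forest_fraction(self) -> float:
        return float(np.mean(self.grid == FOREST))


@dataclass(frozen=True)
class StreamNetwork:
    """Stream polylines in map coordinates (meters)."""

    polylines: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        lines = tuple(np.asarray(p, dtype=float) for p in self.polylines)
        if not lines:
            raise LandscapeError("stream network is empty")
        for p in lines:
            if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] != 2:
                raise LandscapeError("each polyline needs >= 2 (x, y) vertices")
        object.__setattr__(self, "polylines", lines)

    @cached_property
    def geometry(self) -> MultiLineString:
        return MultiLineString([LineString(p) for p in self.polylines])


@dataclass
class Patch:
    """A maximal connected set of forest cells.

    ``cells`` is an (n, 2) array of (row, col) indices; the boundary polygon
    (union of cell squares) is built lazily from shapely and only needed for
    vector output — edge-to-edge patch distances use the exact axis-aligned
    box formula on boundary cells instead.
    """

    id: int
    cells: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def n_cells(self) -> int:
        return int(self.cells.shape[0])

    @property
    def area(self) -> float:
        """Patch area, m²."""
        return self.n_cells * self.resolution**2

    @property
    def area_ha(self) -> float:
        return self.area / M2_PER_HA

    @cached_property
    def boundary_cells(self) -> np.ndarray:
        """Cells with at least one 4-neighbour outside the patch."""
        rows, cols = self.cells[:, 0], self.cells[:, 1]
        r0, c0 = rows.min(), cols.min()
        mask = np.zeros((rows.max() - r0 + 3, cols.max() - c0 + 3), dtype=bool)
        mask[rows - r0 + 1, cols - c0 + 1] = True
        interior = mask[:-2, 1:-1] & mask[2:, 1:-1] & mask[1:-1, :-2] & mask[1:-1, 2:]
        on_edge = ~interior[rows - r0, cols - c0]
        return self.cells[on_edge]

    @cached_property
    def boundary_centers(self) -> np.ndarray:
        """(n, 2) x/y centers of boundary cells."""
        x0, y0 = self.origin
        b = self.boundary_cells
        return np.column_stack(
            (x0 + (b[:, 1] + 0.5) * self.resolution, y0 + (b[:, 0] + 0.5) * self.resolution)
        )

    @cached_property
    def boundary(self) -> shapely.Geometry:
        """Outline polygon: union of the patch's cell squares."""
        x0, y0 = self.origin
        res = self.resolution
        xmin = x0 + self.cells[:, 1] * res
        ymin = y0 + self.cells[:, 0] * res
        boxes = shapely.box(xmin, ymin, xmin + res, ymin + res)
        return shapely.union_all(boxes)


def extract_patches(lcmap: LandCoverMap, connectivity: int = 8) -> list[Patch]:
    """Label maximal connected forest components.

    8-neighbour adjacency by default so one-cell-wide diagonal corridors are
    not split; pass ``connectivity=4`` for rook adjacency.
    """
    if connectivity not in (4, 8):
        raise LandscapeError("connectivity must be 4 or 8")
    structure = np.ones((3, 3)) if connectivity == 8 else None
    labels, n = ndimage.label(lcmap.grid == FOREST, structure=structure)
    patches = []
    for i, slc in enumerate(ndimage.find_objects(labels), start=1):
        rows, cols = np.nonzero(labels[slc] == i)
        cells = np.column_stack((rows + slc[0].start, cols + slc[1].start))
        patches.append(Patch(id=i, cells=cells, resolution=lcmap.resolution, origin=lcmap.origin))
    return patches


def patch_distance(p: Patch, q: Patch) -> float:
    """Minimum edge-to-edge distance between two patches' cell squares.

    For axis-aligned squares of edge ``res`` the pairwise square-to-square
    distance is ``hypot(max(0, |dx| - res), max(0, |dy| - res))`` on center
    offsets, and the minimum over boundary-cell pairs equals the distance
    between the patches' outline polygons exactly.
    """
    a, b = p.boundary_centers, q.boundary_centers
    res = p.resolution
    dx = np.abs(a[:, 0, None] - b[None, :, 0]) - res
    dy = np.abs(a[:, 1, None] - b[None, :, 1]) - res
    np.maximum(dx, 0.0, out=dx)
    np.maximum(dy, 0.0, out=dy)
    return float(np.sqrt(np.min(dx * dx + dy * dy)))


def class_fraction(
    lcmap: LandCoverMap, center: Sequence[float], radius: float, cls: int = FOREST
) -> float:
    """Fraction of class ``cls`` among cells whose centers lie within
    ``radius`` of ``center``; cells outside the map are excluded from the
    denominator."""
    if radius <= 0:
        raise LandscapeError("radius must be > 0")
    cx, cy = float(center[0]), float(center[1])
    res = lcmap.resolution
    x0, y0 = lcmap.origin
    c_lo = max(0, int(np.floor((cx - radius - x0) / res)))
    c_hi = min(lcmap.ncols, int(np.ceil((cx + radius - x0) / res)))
    r_lo = max(0, int(np.floor((cy - radius - y0) / res)))
    r_hi = min(lcmap.nrows, int(np.ceil((cy + radius - y0) / res)))
    if c_lo >= c_hi or r_lo >= r_hi:
        raise EmptyBufferError("buffer lies entirely outside the map extent")
    xs = x0 + (np.arange(c_lo, c_hi) + 0.5) * res
    ys = y0 + (np.arange(r_lo, r_hi) + 0.5) * res
    inside = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= radius**2
    n = int(inside.sum())
    if n == 0:
        raise EmptyBufferError("no cell centers within the buffer")
    window = lcmap.grid[r_lo:r_hi, c_lo:c_hi]
    return float(np.count_nonzero(window[inside] == cls) / n)


def distance_to_stream(streams: StreamNetwork, p: Sequence[float]) -> float:
    """Euclidean distance from ``p`` to the nearest stream segment, meters."""
    return float(streams.geometry.distance(Point(float(p[0]), float(p[1]))))


def distances_to_stream(streams: StreamNetwork, xy: np.ndarray) -> np.ndarray:
    """Vectorized :func:`distance_to_stream` for an (n, 2) point array."""
    pts = shapely.points(np.asarray(xy, dtype=float))
    return shapely.distance(pts, streams.geometry)


@dataclass(frozen=True)
class GapProfile:
    """Run-length land-cover profile along a directed movement step.

    A *gap* is a maximal run of non-forest cover crossed by the step.
    Lengths are in meters; ``pasture_prop_of_gap`` is the fraction of the
    total gap length lying in pasture (defined as 0 for gapless steps so
    interaction covariates stay well-defined).
    """

    segments: tuple[tuple[int, float], ...]
    length: float
    num_gaps: int = field(init=False)
    total_gap_length: float = field(init=False)
    mean_gap_size: float = field(init=False)
    prop_in_forest: float = field(init=False)
    pasture_prop_of_gap: float = field(init=False)

    def __post_init__(self) -> None:
        gaps: list[float] = []
        pasture_len = 0.0
        cur = 0.0
        for cls, seg_len in self.segments:
            if cls == FOREST:
                if cur > 0:
                    gaps.append(cur)
                    cur = 0.0
            else:
                cur += seg_len
                if cls == PASTURE:
                    pasture_len += seg_len
        if cur > 0:
            gaps.append(cur)
        total_gap = float(sum(gaps))
        object.__setattr__(self, "num_gaps", len(gaps))
        object.__setattr__(self, "total_gap_length", total_gap)
        object.__setattr__(self, "mean_gap_size", total_gap / len(gaps) if gaps else 0.0)
        object.__setattr__(self, "prop_in_forest", 1.0 - total_gap / self.length)
        object.__setattr__(
            self, "pasture_prop_of_gap", pasture_len / total_gap if total_gap > 0 else 0.0
        )


def _classes_along(
    lcmap: LandCoverMap, a: np.ndarray, b: np.ndarray, interval: float
) -> tuple[np.ndarray, float]:
    """Class codes at midpoint samples of equal slabs along a->b."""
    length = float(np.hypot(*(b - a)))
    n = max(1, int(np.ceil(length / interval)))
    ts = (np.arange(n) + 0.5) / n
    pts = a[None, :] + ts[:, None] * (b - a)[None, :]
    return lcmap.class_at(pts[:, 0], pts[:, 1]), length


def gap_profile(
    lcmap: LandCoverMap,
    a: Sequence[float],
    b: Sequence[float],
    interval: float | None = None,
) -> GapProfile:
    """Sample the segment a->b at a sub-cell interval (default resolution/4)
    and merge consecutive equal-class runs into a :class:`GapProfile`.

    Runs shorter than one cell are retained (no smoothing); reversing the
    step direction leaves all gap statistics unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.allclose(a, b):
        raise LandscapeError("gap profile requires two distinct endpoints")
    if interval is None:
        interval = lcmap.resolution / 4.0
    classes, length = _classes_along(lcmap, a, b, interval)
    slab = length / len(classes)
    change = np.flatnonzero(np.diff(classes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(classes)]))
    segments = tuple(
        (int(classes[s]), float((e - s) * slab)) for s, e in zip(starts, ends)
    )
    return GapProfile(segments=segments, length=length)


def step_forest_amount(
    lcmap: LandCoverMap, a: Sequence[float], b: Sequence[float], width: float = 30.0
) -> float:
    """Forest fraction inside the capsule of half-width ``width`` around the
    step a->b, by the cell-center-in-capsule rule.

    The capsule buffer width is not stated by the field protocol this
    emulates; 30 m is the package default and is configurable.
    """
    if width <= 0:
        raise LandscapeError("width must be > 0")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    capsule = LineString([a, b]).buffer(width) if not np.allclose(a, b) else Point(a).buffer(width)
    res = lcmap.resolution
    x0, y0 = lcmap.origin
    xmin, ymin, xmax, ymax = capsule.bounds
    c_lo = max(0, int(np.floor((xmin - x0) / res)))
    c_hi = min(lcmap.ncols, int(np.ceil((xmax - x0) / res)))
    r_lo = max(0, int(np.floor((ymin - y0) / res)))
    r_hi = min(lcmap.nrows, int(np.ceil((ymax - y0) / res)))
    if c_lo >= c_hi or r_lo >= r_hi:
        raise EmptyBufferError("step buffer lies entirely outside the map extent")
    xs = x0 + (np.arange(c_lo, c_hi) + 0.5) * res
    ys = y0 + (np.arange(r_lo, r_hi) + 0.5) * res
    X, Y = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(capsule, X.ravel(), Y.ravel()).reshape(X.shape)
    n = int(inside.sum())
    if n == 0:
        raise EmptyBufferError("no cell centers inside the step buffer")
    window = lcmap.grid[r_lo:r_hi, c_lo:c_hi]
    return float(np.count_nonzero(window[inside] == FOREST) / n)
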