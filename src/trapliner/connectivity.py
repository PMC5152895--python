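"""Landscape Coincidence Probability (CON) connectivity index.

CON measures the probability that two points dropped at random in a
landscape both fall in forest patches that are mutually reachable, with
reachability defined by a binary "passibility" rule: two patches are
passable (c_ij = 1) when their edge-to-edge distance does not exceed a
gap-crossing threshold (162 m by default, the maximum gap crossing
observed in the radio-tracking data this package analyses):

    CON = sum_i sum_j (a_i * a_j * c_ij / A_L^2) * 100

with patch areas a_i, total landscape area A_L, both orders of every pair
and the i = j diagonal included (c_ii = 1), so a single patch filling the
landscape scores exactly 100.

Two variants are provided: the literal pairwise double sum above (the
default), and a component variant in which c_ij = 1 whenever i and j lie
in the same connected component of the passibility graph (its transitive
closure); the component variant can only be larger.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import shapely

from .landscape import FOREST, LandCoverMap, LandscapeError, Patch, extract_patches, patch_distance

#: maximum observed gap-crossing distance, meters
DEFAULT_THRESHOLD = 162.0


@dataclass(frozen=True)
class ConnectivityInput:
    """Patch areas, passibility matrix and landscape area for CON."""

    areas: np.ndarray          # m², one per patch
    passibility: np.ndarray    # binary symmetric, unit diagonal
    landscape_area: float      # A_L, m²
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        a = np.asarray(self.areas, dtype=float)
        c = np.asarray(self.passibility, dtype=float)
        if self.landscape_area <= 0:
            raise LandscapeError("landscape area must be > 0")
        if a.ndim != 1 or (a <= 0).any():
            raise LandscapeError("patch areas must be positive")
        if c.shape != (a.size, a.size):
            raise LandscapeError("passibility matrix shape mismatch")
        if not np.array_equal(c, c.T) or not np.all(np.diag(c) == 1):
            raise LandscapeError("passibility must be symmetric with unit diagonal")
        if not np.isin(c, (0.0, 1.0)).all():
            raise LandscapeError("passibility entries must be 0 or 1")
        if a.sum() > self.landscape_area * (1 + 1e-9):
            raise LandscapeError("patch areas exceed landscape area")
        object.__setattr__(self, "areas", a)
        object.__setattr__(self, "passibility", c)


@dataclass(frozen=True)
class ConnectivityResult:
    con: float                 # pairwise CON, percent
    component_variant: float   # CON with c_ij via graph components, percent
    n_patches: int
    landscape_area: float


def passibility_matrix(patches: list[Patch], threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary passibility: 1 iff edge-to-edge patch distance <= threshold
    (inclusive — the threshold itself is an observed crossing), 1 on the
    diagonal."""
    if threshold < 0:
        raise LandscapeError("threshold must be >= 0")
    n = len(patches)
    c = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if patch_distance(patches[i], patches[j]) <= threshold:
                c[i, j] = c[j, i] = 1.0
    return c


def _component_matrix(c: np.ndarray) -> np.ndarray:
    g = nx.from_numpy_array(c)
    full = np.zeros_like(c)
    for comp in nx.connected_components(g):
        idx = np.fromiter(comp, dtype=int)
        full[np.ix_(idx, idx)] = 1.0
    return full


def con_index(inp: ConnectivityInput) -> ConnectivityResult:
    """Evaluate CON and its component variant for a patch mosaic."""
    a, c = inp.areas, inp.passibility
    if a.size == 0:
        return ConnectivityResult(0.0, 0.0, 0, inp.landscape_area)
    al2 = inp.landscape_area**2
    con = float(a @ c @ a / al2 * 100.0)
    comp = float(a @ _component_matrix(c) @ a / al2 * 100.0)
    return ConnectivityResult(con, comp, a.size, inp.landscape_area)


def con_for_map(
    lcmap: LandCoverMap,
    threshold: float = DEFAULT_THRESHOLD,
    patches: list[Patch] | None = None,
) -> ConnectivityResult:
    """CON over all forest patches of a map, A_L = full map area."""
    if patches is None:
        patches = extract_patches(lcmap)
    if not patches:
        return ConnectivityResult(0.0, 0.0, 0, lcmap.landscape_area)
    inp = ConnectivityInput(
        areas=np.array([p.area for p in patches]),
        passibility=passibility_matrix(patches, threshold),
        landscape_area=lcmap.landscape_area,
        threshold=threshold,
    )
    return con_index(inp)


def con_within_polygon(
    lcmap: LandCoverMap, polygon: shapely.Geometry, threshold: float = DEFAULT_THRESHOLD
) -> tuple[ConnectivityResult, float]:
    """CON restricted to a polygon (e.g. a home range): forest cells with
    centers covered by the polygon are re-labelled into clipped patches,
    A_L is the polygon area.

    A_L is measured on the same raster support as the patches (count of
    cells whose centers the polygon covers, times cell area) so that patch
    areas can never exceed it.

    Returns ``(result, mean_patch_size_ha)`` where mean patch size is the
    mean clipped patch area (0 when the polygon holds no forest).
    """
    from scipy import ndimage

    res = lcmap.resolution
    x0, y0 = lcmap.origin
    xmin, ymin, xmax, ymax = polygon.bounds
    c_lo = max(0, int(np.floor((xmin - x0) / res)))
    c_hi = min(lcmap.ncols, int(np.ceil((xmax - x0) / res)))
    r_lo = max(0, int(np.floor((ymin - y0) / res)))
    r_hi = min(lcmap.nrows, int(np.ceil((ymax - y0) / res)))
    if c_lo >= c_hi or r_lo >= r_hi:
        return ConnectivityResult(0.0, 0.0, 0, float(polygon.area)), 0.0
    xs = x0 + (np.arange(c_lo, c_hi) + 0.5) * res
    ys = y0 + (np.arange(r_lo, r_hi) + 0.5) * res
    X, Y = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(polygon, X.ravel(), Y.ravel()).reshape(X.shape)
    window = lcmap.grid[r_lo:r_hi, c_lo:c_hi]
    mask = inside & (window == FOREST)
    a_l = float(inside.sum()) * res**2
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0 or a_l == 0.0:
        return ConnectivityResult(0.0, 0.0, 0, a_l or float(polygon.area)), 0.0
    origin = (x0 + c_lo * res, y0 + r_lo * res)
    patches = []
    for i, slc in enumerate(ndimage.find_objects(labels), start=1):
        rows, cols = np.nonzero(labels[slc] == i)
        cells = np.column_stack((rows + slc[0].start, cols + slc[1].start))
        patches.append(Patch(id=i, cells=cells, resolution=res, origin=origin))
    inp = ConnectivityInput(
        areas=np.array([p.area for p in patches]),
        passibility=passibility_matrix(patches, threshold),
        landscape_area=a_l,
        threshold=threshold,
    )
    mps_ha = float(np.mean([p.area_ha for p in patches]))
    return con_index(inp), mps_ha
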