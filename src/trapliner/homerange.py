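"""Home-range-scale selection: LoCoH estimation and a rotation null model.

The home range is the 95% isopleth of a Local Convex Hull (LoCoH, k-method)
estimator: for every fix, the convex hull of the fix and its k-1 nearest
neighbours is built; hulls are accumulated from smallest to largest until
the union covers 95% of the fixes.  LoCoH respects sharp boundaries in
habitat use (e.g. a forest/pasture edge), unlike kernel estimators.

Availability at the home-range scale is simulated by rotating the observed
isopleth polygon about its centroid in 1-degree increments (359 rotated
alternatives per bird) and re-measuring forest cover, connectivity (CON)
and mean patch size inside each rotation.  Observed-vs-available forest is
compared by a paired Wilcoxon signed-rank test; the connectivity contrast
is additionally repeated on the subset of rotations with forest cover
within +/- 5 percentage points of observed, which removes the confounding
of connectivity with forest amount.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.spatial import cKDTree
from shapely import affinity
from shapely.geometry import MultiPoint

from .connectivity import DEFAULT_THRESHOLD, con_within_polygon
from .landscape import FOREST, M2_PER_HA, LandCoverMap

__all__ = [
    "HomeRange",
    "locoh_k",
    "RotationNull",
    "rotation_null",
    "wilcoxon_signed_rank",
    "matched_availability_test",
    "hr_size_regression",
]


@dataclass
class HomeRange:
    """A LoCoH isopleth polygon set for one bird."""

    bird_id: object
    isopleth: float
    polygon: shapely.Geometry          # Polygon or MultiPolygon
    k: int
    n_points: int

    @property
    def area_ha(self) -> float:
        return float(self.polygon.area) / M2_PER_HA

    @property
    def center(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    @property
    def hr_length(self) -> float:
        """Maximum vertex-to-vertex distance of the polygon set, m."""
        coords = _polygon_vertices(self.polygon)
        hull = MultiPoint(coords).convex_hull
        pts = np.asarray(hull.exterior.coords) if hull.geom_type == "Polygon" else np.asarray(coords)
        d = 0.0
        for i, j in itertools.combinations(range(len(pts)), 2):
            d = max(d, math.hypot(*(pts[i] - pts[j])))
        return d


def _polygon_vertices(geom: shapely.Geometry) -> np.ndarray:
    parts = geom.geoms if hasattr(geom, "geoms") else [geom]
    coords = []
    for p in parts:
        coords.append(np.asarray(p.exterior.coords))
    return np.vstack(coords)


def locoh_k(
    points: np.ndarray,
    k: int | None = None,
    isopleth: float = 0.95,
    bird_id: object = None,
    jitter_seed: int = 0,
) -> HomeRange:
    """k-method LoCoH home range.

    ``k`` defaults to ceil(sqrt(n)), a common heuristic when the field
    protocol does not state one.  Duplicate points (which collapse hulls to
    zero area and break nearest-neighbour ties) are resolved by a
    micrometer-scale deterministic jitter.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if k is None:
        k = max(3, math.ceil(math.sqrt(n)))
    if not 3 <= k <= n:
        raise ValueError(f"need n >= k >= 3 (n={n}, k={k})")
    if not 0 < isopleth <= 1:
        raise ValueError("isopleth must be in (0, 1]")
    if len(np.unique(pts, axis=0)) < n:
        rng = np.random.default_rng(jitter_seed)
        pts = pts + rng.normal(scale=1e-6, size=pts.shape)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    hulls = [MultiPoint(pts[idx[i]]).convex_hull for i in range(n)]
    order = np.argsort([h.area for h in hulls], kind="stable")
    target = math.ceil(isopleth * n)
    covered = np.zeros(n, dtype=bool)
    union_parts: list[shapely.Geometry] = []
    for i in order:
        union_parts.append(hulls[i])
        newly = shapely.covers(hulls[i], shapely.points(pts[~covered]))
        covered[np.flatnonzero(~covered)[newly]] = True
        if covered.sum() >= target:
            break
    union = shapely.union_all(union_parts)
    return HomeRange(bird_id=bird_id, isopleth=isopleth, polygon=union, k=k, n_points=n)


# ---------------------------------------------------------------------------
# rotation null model
# ---------------------------------------------------------------------------

@dataclass
class RotationNull:
    """Observed vs rotated landscape metrics for one bird's home range."""

    bird_id: object
    observed: pd.Series                  # forest_pct, con, mps_ha at 0 degrees
    rotated: pd.DataFrame                # one row per angle
    excluded_angles: int

    @property
    def all_forest(self) -> bool:
        """Observed and every rotated alternative fully forested."""
        return bool(
            self.observed["forest_pct"] >= 100.0 - 1e-9
            and (self.rotated["forest_pct"] >= 100.0 - 1e-9).all()
        )


def _polygon_forest_pct(lcmap: LandCoverMap, polygon: shapely.Geometry) -> float | None:
    res = lcmap.resolution
    x0, y0 = lcmap.origin
    xmin, ymin, xmax, ymax = polygon.bounds
    c_lo = max(0, int(np.floor((xmin - x0) / res)))
    c_hi = min(lcmap.ncols, int(np.ceil((xmax - x0) / res)))
    r_lo = max(0, int(np.floor((ymin - y0) / res)))
    r_hi = min(lcmap.nrows, int(np.ceil((ymax - y0) / res)))
    if c_lo >= c_hi or r_lo >= r_hi:
        return None
    xs = x0 + (np.arange(c_lo, c_hi) + 0.5) * res
    ys = y0 + (np.arange(r_lo, r_hi) + 0.5) * res
    X, Y = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(polygon, X.ravel(), Y.ravel()).reshape(X.shape)
    n = int(inside.sum())
    if n == 0:
        return None
    window = lcmap.grid[r_lo:r_hi, c_lo:c_hi]
    return 100.0 * float(np.count_nonzero(window[inside] == FOREST)) / n


def _within_map(lcmap: LandCoverMap, polygon: shapely.Geometry) -> bool:
    xmin, ymin, xmax, ymax = polygon.bounds
    bx0, by0, bx1, by1 = lcmap.bounds
    return xmin >= bx0 and ymin >= by0 and xmax <= bx1 and ymax <= by1


def rotation_null(
    hr: HomeRange,
    lcmap: LandCoverMap,
    threshold: float = DEFAULT_THRESHOLD,
    angle_step: float = 1.0,
    area_rtol: float = 1e-9,
) -> RotationNull:
    """Rotate the home-range polygon about its centroid through 1-degree
    steps (359 alternatives by default) and measure forest %, CON and mean
    patch size inside each rotation.

    Rotations extending beyond the map are excluded (counted); rotation is
    verified to preserve polygon area to ``area_rtol`` relative error.
    """
    center = hr.center
    base_area = hr.polygon.area

    def metrics(poly) -> dict | None:
        fp = _polygon_forest_pct(lcmap, poly)
        if fp is None:
            return None
        conres, mps = con_within_polygon(lcmap, poly, threshold)
        return {"forest_pct": fp, "con": conres.con, "mps_ha": mps}

    obs = metrics(hr.polygon)
    if obs is None or not _within_map(lcmap, hr.polygon):
        raise ValueError("observed home range is not covered by the map")
    angles = np.arange(angle_step, 360.0, angle_step)
    rows = []
    excluded = 0
    for ang in angles:
        poly = affinity.rotate(hr.polygon, ang, origin=center)
        if abs(poly.area - base_area) > area_rtol * base_area:
            raise AssertionError(f"rotation by {ang} deg changed polygon area")
        if not _within_map(lcmap, poly):
            excluded += 1
            continue
        m = metrics(poly)
        if m is None:
            excluded += 1
            continue
        rows.append({"angle": ang, **m})
    return RotationNull(
        bird_id=hr.bird_id,
        observed=pd.Series(obs),
        rotated=pd.DataFrame(rows),
        excluded_angles=excluded,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    observed: np.ndarray,
    alternative_means: np.ndarray,
    alternative: str = "two-sided",
    exact_max_n: int = 15,
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test.

    V is the sum of the ranks (of |d|, average ranks for ties) of the
    positive differences, zero differences dropped.  P is exact (full 2^n
    enumeration of sign patterns, respecting the observed tie structure)
    for n <= ``exact_max_n``, otherwise a normal approximation with tie and
    continuity corrections.

    Returns ``(V, P)``.
    """
    d = np.asarray(observed, float) - np.asarray(alternative_means, float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; test degenerate")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided, greater or less")

    if n <= exact_max_n:
        # exact null distribution of V over all sign assignments
        vs = np.zeros(1)
        for r in ranks:
            vs = np.concatenate((vs, vs + r))
        if alternative == "greater":
            p = float(np.mean(vs >= v - 1e-12))
        elif alternative == "less":
            p = float(np.mean(vs <= v + 1e-12))
        else:
            p = float(min(1.0, 2.0 * min(np.mean(vs >= v - 1e-12), np.mean(vs <= v + 1e-12))))
        return v, p

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = float(np.sum(counts**3 - counts)) / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    if alternative == "greater":
        z = (v - mu - 0.5) / sigma
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        z = (v - mu + 0.5) / sigma
        p = float(stats.norm.cdf(z))
    else:
        z = (v - mu - math.copysign(0.5, v - mu)) / sigma if v != mu else 0.0
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return v, p


# ---------------------------------------------------------------------------
# matched-availability connectivity contrast
# ---------------------------------------------------------------------------

@dataclass
class AvailabilityTestResult:
    t: float
    p: float
    df: int
    n_birds: int
    excluded_birds: tuple
    mean_difference: float      # observed CON minus mean available CON
    restricted: bool
    tolerance: float | None


def matched_availability_test(
    nulls: list[RotationNull],
    tolerance: float | None = 5.0,
    metric: str = "con",
    exclude_all_forest: bool = True,
) -> AvailabilityTestResult:
    """Paired t-test of observed vs mean available connectivity across birds.

    With ``tolerance`` set (percentage points, absolute), only rotated
    alternatives whose forest cover is within that band of the observed
    cover count as available — the forest-matched version of the contrast.
    ``tolerance=None`` uses every rotation.  Birds with no qualifying
    rotation (or, optionally, fully forested everywhere) are excluded.
    """
    obs_vals, avail_vals, excluded = [], [], []
    for nl in nulls:
        if exclude_all_forest and nl.all_forest:
            excluded.append(nl.bird_id)
            continue
        rot = nl.rotated
        if tolerance is not None:
            ok = (rot["forest_pct"] - nl.observed["forest_pct"]).abs() <= tolerance
            rot = rot[ok]
        if rot.empty:
            excluded.append(nl.bird_id)
            continue
        obs_vals.append(nl.observed[metric])
        avail_vals.append(rot[metric].mean())
    n = len(obs_vals)
    if n < 2:
        raise ValueError("fewer than 2 birds with usable availability sets")
    t, p = stats.ttest_rel(obs_vals, avail_vals)
    return AvailabilityTestResult(
        t=float(t),
        p=float(p),
        df=n - 1,
        n_birds=n,
        excluded_birds=tuple(excluded),
        mean_difference=float(np.mean(np.array(obs_vals) - np.array(avail_vals))),
        restricted=tolerance is not None,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# home-range size regression
# ---------------------------------------------------------------------------

def hr_size_regression(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """log(home-range area) regressed on forest %, mean patch size and sex.

    ``records`` columns: hr_area_ha, forest_pct, mps_ha, sex.  Returns the
    full three-predictor OLS fit plus each univariate fit, as tidy tables
    of coef / se / t / p.  A warning is attached when the full-model design
    is ill-conditioned.
    """
    import statsmodels.api as sm

    if len(records) < 5:
        raise ValueError("need at least 5 home ranges")
    y = np.log(records["hr_area_ha"].to_numpy(float))
    df = records.copy()
    df["sex"] = pd.factorize(df["sex"])[0].astype(float)
    preds = ["forest_pct", "mps_ha", "sex"]

    def tidy(fit, names):
        return pd.DataFrame(
            {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues},
            index=names,
        )

    out: dict[str, pd.DataFrame] = {}
    X = sm.add_constant(df[preds].to_numpy(float))
    full = sm.OLS(y, X).fit()
    if np.linalg.cond(X) > 1e8:
        import warnings

        warnings.warn("ill-conditioned design in home-range size regression")
    out["full"] = tidy(full, ["intercept", *preds])
    for p_ in preds:
        Xu = sm.add_constant(df[[p_]].to_numpy(float))
        out[p_] = tidy(sm.OLS(y, Xu).fit(), ["intercept", p_])
    return out
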