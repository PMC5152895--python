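"""Point-scale habitat selection.

Two analyses run at the scale of individual telemetry fixes:

1. *Forest dependency* — the difference between forest cover used (30-m
   buffer around each fix) and forest cover available (500-m buffer) is
   regressed on total available forest, with a per-bird random intercept
   and a spatially correlated residual (exponential, gaussian, spherical
   or rational-quadratic correlation by distance), estimated by REML.
   A Moran's I correlogram of residuals diagnoses leftover spatial
   autocorrelation.

2. *Resource availability and canopy cover* — each used vegetation plot is
   matched to a random plot within 500 m; a matched-pair conditional
   logistic regression estimates the odds of use per flowering plant and
   per percent canopy cover.  With 1:1 matching the conditional likelihood
   absorbs both the pair and the individual intercepts exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.spatial.distance import pdist, squareform

from .landscape import FOREST, LandCoverMap, class_fraction

__all__ = [
    "DISTANCE_CLASSES",
    "filter_and_dedupe",
    "build_point_records",
    "GLSFit",
    "fit_gls_spatial",
    "CORRELATION_STRUCTURES",
    "morans_correlogram",
    "PairedLogisticFit",
    "fit_paired_logistic",
    "plot_area_ha",
    "plants_per_ha",
]

#: observer-distance classes; fixes recorded from > 30 m are discarded
DISTANCE_CLASSES = ("0-10", "11-20", "21-30", ">30")

USED_BUFFER_M = 30.0
AVAILABLE_BUFFER_M = 500.0
MIN_SEPARATION_M = 1.0


# ---------------------------------------------------------------------------
# fix filtering
# ---------------------------------------------------------------------------

def filter_and_dedupe(
    fixes: pd.DataFrame, min_separation: float = MIN_SEPARATION_M
) -> pd.DataFrame:
    """Drop fixes observed from beyond 30 m, then thin near-duplicates.

    Deduplication is sequential per bird in time order: a fix is dropped
    when it lies within ``min_separation`` of the previously *retained*
    fix, so stationary bursts collapse to one record.
    """
    df = fixes.copy()
    bad = ~df["obs_dist_class"].isin(DISTANCE_CLASSES)
    if bad.any():
        raise ValueError(
            f"unknown observer-distance classes: {sorted(df.loc[bad, 'obs_dist_class'].unique())}"
        )
    df = df[df["obs_dist_class"] != ">30"]
    df = df.sort_values(["bird_id", "timestamp"], kind="mergesort")
    keep_idx: list = []
    for _, sub in df.groupby("bird_id", sort=False):
        xs = sub["x"].to_numpy(float)
        ys = sub["y"].to_numpy(float)
        last = 0
        keep_idx.append(sub.index[0])
        for i in range(1, len(sub)):
            if np.hypot(xs[i] - xs[last], ys[i] - ys[last]) > min_separation:
                keep_idx.append(sub.index[i])
                last = i
    return df.loc[keep_idx]


def remove_far_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Only the observer-distance filter (no deduplication)."""
    return fixes[fixes["obs_dist_class"] != ">30"]


# ---------------------------------------------------------------------------
# used / available records
# ---------------------------------------------------------------------------

def build_point_records(
    fixes: pd.DataFrame,
    lcmap: LandCoverMap,
    used_radius: float = USED_BUFFER_M,
    available_radius: float = AVAILABLE_BUFFER_M,
) -> pd.DataFrame:
    """Per-fix used-vs-available forest record.

    ``difference`` = 100 * (forest fraction within the used buffer − forest
    fraction within the available buffer), percentage points;
    ``total_forest`` = 100 * available-buffer forest fraction.
    """
    rows = []
    for fix in fixes.itertuples(index=False):
        p = (fix.x, fix.y)
        used = class_fraction(lcmap, p, used_radius, FOREST)
        avail = class_fraction(lcmap, p, available_radius, FOREST)
        rows.append(
            {
                "bird_id": fix.bird_id,
                "x": fix.x,
                "y": fix.y,
                "difference": 100.0 * (used - avail),
                "total_forest": 100.0 * avail,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GLS with spatial correlation structures (REML)
# ---------------------------------------------------------------------------

def _corr_exponential(d, rho):
    return np.exp(-d / rho)


def _corr_gaussian(d, rho):
    return np.exp(-((d / rho) ** 2))


def _corr_spherical(d, rho):
    r = np.clip(d / rho, 0.0, 1.0)
    return np.where(d < rho, 1.0 - 1.5 * r + 0.5 * r**3, 0.0)


def _corr_rational_quadratic(d, rho):
    return 1.0 / (1.0 + (d / rho) ** 2)


CORRELATION_STRUCTURES = {
    "exponential": _corr_exponential,
    "gaussian": _corr_gaussian,
    "spherical": _corr_spherical,
    "rational_quadratic": _corr_rational_quadratic,
    "none": None,
}


@dataclass
class GLSFit:
    """REML fit of difference ~ total_forest with bird random intercept and
    a spatial residual correlation structure."""

    structure: str
    params: pd.DataFrame          # coef, se, ci_low, ci_high per term
    sigma2: float                 # residual variance
    sigma2_bird: float            # random-intercept variance
    rho: float | None             # correlation range, m (None for "none")
    loglik: float                 # restricted log-likelihood
    aicc: float
    n_obs: int
    residuals: np.ndarray = field(repr=False, default=None)
    converged: bool = True

    @property
    def slope(self) -> float:
        return float(self.params.loc["total_forest", "coef"])

    @property
    def slope_se(self) -> float:
        return float(self.params.loc["total_forest", "se"])


def _reml_neg_loglik(theta, y, X, dists, bird_blocks, corr_fn):
    n, p = X.shape
    if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 40.0:
        return 1e10
    log_s2, log_s2b = theta[0], theta[1]
    V = np.exp(log_s2b) * bird_blocks
    if corr_fn is not None:
        rho = np.exp(theta[2])
        V = V + np.exp(log_s2) * corr_fn(dists, rho)
    else:
        V = V + np.exp(log_s2) * np.eye(n)
    # small ridge keeps V factorizable when variance components collapse
    V[np.diag_indices(n)] += 1e-8 * (np.exp(log_s2) + np.exp(log_s2b))
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return 1e10
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    try:
        beta = linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    except linalg.LinAlgError:
        return 1e10
    r = yw - Xw @ beta
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    if sign <= 0:
        return 1e10
    return 0.5 * (logdet_V + logdet_XtX + float(r @ r))


def fit_gls_spatial(
    records: pd.DataFrame,
    structure: str = "rational_quadratic",
    response: str = "difference",
    predictor: str = "total_forest",
) -> GLSFit:
    """REML fit of ``response ~ 1 + predictor`` with per-bird random
    intercept and residual correlation ``Corr(d)`` given by ``structure``.

    AICc counts fixed effects plus variance parameters and is comparable
    across structures fitted to the same records.
    """
    if structure not in CORRELATION_STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; choose from {sorted(CORRELATION_STRUCTURES)}")
    corr_fn = CORRELATION_STRUCTURES[structure]
    y = records[response].to_numpy(float)
    x = records[predictor].to_numpy(float)
    coords = records[["x", "y"]].to_numpy(float)
    n = len(y)
    if n < 3 or len(np.unique(coords, axis=0)) < 3:
        raise ValueError("need at least 3 distinct locations")
    if np.ptp(x) == 0:
        raise ValueError(f"singular design: {predictor} is constant")
    X = np.column_stack((np.ones(n), x))
    dists = squareform(pdist(coords))
    birds = records["bird_id"].to_numpy()
    bird_blocks = (birds[:, None] == birds[None, :]).astype(float)

    # degenerate response: GLS estimates are exactly zero for any V
    if np.allclose(y, 0.0):
        params = pd.DataFrame(
            {"coef": [0.0, 0.0], "se": [0.0, 0.0], "ci_low": [0.0, 0.0], "ci_high": [0.0, 0.0]},
            index=["intercept", predictor],
        )
        return GLSFit(structure, params, 0.0, 0.0, None, np.nan, np.nan, n, np.zeros(n))

    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_var = max(float(np.var(y - X @ ols_beta)), 1e-8)
    med_d = float(np.median(dists[dists > 0])) if (dists > 0).any() else 1.0
    starts = [np.log([0.8 * resid_var, 0.2 * resid_var])]
    if corr_fn is not None:
        starts = [
            np.concatenate((starts[0], [np.log(r)])) for r in (med_d / 4, med_d, med_d * 2)
        ]
    best = None
    for s0 in starts:
        res = optimize.minimize(
            _reml_neg_loglik,
            s0,
            args=(y, X, dists, bird_blocks, corr_fn),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    sigma2, sigma2_bird = float(np.exp(theta[0])), float(np.exp(theta[1]))
    rho = float(np.exp(theta[2])) if corr_fn is not None else None

    V = sigma2_bird * bird_blocks
    V = V + sigma2 * (corr_fn(dists, rho) if corr_fn is not None else np.eye(n))
    V[np.diag_indices(n)] += 1e-8 * (sigma2 + sigma2_bird)
    L = linalg.cholesky(V, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    cov_beta = linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    const = -0.5 * (n - X.shape[1]) * np.log(2 * np.pi)
    loglik = -best.fun + const
    k = X.shape[1] + len(theta)
    aicc = -2 * loglik + 2 * k + 2 * k * (k + 1) / max(n - k - 1, 1)
    params = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "ci_low": beta - 1.96 * se,
            "ci_high": beta + 1.96 * se,
        },
        index=["intercept", predictor],
    )
    return GLSFit(
        structure=structure,
        params=params,
        sigma2=sigma2,
        sigma2_bird=sigma2_bird,
        rho=rho,
        loglik=float(loglik),
        aicc=float(aicc),
        n_obs=n,
        residuals=y - X @ beta,
        converged=bool(best.success),
    )


def compare_gls_structures(
    records: pd.DataFrame, structures: tuple[str, ...] = tuple(CORRELATION_STRUCTURES)
) -> pd.DataFrame:
    """Fit every requested structure and rank by AICc (best first)."""
    fits = {s: fit_gls_spatial(records, s) for s in structures}
    tab = pd.DataFrame(
        {
            "structure": list(fits),
            "aicc": [f.aicc for f in fits.values()],
            "loglik": [f.loglik for f in fits.values()],
            "slope": [f.slope for f in fits.values()],
            "slope_se": [f.slope_se for f in fits.values()],
        }
    ).sort_values("aicc", kind="mergesort")
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    return tab.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Moran's I correlogram
# ---------------------------------------------------------------------------

#: |I| above this in any bin is flagged as residual spatial autocorrelation
MORAN_WARN_THRESHOLD = 0.1


@dataclass(frozen=True)
class CorrelogramResult:
    bin_centers: np.ndarray
    morans_i: np.ndarray
    bin_counts: np.ndarray

    @property
    def autocorrelated(self) -> bool:
        return bool(np.any(np.abs(self.morans_i) > MORAN_WARN_THRESHOLD))


def morans_correlogram(
    values: np.ndarray,
    coords: np.ndarray,
    n_bins: int = 10,
    max_dist: float | None = None,
) -> CorrelogramResult:
    """Moran's I per distance bin with row-standardized binary weights.

    Bins span (0, max_dist] with max_dist defaulting to half the maximum
    pairwise distance; empty bins are dropped with a warning.
    """
    z = np.asarray(values, float)
    coords = np.asarray(coords, float)
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 points for a correlogram")
    z = z - z.mean()
    denom = float(z @ z)
    d = squareform(pdist(coords))
    if max_dist is None:
        max_dist = d.max() / 2.0
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    centers, eyes, counts = [], [], []
    off_diag = ~np.eye(n, dtype=bool)
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = ((d > lo) & (d <= hi) & off_diag).astype(float)
        npairs = int(w.sum())
        if npairs == 0:
            warnings.warn(f"empty correlogram bin ({lo:.0f}, {hi:.0f}] m omitted")
            continue
        rs = w.sum(axis=1)
        w[rs > 0] /= rs[rs > 0, None]
        s0 = w.sum()
        eyes.append(n / s0 * float(z @ w @ z) / denom)
        centers.append((lo + hi) / 2.0)
        counts.append(npairs)
    return CorrelogramResult(np.array(centers), np.array(eyes), np.array(counts))


# ---------------------------------------------------------------------------
# matched-pair conditional logistic regression
# ---------------------------------------------------------------------------

def plot_area_ha(radius_m: float = 20.0) -> float:
    """Area of a circular vegetation plot, hectares."""
    return float(np.pi * radius_m**2 / 1e4)


def plants_per_ha(n_plants: float, radius_m: float = 20.0) -> float:
    """Convert a per-plot plant count to a density per hectare."""
    return float(n_plants / plot_area_ha(radius_m))


@dataclass
class PairedLogisticFit:
    """Conditional (matched-pair) logistic fit.

    ``status`` is "ok", "separation" (a covariate perfectly discriminates
    used from random plots — the MLE diverges) or "degenerate" (covariates
    identical within every pair — the likelihood is flat).
    """

    params: pd.DataFrame     # coef, se, or, ci_low, ci_high, std_coef per covariate
    loglik: float
    n_pairs: int
    status: str = "ok"

    def odds_ratio(self, name: str) -> float:
        return float(self.params.loc[name, "or"])


def fit_paired_logistic(
    pairs: pd.DataFrame,
    covariates: tuple[str, ...] = ("heliconia_n", "canopy_pct"),
    max_iter: int = 100,
    tol: float = 1e-10,
) -> PairedLogisticFit:
    """Maximize the 1:1 matched-pair conditional logistic likelihood

        l(beta) = sum_pairs [beta.x_used - log(exp(beta.x_used) + exp(beta.x_rand))]

    which depends on the data only through within-pair covariate
    differences, so pair and individual intercepts drop out exactly.

    ``pairs`` is long-format with columns pair_id, role ("used"/"random")
    and the covariates.  Standardized coefficients are beta * SD(x) with
    the SD taken over all plots.
    """
    used = pairs[pairs["role"] == "used"].set_index("pair_id")
    rand = pairs[pairs["role"] == "random"].set_index("pair_id")
    if not used.index.sort_values().equals(rand.index.sort_values()):
        raise ValueError("each pair needs exactly one used and one random plot")
    rand = rand.loc[used.index]
    D = used[list(covariates)].to_numpy(float) - rand[list(covariates)].to_numpy(float)
    n, k = D.shape
    sds = pairs[list(covariates)].std(ddof=1).to_numpy(float)

    def make_params(beta, se):
        return pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "or": np.exp(beta),
                "ci_low": np.exp(beta - 1.96 * se),
                "ci_high": np.exp(beta + 1.96 * se),
                "std_coef": beta * sds,
            },
            index=list(covariates),
        )

    if np.allclose(D, 0.0):
        return PairedLogisticFit(
            make_params(np.full(k, np.nan), np.full(k, np.nan)),
            loglik=float(-n * np.log(2.0)),
            n_pairs=n,
            status="degenerate",
        )

    beta = np.zeros(k)
    status = "ok"
    d_scale = np.maximum(np.std(D, axis=0), 1e-12)
    for _ in range(max_iter):
        eta = D @ beta
        p = 1.0 / (1.0 + np.exp(-eta))          # P(observed choice | pair)
        if np.all(p > 1.0 - 1e-8):              # perfect concordance: MLE diverges
            status = "separation"
            break
        grad = D.T @ (1.0 - p)
        W = p * (1.0 - p)
        H = (D * W[:, None]).T @ D
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            status = "separation" if np.min(p) > 0.5 else "degenerate"
            break
        beta = beta + step
        if np.max(np.abs(beta) * d_scale) > 50.0:   # diverging on the difference scale
            status = "separation"
            break
        if np.max(np.abs(step)) < tol:
            break
    eta = D @ beta
    loglik = float(-np.sum(np.log1p(np.exp(-eta))))
    if status != "ok":
        return PairedLogisticFit(
            make_params(np.full(k, np.nan), np.full(k, np.nan)), loglik, n, status
        )
    p = 1.0 / (1.0 + np.exp(-eta))
    H = (D * (p * (1 - p))[:, None]).T @ D
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return PairedLogisticFit(make_params(beta, se), loglik, n, status)
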