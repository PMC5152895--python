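"""Step-selection-function (SSF) pipeline.

An observed movement *step* (the straight line between consecutively
visited points, after resampling the fix stream to >= 10 m and <= 15 min)
is matched with 20 random alternative steps sharing its origin, drawn
from the leave-one-out empirical step-length and turning-angle pools of
the remaining birds and constrained to end in forest.  Each matched set
(*stratum*) enters a conditional logistic regression

    l(beta) = sum_strata [ beta.x_used - log sum_{j in stratum} exp(beta.x_j) ]

whose coefficients quantify selection for (or against) gap-exposure and
stream-proximity covariates.  Candidate models are ranked by AICc, and a
second-stage OLS regresses per-bird coefficients on landscape context
(forest amount, connectivity) and sex.

Covariates per step (names follow field usage):

========== ==================================================================
TotGap     total gap (non-forest) length crossed by the step, m
MeanGap    mean gap size, m (0 when no gap)
NumGap     number of gaps crossed
PropInFor  proportion of the step length in forest
ForAm      forest fraction inside a capsule buffer around the step
Stream     distance from the step destination to the nearest stream, m
Pasture    proportion of the total gap length lying in pasture
========== ==================================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landscape import (
    FOREST,
    LandCoverMap,
    StreamNetwork,
    distances_to_stream,
    gap_profile,
    step_forest_amount,
)

__all__ = [
    "Step",
    "resample_to_steps",
    "EmpiricalMoveDistributions",
    "loo_distributions",
    "generate_random_steps",
    "StratumDropped",
    "build_strata",
    "MODEL_REGISTRY",
    "assemble_design",
    "SSFFit",
    "fit_conditional_logit",
    "rank_models",
    "second_stage",
    "odds_ratio",
    "wald_ci",
    "aicc",
]

MIN_STEP_DIST_M = 10.0
MAX_STEP_DT_MIN = 15.0
N_RANDOM_STEPS = 20
REJECTION_CAP = 10_000

COVARIATES = ("TotGap", "MeanGap", "NumGap", "PropInFor", "ForAm", "Stream", "Pasture")


# ---------------------------------------------------------------------------
# reported-coefficient arithmetic
# ---------------------------------------------------------------------------

def odds_ratio(coef: float) -> float:
    """OR = exp(beta)."""
    return float(np.exp(coef))


def wald_ci(coef: float, se: float, z: float = 1.96) -> tuple[float, float]:
    """Symmetric 95% Wald interval (beta -/+ 1.96 SE)."""
    return (coef - z * se, coef + z * se)


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1), n = number of strata."""
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# steps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Step:
    """A directed movement segment; ``turn`` is relative to the previous
    step's heading and NaN at bout starts."""

    bird_id: object
    origin: tuple[float, float]
    dest: tuple[float, float]
    dt_min: float
    used: bool = True
    turn: float = math.nan

    @property
    def length(self) -> float:
        return math.hypot(self.dest[0] - self.origin[0], self.dest[1] - self.origin[1])

    @property
    def heading(self) -> float:
        return math.atan2(self.dest[1] - self.origin[1], self.dest[0] - self.origin[0])


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


def resample_to_steps(
    fixes: pd.DataFrame,
    min_dist: float = MIN_STEP_DIST_M,
    max_dt: float = MAX_STEP_DT_MIN,
) -> list[Step]:
    """Greedy per-bird resampling of the fix stream into used steps.

    From the current anchor the next retained fix is the first one at
    least ``min_dist`` away; the pair forms a step only if separated by at
    most ``max_dt`` minutes, otherwise a new bout starts at that fix (and
    the next step's turning angle is undefined).
    """
    steps: list[Step] = []
    df = fixes.sort_values(["bird_id", "timestamp"], kind="mergesort")
    for bird, sub in df.groupby("bird_id", sort=False):
        xs = sub["x"].to_numpy(float)
        ys = sub["y"].to_numpy(float)
        ts = pd.to_datetime(sub["timestamp"]).to_numpy()
        anchor = 0
        prev_heading = math.nan
        i = 1
        while i < len(sub):
            d = math.hypot(xs[i] - xs[anchor], ys[i] - ys[anchor])
            if d < min_dist:
                i += 1
                continue
            dt = (ts[i] - ts[anchor]) / np.timedelta64(1, "m")
            if dt <= max_dt:
                step = Step(
                    bird_id=bird,
                    origin=(xs[anchor], ys[anchor]),
                    dest=(xs[i], ys[i]),
                    dt_min=float(dt),
                    used=True,
                )
                turn = (
                    math.nan
                    if math.isnan(prev_heading)
                    else _wrap_angle(step.heading - prev_heading)
                )
                steps.append(replace(step, turn=turn))
                prev_heading = step.heading
            else:
                prev_heading = math.nan  # bout break
            anchor = i
            i += 1
    return steps


# ---------------------------------------------------------------------------
# leave-one-out movement pools
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmpiricalMoveDistributions:
    """Step-length and turning-angle pools from all birds but the focal one."""

    lengths: np.ndarray
    turns: np.ndarray
    source_birds: tuple

    def __post_init__(self) -> None:
        if self.lengths.size == 0 or self.turns.size == 0:
            raise ValueError("empirical movement pools are empty")


def loo_distributions(all_steps: list[Step], focal_bird) -> EmpiricalMoveDistributions:
    birds = {s.bird_id for s in all_steps}
    if len(birds) < 2:
        raise ValueError("leave-one-out pools need at least 2 birds")
    others = [s for s in all_steps if s.bird_id != focal_bird]
    lengths = np.array([s.length for s in others])
    turns = np.array([s.turn for s in others if not math.isnan(s.turn)])
    return EmpiricalMoveDistributions(
        lengths=lengths, turns=turns, source_birds=tuple(sorted(birds - {focal_bird}))
    )


# ---------------------------------------------------------------------------
# random steps
# ---------------------------------------------------------------------------

class StratumDropped(RuntimeError):
    """No forest-ending random step could be generated for a stratum."""


def generate_random_steps(
    step: Step,
    dists: EmpiricalMoveDistributions,
    lcmap: LandCoverMap,
    rng: np.random.Generator,
    n: int = N_RANDOM_STEPS,
    max_rejections: int = REJECTION_CAP,
) -> list[Step]:
    """Draw ``n`` random steps from ``step``'s origin: (length, turn) sampled
    with replacement from the pools, rejection-sampled until the endpoint
    lies in forest and inside the map.

    When the used step has no previous heading (bout start) candidate
    headings are uniform on (-pi, pi]; otherwise heading = previous heading
    + a pooled turning angle.
    """
    ox, oy = step.origin
    prev_heading = None if math.isnan(step.turn) else step.heading - step.turn
    out: list[Step] = []
    rejected = 0
    batch = max(4 * n, 64)
    while len(out) < n:
        if rejected > max_rejections:
            raise StratumDropped(
                f"{rejected} rejections without {n} forest-ending steps "
                f"(origin {step.origin}, bird {step.bird_id})"
            )
        lens = rng.choice(dists.lengths, size=batch)
        if prev_heading is None:
            heads = rng.uniform(-math.pi, math.pi, size=batch)
            turns = heads
        else:
            turns = rng.choice(dists.turns, size=batch)
            heads = prev_heading + turns
        ex = ox + lens * np.cos(heads)
        ey = oy + lens * np.sin(heads)
        row, col = lcmap._cells_of(ex, ey)
        ok = (row >= 0) & (lcmap.grid[np.maximum(row, 0), np.maximum(col, 0)] == FOREST)
        for i in np.nonzero(ok)[0]:
            if len(out) == n:
                break
            out.append(
                Step(
                    bird_id=step.bird_id,
                    origin=step.origin,
                    dest=(float(ex[i]), float(ey[i])),
                    dt_min=step.dt_min,
                    used=False,
                    turn=float(_wrap_angle(turns[i])),
                )
            )
        rejected += int(batch - ok.sum())
    return out


# ---------------------------------------------------------------------------
# covariates and strata
# ---------------------------------------------------------------------------

def step_covariates(
    lcmap: LandCoverMap,
    streams: StreamNetwork,
    step: Step,
    foram_width: float = 30.0,
    which: tuple[str, ...] = COVARIATES,
) -> dict[str, float]:
    """Compute the requested SSF covariates for one step.

    Stream distance is measured at the step destination (where the step
    takes the bird); the gap profile is sampled at resolution/4.
    """
    out: dict[str, float] = {}
    need_gap = any(c in which for c in ("TotGap", "MeanGap", "NumGap", "PropInFor", "Pasture"))
    if need_gap:
        gp = gap_profile(lcmap, step.origin, step.dest)
        out.update(
            TotGap=gp.total_gap_length,
            MeanGap=gp.mean_gap_size,
            NumGap=float(gp.num_gaps),
            PropInFor=gp.prop_in_forest,
            Pasture=gp.pasture_prop_of_gap,
        )
    if "ForAm" in which:
        out["ForAm"] = step_forest_amount(lcmap, step.origin, step.dest, width=foram_width)
    if "Stream" in which:
        out["Stream"] = float(distances_to_stream(streams, np.array([step.dest]))[0])
    return {k: out[k] for k in which if k in out}


def build_strata(
    used_steps: list[Step],
    lcmap: LandCoverMap,
    streams: StreamNetwork,
    seed: int,
    n_random: int = N_RANDOM_STEPS,
    foram_width: float = 30.0,
    covariates: tuple[str, ...] = COVARIATES,
    pools: EmpiricalMoveDistributions | dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the long-format strata table: one row per step (used and
    random), with stratum id, bird id, used flag and covariates.

    By default availability pools are leave-one-out empirical distributions
    (per focal bird, from the remaining birds' steps); a single
    :class:`EmpiricalMoveDistributions` (e.g. a known simulation kernel) or
    a per-bird dict may be supplied instead.  Strata whose random steps
    cannot be generated are dropped and counted.  Returns ``(strata, log)``
    where ``log`` reports drops per reason.
    """
    rng = np.random.default_rng(seed)
    if pools is None:
        pools = {b: loo_distributions(used_steps, b) for b in {s.bird_id for s in used_steps}}
    elif isinstance(pools, EmpiricalMoveDistributions):
        pools = {b: pools for b in {s.bird_id for s in used_steps}}
    # vectorize stream distances over all destinations at the end
    rows: list[dict] = []
    step_objs: list[Step] = []
    dropped = 0
    sid = 0
    for st in used_steps:
        try:
            rand = generate_random_steps(st, pools[st.bird_id], lcmap, rng, n=n_random)
        except StratumDropped:
            dropped += 1
            continue
        for s in [st, *rand]:
            cov = step_covariates(
                lcmap, streams, s, foram_width=foram_width,
                which=tuple(c for c in covariates if c != "Stream"),
            )
            rows.append(
                {"stratum": sid, "bird_id": s.bird_id, "used": s.used,
                 "length": s.length, **cov}
            )
            step_objs.append(s)
        sid += 1
    strata = pd.DataFrame(rows)
    if "Stream" in covariates and len(strata):
        dests = np.array([s.dest for s in step_objs])
        strata["Stream"] = distances_to_stream(streams, dests)
    log = {"strata_built": sid, "strata_dropped": dropped, "n_random": n_random, "seed": seed}
    return strata, log


# ---------------------------------------------------------------------------
# candidate models (the field study's candidate set)
# ---------------------------------------------------------------------------

#: Candidate model registry: a univariate model per exposure variable, the
#: exposure + Stream pairs, pasture-interaction versions for the three gap
#: metrics, and Stream alone.  ``A * Pasture`` denotes the exposure main
#: effect plus its product with the Pasture covariate (no Pasture main
#: effect, matching the matched-design convention that stratum-constant
#: terms are not identifiable).
MODEL_REGISTRY = (
    "Stream + TotGap",
    "Stream + TotGap * Pasture",
    "Stream + MeanGap",
    "Stream + MeanGap * Pasture",
    "TotGap",
    "Stream + PropInFor",
    "Stream + NumGap * Pasture",
    "Stream + ForAm",
    "Stream + NumGap",
    "MeanGap",
    "Stream",
    "PropInFor",
    "NumGap",
    "ForAm",
)


def parse_model_spec(spec: str) -> list[str]:
    """Expand a model spec into design-column names.

    ``"A * B"`` contributes columns ``A`` and ``A:B`` (the product).
    """
    cols: list[str] = []
    for term in (t.strip() for t in spec.split("+")):
        if "*" in term:
            a, b = (u.strip() for u in term.split("*"))
            cols.extend([a, f"{a}:{b}"])
        else:
            cols.append(term)
    return cols


def assemble_design(strata: pd.DataFrame, model_spec: str) -> pd.DataFrame:
    """Design-matrix columns for one candidate model, indexed like ``strata``."""
    cols = parse_model_spec(model_spec)
    out = {}
    for c in cols:
        if ":" in c:
            a, b = c.split(":")
            for v in (a, b):
                if v not in strata.columns:
                    raise KeyError(f"unknown covariate {v!r} in model {model_spec!r}")
            out[c] = strata[a].to_numpy(float) * strata[b].to_numpy(float)
        else:
            if c not in strata.columns:
                raise KeyError(f"unknown covariate {c!r} in model {model_spec!r}")
            out[c] = strata[c].to_numpy(float)
    return pd.DataFrame(out, index=strata.index)


# ---------------------------------------------------------------------------
# conditional logistic regression
# ---------------------------------------------------------------------------

@dataclass
class SSFFit:
    """Conditional-logit fit for one candidate model."""

    model: str
    params: pd.DataFrame          # coef, se, z, ci_low, ci_high, or per covariate
    loglik: float
    aicc: float
    n_strata: int
    status: str = "ok"            # ok | unidentifiable | separation | not_converged
    random_sd: pd.Series | None = None   # per-covariate random-coefficient SDs

    @property
    def k(self) -> int:
        return len(self.params) + (0 if self.random_sd is None else len(self.random_sd))

    def coef(self, name: str) -> float:
        return float(self.params.loc[name, "coef"])

    def se(self, name: str) -> float:
        return float(self.params.loc[name, "se"])


def _cl_loglik_grad_hess(beta, X, strat_idx, used_mask, want_hess=True):
    """Conditional-logit log-likelihood, gradient and Hessian via segment ops."""
    eta = X @ beta
    # per-stratum softmax (stable)
    order_max = np.full(strat_idx.max() + 1, -np.inf)
    np.maximum.at(order_max, strat_idx, eta)
    w = np.exp(eta - order_max[strat_idx])
    denom = np.zeros(strat_idx.max() + 1)
    np.add.at(denom, strat_idx, w)
    p = w / denom[strat_idx]
    ll = float(np.sum(eta[used_mask]) - np.sum(np.log(denom) + order_max))
    xbar = np.zeros((strat_idx.max() + 1, X.shape[1]))
    np.add.at(xbar, strat_idx, X * p[:, None])
    grad = X[used_mask].sum(axis=0) - xbar.sum(axis=0)
    if not want_hess:
        return ll, grad, None
    # Hessian = -sum_s [ E_s(xx') - xbar_s xbar_s' ]
    exx = (X * p[:, None]).T @ X
    hess = -(exx - xbar.T @ xbar)
    return ll, grad, hess


def fit_conditional_logit(
    design: pd.DataFrame,
    strata: pd.DataFrame,
    model: str = "",
    random_coefs: bool = False,
    n_draws: int = 200,
    seed: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> SSFFit:
    """Fit the matched case-control (conditional) logistic regression.

    Fixed-effects mode maximizes the exact conditional likelihood by
    Newton-Raphson.  With ``random_coefs=True`` every covariate in the
    model also carries a per-bird Gaussian deviation; the marginal
    likelihood is integrated by seeded antithetic Monte-Carlo draws
    (simulated maximum likelihood) and the variance->0 limit recovers the
    fixed-effects fit.
    """
    X = design.to_numpy(float)
    names = list(design.columns)
    strat_idx = pd.factorize(strata["stratum"])[0]
    used_mask = strata["used"].to_numpy(bool)
    n_strata = int(strat_idx.max() + 1)
    if n_strata < 2:
        raise ValueError("need at least 2 strata")
    k = X.shape[1]

    # identifiability: within-stratum variation must exist
    centered = X - np.array([np.bincount(strat_idx, weights=X[:, j]) /
                             np.bincount(strat_idx) for j in range(k)]).T[strat_idx]
    if np.allclose(centered, 0.0):
        params = _ssf_params(np.full(k, np.nan), np.full(k, np.nan), names)
        ll0 = -n_strata * np.log(np.bincount(strat_idx).mean())
        return SSFFit(model, params, float(ll0), math.inf, n_strata, status="unidentifiable")

    scale = np.maximum(centered.std(axis=0), 1e-12)
    beta = np.zeros(k)
    status = "ok"
    for _ in range(max_iter):
        ll, grad, hess = _cl_loglik_grad_hess(beta, X, strat_idx, used_mask)
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            status = "unidentifiable"
            break
        # dampen huge steps for stability
        if np.max(np.abs(step * scale)) > 5.0:
            step = step * 5.0 / np.max(np.abs(step * scale))
        beta = beta + step
        if np.max(np.abs(beta * scale)) > 100.0:
            status = "separation"
            break
        if np.max(np.abs(step * scale)) < tol:
            break
    else:
        status = "not_converged"

    ll, grad, hess = _cl_loglik_grad_hess(beta, X, strat_idx, used_mask)
    if status in ("separation", "unidentifiable"):
        params = _ssf_params(np.full(k, np.nan), np.full(k, np.nan), names)
        return SSFFit(model, params, float(ll), math.inf, n_strata, status=status)

    if not random_coefs:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(cov))
        params = _ssf_params(beta, se, names)
        return SSFFit(model, params, float(ll), aicc(ll, k, n_strata), n_strata, status=status)

    # --- simulated maximum likelihood with per-bird random coefficients ----
    from scipy import optimize as _opt

    birds, bird_idx = np.unique(strata["bird_id"].to_numpy(), return_inverse=True)
    # stratum -> bird (constant within stratum)
    strat_bird = np.zeros(n_strata, dtype=int)
    strat_bird[strat_idx] = bird_idx
    rng = np.random.default_rng(seed)
    half = max(n_draws // 2, 1)
    z_half = rng.standard_normal((len(birds), half, k))
    z = np.concatenate((z_half, -z_half), axis=1)          # antithetic pairs
    n_draws = z.shape[1]

    def neg_sml(theta):
        b, log_sd = theta[:k], theta[k:]
        sd = np.exp(log_sd)
        total = 0.0
        for bi in range(len(birds)):
            rows = bird_idx == bi
            Xb = X[rows]
            si = strat_idx[rows]
            si = np.unique(si, return_inverse=True)[1]
            ub = used_mask[rows]
            lls = np.empty(n_draws)
            for d in range(n_draws):
                bd = b + sd * z[bi, d]
                lls[d] = _cl_loglik_grad_hess(bd, Xb, si, ub, want_hess=False)[0]
            m = lls.max()
            total += m + np.log(np.mean(np.exp(lls - m)))
        return -total

    theta0 = np.concatenate((beta, np.log(np.full(k, 0.1) / scale)))
    res = _opt.minimize(neg_sml, theta0, method="Nelder-Mead",
                        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 4000})
    bhat, sdhat = res.x[:k], np.exp(res.x[k:])
    ll = -res.fun
    # numerical observed information for SEs of fixed coefficients
    h = 1e-4 / scale
    hess_n = np.zeros((k, k))
    f0 = -neg_sml(res.x)
    for i in range(k):
        for j in range(i, k):
            xpp = res.x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = res.x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = res.x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = res.x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            hess_n[i, j] = hess_n[j, i] = (
                (-neg_sml(xpp)) - (-neg_sml(xpm)) - (-neg_sml(xmp)) + (-neg_sml(xmm))
            ) / (4 * h[i] * h[j])
    try:
        se = np.sqrt(np.diag(np.linalg.inv(-hess_n)))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    params = _ssf_params(bhat, se, names)
    k_all = 2 * k
    fit = SSFFit(model, params, float(ll), aicc(ll, k_all, n_strata), n_strata,
                 status="ok" if res.success else "not_converged",
                 random_sd=pd.Series(sdhat, index=names))
    return fit


def _ssf_params(beta, se, names) -> pd.DataFrame:
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    return pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "z": beta / se,
            "ci_low": lo,
            "ci_high": hi,
            "or": np.exp(beta),
        },
        index=list(names),
    )


def rank_models(fits: list[SSFFit]) -> pd.DataFrame:
    """AICc ranking table (ascending; ties broken by fewer parameters)."""
    tab = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aicc": [f.aicc for f in fits],
        }
    ).sort_values(["aicc", "k"], kind="mergesort")
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    return tab.reset_index(drop=True)


# ---------------------------------------------------------------------------
# second stage: explain per-bird coefficients
# ---------------------------------------------------------------------------

def second_stage(
    per_bird_coefs: pd.Series,
    bird_covariates: pd.DataFrame,
    predictors: tuple[str, ...] = ("forest_amount", "connectivity", "sex"),
) -> pd.DataFrame:
    """OLS of per-bird selection coefficients on landscape context and sex.

    ``per_bird_coefs`` is indexed by bird id; ``bird_covariates`` holds the
    predictor columns (sex may be categorical; it is dummy-coded).  Returns
    a tidy table of slope, SE, t and P per predictor.
    """
    import statsmodels.api as sm

    df = bird_covariates.loc[per_bird_coefs.index, list(predictors)].copy()
    for c in df.columns:
        if df[c].dtype == object or str(df[c].dtype) == "category":
            df[c] = pd.factorize(df[c])[0].astype(float)
    y = per_bird_coefs.to_numpy(float)
    if len(y) < len(predictors) + 1:
        raise ValueError("fewer birds than regression parameters")
    X = sm.add_constant(df.to_numpy(float))
    fit = sm.OLS(y, X).fit()
    names = ["intercept", *predictors]
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        },
        index=names,
    )
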