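"""Synthetic landscapes, telemetry tracks and vegetation plots with known
ground truth.

The generator emulates the study system this package was built to analyse:
a fragmented premontane tropical landscape (forest remnants in a pasture-
dominated matrix, riparian forest corridors 10-40 m wide crossed by
streams), telemetry on ~20 radio-tracked hummingbirds whose fixes carry
GPS noise and an observer-distance class, and used/random vegetation-plot
pairs.  Movement is simulated from the same step-selection model the
pipeline fits: at every move the bird draws candidate steps from its
movement pools and picks one with probability proportional to
exp(beta . covariates), so fitted coefficients can be checked against the
simulating ones.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import (
    FOREST,
    OTHER_MATRIX,
    PASTURE,
    LandCoverMap,
    StreamNetwork,
    class_fraction,
    distances_to_stream,
    gap_profile,
    step_forest_amount,
)

__all__ = ["SimulationConfig", "GroundTruth", "gen_landscape", "simulate_track",
           "simulate_fixes", "gen_vegplot_pairs"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic generator.

    Sample sizes mirror the tracked population: 20 birds and 2428 raw
    fixes of which 46/32/22% of the usable (<= 30 m observer distance)
    records fall in the 0-10 / 11-20 / 21-30 m classes and 1561 are usable
    in total.  GPS noise uses the observed mean accuracy (6.54 m).
    Movement pools (gamma step lengths, von Mises turning angles) are
    package defaults chosen to give daily spans comparable to the observed
    home-range lengths (median ~240 m); they are defaults, not estimates.
    """

    seed: int
    map_size: float = 1500.0          # m, square landscape
    resolution: float = 5.0           # m / cell; resolves 10-40 m corridors
    forest_fraction: float = 0.40     # target forest cover
    n_patch_seeds: int = 12
    n_streams: int = 3
    corridor_width: tuple[float, float] = (10.0, 40.0)
    pasture_share: float = 90.0 / 95.0  # of non-forest matrix (rest: coffee/banana)
    n_birds: int = 20
    total_fixes: int = 2428
    usable_fraction: float = 1561.0 / 2428.0
    dist_class_probs: tuple[float, float, float] = (0.46, 0.32, 0.22)
    fix_interval_min: float = 5.0
    gamma_shape: float = 2.0
    gamma_scale: float = 40.0         # m
    min_step_length: float = 10.0     # m; perch-scale shuffles are not relocations
    vonmises_kappa: float = 0.5
    n_candidates: int = 50            # simulator choice-set size (not the analysis's 20)
    forest_only_candidates: bool = True
    beta: dict = field(default_factory=lambda: {"Stream": -0.020, "TotGap": -0.019})
    gps_noise_sd: float = 6.54        # m
    beta_plants: float = 0.0526       # per flowering plant (OR 1.054)
    beta_canopy: float = 0.0218       # per % canopy cover (OR 1.022)

    def __post_init__(self) -> None:
        if not 0 < self.forest_fraction <= 1:
            raise ValueError("forest_fraction must be in (0, 1]")
        if self.gps_noise_sd < 0 or self.gamma_scale <= 0:
            raise ValueError("variances and scales must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually used, stored for recovery tests."""

    beta: dict
    bird_starts: dict
    config: SimulationConfig


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------

def _grow_clumps(mask: np.ndarray, n_seeds: int, target_cells: int,
                 rng: np.random.Generator) -> None:
    """Seeded stochastic clump growth until ``mask`` has target_cells True."""
    nrows, ncols = mask.shape
    # pre-existing forest (riparian corridors) also grows, else it would wall
    # off regions from the clump seeds
    frontier: list[tuple[int, int]] = [tuple(rc) for rc in np.argwhere(mask)]
    for _ in range(n_seeds):
        r, c = int(rng.integers(nrows)), int(rng.integers(ncols))
        mask[r, c] = True
        frontier.append((r, c))
    count = int(mask.sum())
    while count < target_cells and frontier:
        i = int(rng.integers(len(frontier)))
        r, c = frontier[i]
        nbrs = [(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= r + dr < nrows and 0 <= c + dc < ncols and not mask[r + dr, c + dc]]
        if not nbrs:
            frontier[i] = frontier[-1]
            frontier.pop()
            continue
        nr, nc = nbrs[int(rng.integers(len(nbrs)))]
        mask[nr, nc] = True
        frontier.append((nr, nc))
        count += 1


def gen_landscape(cfg: SimulationConfig) -> tuple[LandCoverMap, StreamNetwork]:
    """Generate the land-cover mosaic and stream network.

    Streams are noisy directed walks across the map, each wrapped in a
    forest corridor of width drawn from ``cfg.corridor_width``; remaining
    forest grows as seeded clumps until the target forest fraction is hit
    (within 2 percentage points).  Non-forest cells split into pasture and
    other matrix (coffee/banana) at the configured share.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.map_size / cfg.resolution))
    res = cfg.resolution
    forest = np.zeros((n, n), dtype=bool)

    # streams: directed random walks spanning the map
    polylines = []
    xs_grid = (np.arange(n) + 0.5) * res
    for _ in range(cfg.n_streams):
        vertical = rng.random() < 0.5
        pos = rng.uniform(0.2, 0.8) * cfg.map_size
        pts = []
        step = 10 * res
        t = 0.0
        while t <= cfg.map_size:
            pts.append((t, pos) if not vertical else (pos, t))
            pos = float(np.clip(pos + rng.normal(0, step / 2), res, cfg.map_size - res))
            t += step
        polylines.append(np.array(pts))
    streams = StreamNetwork(tuple(polylines))

    # riparian corridors: forest within width/2 of a stream
    X, Y = np.meshgrid(xs_grid, xs_grid)
    centers = np.column_stack((X.ravel(), Y.ravel()))
    for poly, width in zip(
        streams.polylines, rng.uniform(*cfg.corridor_width, size=len(polylines))
    ):
        one = StreamNetwork((poly,))
        d1 = distances_to_stream(one, centers)
        forest |= (d1 <= width / 2.0).reshape(n, n)

    target = int(round(cfg.forest_fraction * n * n))
    if forest.sum() < target:
        _grow_clumps(forest, cfg.n_patch_seeds, target, rng)

    grid = np.where(forest, FOREST, PASTURE).astype(np.int8)
    nonforest = ~forest
    other = nonforest & (rng.random((n, n)) > cfg.pasture_share)
    grid[other] = OTHER_MATRIX
    lcmap = LandCoverMap(grid=grid, resolution=res)
    realized = lcmap.forest_fraction()
    if abs(realized - cfg.forest_fraction) > 0.02 and realized < cfg.forest_fraction:
        raise RuntimeError(
            f"landscape generation missed the forest target: {realized:.3f} "
            f"vs {cfg.forest_fraction:.3f}"
        )
    return lcmap, streams


# ---------------------------------------------------------------------------
# movement simulation
# ---------------------------------------------------------------------------

def _candidate_covariates(
    lcmap: LandCoverMap,
    streams: StreamNetwork,
    origin: np.ndarray,
    ends: np.ndarray,
    which: tuple[str, ...],
    foram_width: float = 30.0,
) -> np.ndarray:
    """(n_candidates, len(which)) covariate matrix for candidate endpoints."""
    cols = []
    need_gap = [c for c in which if c in ("TotGap", "MeanGap", "NumGap", "PropInFor", "Pasture")]
    gap_vals = {}
    if need_gap:
        for name in need_gap:
            gap_vals[name] = np.empty(len(ends))
        for i, e in enumerate(ends):
            gp = gap_profile(lcmap, origin, e)
            vals = {
                "TotGap": gp.total_gap_length,
                "MeanGap": gp.mean_gap_size,
                "NumGap": float(gp.num_gaps),
                "PropInFor": gp.prop_in_forest,
                "Pasture": gp.pasture_prop_of_gap,
            }
            for name in need_gap:
                gap_vals[name][i] = vals[name]
    for c in which:
        if c == "Stream":
            cols.append(distances_to_stream(streams, ends))
        elif c == "ForAm":
            cols.append(
                np.array([step_forest_amount(lcmap, origin, e, width=foram_width) for e in ends])
            )
        else:
            cols.append(gap_vals[c])
    return np.column_stack(cols)


def _draw_lengths(cfg: SimulationConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Gamma step lengths left-truncated at ``cfg.min_step_length``."""
    out = np.empty(0)
    while out.size < size:
        draw = rng.gamma(cfg.gamma_shape, cfg.gamma_scale, size=2 * size)
        out = np.concatenate((out, draw[draw >= cfg.min_step_length]))
    return out[:size]


def kernel_move_distributions(cfg: SimulationConfig, n: int = 5000,
                              rng: np.random.Generator | None = None):
    """Movement pools drawn from the *true* simulation kernel.

    Only available in simulation (the kernel is unknown for field data,
    where leave-one-out empirical pools stand in for it); used to validate
    the conditional-logit estimator free of the empirical-availability
    approximation.
    """
    from .pathscale import EmpiricalMoveDistributions

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 31]))
    return EmpiricalMoveDistributions(
        lengths=_draw_lengths(cfg, rng, n),
        turns=rng.vonmises(0.0, cfg.vonmises_kappa, size=n),
        source_birds=("movement-kernel",),
    )


def simulate_track(
    cfg: SimulationConfig,
    lcmap: LandCoverMap,
    streams: StreamNetwork,
    beta: dict | None = None,
    bird_id: object = 0,
    n_fixes: int | None = None,
    rng: np.random.Generator | None = None,
    start: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Simulate one bird's fix stream from the step-selection model.

    At each move, ``cfg.n_candidates`` candidate steps are drawn from the
    movement pools (lengths gamma, turns von Mises about the previous
    heading); one is chosen with probability proportional to
    exp(beta . x).  Candidates leaving the map (and, by default, ending
    outside forest) are redrawn; if none can be found the bird restarts at
    a new forest origin.  Emitted coordinates carry Gaussian GPS noise and
    timestamps at the configured interval.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if beta is None:
        beta = cfg.beta
    if n_fixes is None:
        n_fixes = cfg.total_fixes // cfg.n_birds
    names = tuple(beta.keys())
    bvec = np.array([beta[k] for k in names], dtype=float)
    forest_rows, forest_cols = np.nonzero(lcmap.grid == FOREST)

    def random_forest_point() -> np.ndarray:
        i = int(rng.integers(len(forest_rows)))
        x, y = lcmap.cell_center(forest_rows[i], forest_cols[i])
        return np.array([x, y])

    pos = np.asarray(start, float) if start is not None else random_forest_point()
    heading = float(rng.uniform(-math.pi, math.pi))
    true_positions = [pos.copy()]
    m = cfg.n_candidates
    for _ in range(n_fixes - 1):
        ends = None
        for _attempt in range(40):
            lens = _draw_lengths(cfg, rng, m)
            turns = rng.vonmises(0.0, cfg.vonmises_kappa, size=m)
            heads = heading + turns
            cand = pos[None, :] + np.column_stack((lens * np.cos(heads), lens * np.sin(heads)))
            row, col = lcmap._cells_of(cand[:, 0], cand[:, 1])
            ok = row >= 0
            if cfg.forest_only_candidates:
                ok &= lcmap.grid[np.maximum(row, 0), np.maximum(col, 0)] == FOREST
            if ok.sum() >= max(2, m // 10):
                ends = cand[ok]
                break
        if ends is None:
            pos = random_forest_point()   # trapped: restart, logged by caller via gaps
            heading = float(rng.uniform(-math.pi, math.pi))
            true_positions.append(pos.copy())
            continue
        if bvec.size:
            Xc = _candidate_covariates(lcmap, streams, pos, ends, names)
            w = Xc @ bvec
            w -= w.max()
            p = np.exp(w)
            p /= p.sum()
        else:
            p = np.full(len(ends), 1.0 / len(ends))
        j = int(rng.choice(len(ends), p=p))
        new = ends[j]
        heading = math.atan2(new[1] - pos[1], new[0] - pos[0])
        pos = new
        true_positions.append(pos.copy())

    true_xy = np.array(true_positions)
    noisy = true_xy + rng.normal(0.0, cfg.gps_noise_sd, size=true_xy.shape)
    # keep noisy fixes on the map
    x0, y0, x1, y1 = lcmap.bounds
    eps = lcmap.resolution / 10
    noisy[:, 0] = np.clip(noisy[:, 0], x0 + eps, x1 - eps)
    noisy[:, 1] = np.clip(noisy[:, 1], y0 + eps, y1 - eps)
    t0 = pd.Timestamp("2012-03-01 06:00:00")
    times = t0 + pd.to_timedelta(np.arange(n_fixes) * cfg.fix_interval_min, unit="m")
    return pd.DataFrame(
        {
            "bird_id": bird_id,
            "x": noisy[:, 0],
            "y": noisy[:, 1],
            "true_x": true_xy[:, 0],
            "true_y": true_xy[:, 1],
            "timestamp": times,
            "gps_acc_m": cfg.gps_noise_sd,
        }
    )


def _distance_classes(n_total: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Observer-distance classes with deterministic class totals: the usable
    fraction splits 46/32/22 across the three <= 30 m classes, the rest is
    > 30 m."""
    n_usable = int(round(cfg.usable_fraction * n_total))
    c1 = int(round(cfg.dist_class_probs[0] * n_usable))
    c2 = int(round(cfg.dist_class_probs[1] * n_usable))
    c3 = n_usable - c1 - c2
    labels = np.array(
        ["0-10"] * c1 + ["11-20"] * c2 + ["21-30"] * c3 + [">30"] * (n_total - n_usable)
    )
    rng.shuffle(labels)
    return labels


def simulate_fixes(
    cfg: SimulationConfig,
    lcmap: LandCoverMap,
    streams: StreamNetwork,
    beta: dict | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the full multi-bird telemetry dataset.

    Total fixes are distributed as evenly as possible over the birds
    (summing exactly to ``cfg.total_fixes``); each bird starts at an
    independent random forest location; observer-distance classes are
    assigned with deterministic totals so the usable count matches the
    configured fraction exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    base = cfg.total_fixes // cfg.n_birds
    extra = cfg.total_fixes - base * cfg.n_birds
    counts = [base + (1 if i < extra else 0) for i in range(cfg.n_birds)]
    frames = []
    starts = {}
    sexes = {}
    for i, nf in enumerate(counts):
        bird = f"bird{i:02d}"
        track = simulate_track(
            cfg, lcmap, streams, beta=beta, bird_id=bird, n_fixes=nf,
            rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, 11, i])),
        )
        starts[bird] = (float(track["true_x"].iloc[0]), float(track["true_y"].iloc[0]))
        sexes[bird] = "M" if i < round(0.4 * cfg.n_birds) else "F"  # 8 of 20 male
        frames.append(track)
    fixes = pd.concat(frames, ignore_index=True)
    fixes["obs_dist_class"] = _distance_classes(len(fixes), cfg, rng)
    fixes["sex"] = fixes["bird_id"].map(sexes)
    gt = GroundTruth(beta=dict(beta if beta is not None else cfg.beta),
                     bird_starts=starts, config=cfg)
    return fixes, gt


# ---------------------------------------------------------------------------
# vegetation-plot pairs
# ---------------------------------------------------------------------------

def gen_vegplot_pairs(
    cfg: SimulationConfig,
    lcmap: LandCoverMap,
    n_pairs: int,
    rng: np.random.Generator | None = None,
    plot_radius: float = 20.0,
    max_pair_dist: float = 500.0,
    plants_base: float = 2.5,
    plants_forest_gain: float = 1.0,
) -> pd.DataFrame:
    """Used/random vegetation-plot pairs with known selection effects.

    Two candidate plot centers are drawn within ``max_pair_dist`` of each
    other; canopy cover is 100 x the forest fraction in a plot-radius
    buffer, plant counts are Poisson with mean ``plants_base +
    plants_forest_gain * forest_fraction`` (only weakly tied to canopy,
    mirroring the near-zero canopy/resource correlation observed in the
    field plots), and the *used* member is chosen with the paired-logit
    probability exp(beta.x1) / (exp(beta.x1) + exp(beta.x2)) — exactly the
    model the paired conditional logistic fit assumes.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    x0, y0, x1, y1 = lcmap.bounds
    pad = plot_radius + 1.0
    rows = []
    for pid in range(n_pairs):
        p1 = np.array([rng.uniform(x0 + pad, x1 - pad), rng.uniform(y0 + pad, y1 - pad)])
        while True:
            ang = rng.uniform(0, 2 * math.pi)
            r = rng.uniform(plot_radius, max_pair_dist)
            p2 = p1 + r * np.array([math.cos(ang), math.sin(ang)])
            if x0 + pad < p2[0] < x1 - pad and y0 + pad < p2[1] < y1 - pad:
                break
        plots = []
        for p in (p1, p2):
            ff = class_fraction(lcmap, p, plot_radius, FOREST)
            canopy = 100.0 * ff
            plants = int(rng.poisson(plants_base + plants_forest_gain * ff))
            plots.append({"canopy_pct": canopy, "heliconia_n": plants})
        u1 = cfg.beta_plants * plots[0]["heliconia_n"] + cfg.beta_canopy * plots[0]["canopy_pct"]
        u2 = cfg.beta_plants * plots[1]["heliconia_n"] + cfg.beta_canopy * plots[1]["canopy_pct"]
        p_first = 1.0 / (1.0 + math.exp(u2 - u1))
        used_first = rng.random() < p_first
        for j, plot in enumerate(plots):
            rows.append(
                {
                    "pair_id": pid,
                    "bird_id": f"bird{pid % cfg.n_birds:02d}",
                    "role": "used" if (j == 0) == used_first else "random",
                    **plot,
                }
            )
    return pd.DataFrame(rows)
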