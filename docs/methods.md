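# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate and raster conventions

All geometry is planar (meters, UTM-like); any reprojection happens before
ingest. Land cover is a categorical grid (forest / pasture / other matrix)
with origin at the lower-left corner; the default resolution is 5 m so that
10–40 m riparian corridors are resolved by at least two cells. Buffer
membership is by the cell-center-in-circle rule everywhere, which makes
buffer fractions exactly reproducible by enumeration. Patches are maximal
8-neighbour components (4-neighbour adjacency would split one-cell diagonal
corridor pixels; configurable). Patch-to-patch distance is the minimum
edge-to-edge distance between the patches' cell squares, computed exactly
with the axis-aligned box formula `hypot(max(0,|Δx|−res), max(0,|Δy|−res))`
over boundary cells — identical to the shapely polygon distance but much
cheaper, which matters inside the rotation null model.

## Point scale

Fixes recorded from beyond 30 m are discarded; the > 1 m thinning is
*sequential* per bird in time order (a fix is dropped if it lies within 1 m
of the previously retained fix). A global rule would also delete revisits to
the same perch minutes apart, which are real use.

The forest-dependency model is `Difference ~ 1 + TotalForest` with a
per-bird random intercept (block compound symmetry added to the covariance)
and residual spatial correlation `Corr(d)` in one of the standard
mixed-model parameterizations:

| structure          | Corr(d)                                   |
|--------------------|-------------------------------------------|
| exponential        | exp(−d/ρ)                                 |
| gaussian           | exp(−(d/ρ)²)                              |
| spherical          | 1 − 1.5(d/ρ) + 0.5(d/ρ)³ for d < ρ, else 0|
| rational quadratic | 1 / (1 + (d/ρ)²)                          |

Estimation is REML by Nelder–Mead over (log σ², log σ²_bird, log ρ), with a
1e−8·σ² diagonal ridge for factorizability when a variance component
collapses, multiple ρ starting values (med/4, med, 2·med of pairwise
distances), and Wald 95% intervals (β ± 1.96 SE). AICc counts fixed plus
variance parameters, n = observations. A practical caveat verified while
validating: at field-realistic n (one–two hundred points) AICc reliably
*detects* spatial correlation (the exponential model beats independent
errors essentially always when ρ = 200 m) but cannot reliably *discriminate
among* correlation families — spherical and rational-quadratic fits mimic an
exponential truth in a large share of replicates. The structure-comparison
helper therefore reports the full ranking, but the meaningful automated
check is correlated-vs-independent.

Moran's I uses 10 distance bins up to half the maximum pairwise distance,
binary bin-membership weights row-standardized; |I| > 0.1 in any bin flags
residual autocorrelation.

The vegetation-plot model is the exact 1:1 matched conditional logistic
likelihood, `Σ log σ(β·(x_used − x_random))`, maximized by Newton–Raphson.
Pair and individual intercepts cancel in the within-pair differences, so the
"pair nested in individual" random-intercept structure is handled without
approximation. Complete separation (the used plot dominates every pair) is
detected by perfect concordance of fitted probabilities or divergence on the
within-pair-difference scale and reported as a status, not as a number.
Standardized coefficients are β·SD(x) with SD over all plots.

## Path scale

Step resampling is a greedy forward scan: from the current anchor, the next
retained fix is the first ≥ 10 m away; the pair forms a step only if ≤ 15
min apart, otherwise a new bout starts there (and the next step has no
defined turning angle). Random steps draw (length, turn) independently with
replacement from leave-one-out empirical pools; bout-start strata draw
headings uniformly on (−π, π]. Endpoints are rejection-sampled to forest
with a 10,000-rejection cap per stratum; dropped strata are counted in the
run log. Distance to stream is measured at the step destination (the step
"takes the bird" somewhere; configurable to other points if needed). The
capsule buffer width for `ForAm` is not fixed by any field protocol; the
default is 30 m and it is a keyword everywhere.

The candidate-model registry holds the 14 models of the field analysis's candidate
set: five univariate exposure models, the five exposure + Stream pairs,
pasture-interaction versions of the three gap metrics (exposure + Stream +
exposure×Pasture; no Pasture main effect, since a within-gap proportion has
no meaning for gapless steps and the matched design removes stratum-level
intercepts anyway), and Stream alone.

The fixed-effects conditional logit is maximized by damped Newton–Raphson on
the exact matched case-control likelihood with segment (per-stratum softmax)
arithmetic; identifiability is pre-checked by within-stratum centering, and
separation is reported as a status. AICc uses n = number of strata (the
independent choice events). The random-coefficients variant gives every
covariate a per-bird Gaussian deviation and maximizes the simulated
likelihood with seeded antithetic normal draws (200 per bird by default);
the variance→0 limit reproduces the fixed-effects fit (tested). Wald CIs and
OR = exp(β) throughout. The second stage is OLS of per-bird coefficients on
forest amount, connectivity and sex.

## Connectivity

CON is implemented literally as the printed double sum including both orders
of each pair and the i = j diagonal with c_ii = 1 — otherwise a single patch
filling the landscape could not reach the maximum of 100. "Within the
threshold" is inclusive (≤ 162 m; the threshold is itself an observed
crossing). Because the cited index family is defined via graph components
while the printed formula uses pairwise binary passibility, both are
computed; the pairwise form is the default and the component variant (≥ the
pairwise value by construction) is reported alongside. For CON inside a
polygon (rotation null), the landscape area A_L is measured on the same
raster support as the patches (cells whose centers the polygon covers), so
patch areas can never exceed A_L.

## Home-range scale

LoCoH (k-method): hulls of each point and its k−1 nearest neighbours,
accumulated smallest-first until the union covers ⌈isopleth·n⌉ points.
k defaults to ⌈√n⌉ — the field protocol does not state one — and duplicates
are broken by a deterministic micrometer jitter. Home-range length is the
maximum vertex-to-vertex distance of the polygon set ("mean home range
length" has no unique definition; this is the natural diameter).

The rotation null rotates the isopleth polygon about its area centroid in 1°
steps (359 alternatives), asserting per angle that the area is preserved to
1e−9 relative error; rotations leaving the map are excluded and counted.
Forest %, CON (162-m threshold) and mean patch size (patches clipped to the
polygon; within-range fragmentation is the quantity of interest) are
recomputed per rotation. The observed-vs-available forest comparison is a
paired Wilcoxon signed-rank test: V = sum of ranks of positive differences,
zeros dropped, average ranks for ties; exact P by full 2ⁿ enumeration for
n ≤ 15 (respecting the observed tie structure), otherwise a normal
approximation with tie and continuity corrections. Birds whose observed
range and every rotation are fully forested are excluded from that
comparison. The connectivity contrast is a paired t-test of observed vs mean
available CON, run unrestricted and restricted to rotations within ± 5
*absolute* percentage points of the observed forest cover (the reported
"± 5%" band read as percentage points; a relative band would be narrower for
low-forest birds for no stated reason). The home-range size model is OLS of
log(area) on forest %, MPS and sex, with each univariate fit also reported;
both buffer scales corresponding to the largest observed home range with and
without the outlier bird (153 ha and 6.08 ha) are supported as buffer areas.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: 20 birds; 2,428 recorded
fixes of which 64.3% (1,561) are usable, split 46/32/22% across the 0–10 /
11–20 / 21–30 m observer classes (class totals are deterministic so the
usable count is exact); GPS noise SD 6.54 m; forest target fractions with
± 2 points tolerance; riparian corridors 10–40 m wide; non-forest split
~90:5 pasture:other. Movement pools are gamma(2, 40 m) step lengths
left-truncated at 10 m and von Mises(0, κ = 0.5) turns — defaults chosen to
give home-range spans comparable to the observed median length (~240 m), not
estimates. The 10-m truncation matches the analysis's own resolution floor:
sub-10-m perch shuffles are below GPS accuracy and are never reconstructed
as steps, and keeping them in the simulator only injects chord-over-two-
moves misspecification into recovery checks. The simulator chooses among
M = 50 candidate steps (distinct from the analysis's 20 random steps)
with probability ∝ exp(β·x), restricted to forest endpoints — the same
availability definition the fitting uses, so the fitted conditional logit is
the true data-generating model. Vegetation plots tie canopy to local forest
fraction but keep plant counts only weakly forest-dependent, mirroring the
near-zero canopy/resource correlation reported from the field plots.

Two deliberate separations between "field pipeline" and "estimator
validation":

1. **Availability pools.** The field pipeline uses leave-one-out *empirical*
   pools, as practitioners must. Those pools are built from realized —
   already selected and forest-conditioned — steps, and under strong
   selection this makes the availability sample too similar to the used
   steps, attenuating coefficients (the classical empirical-availability
   bias of step-selection designs). Recovery experiments therefore draw
   pools from the known movement kernel, which exists only in simulation;
   the end-to-end check on the full empirical-pool pipeline asserts sign
   recovery, which is what that design supports.
2. **Choice-set size and GPS noise.** A best-of-50 multinomial choice leaves
   a finite-choice-set gap between the realized-choice distribution and
   q(x)exp(β·x)/Z of order 1/M, visible as ~2-SE attenuation at ~1,000
   strata; recovery runs use M = 200. GPS noise attenuates step covariates
   toward zero (errors-in-variables), so recovery runs disable it while the
   generator default keeps 6.54 m for realistic data products.

Passing recovery tests therefore demonstrate that the estimators are correct
under their own assumptions at study-scale sample sizes; they do not
demonstrate that empirical-pool SSF coefficients from field data are
unbiased (they are known not to be, under strong selection).

## Problem sizes and determinism

Test and acceptance problem sizes are chosen to exercise each claim at the
smallest scale that identifies it: ~1,000 strata for coefficient recovery,
200 single-bird replicates for null CI coverage, 100 replicates of 120
clustered points for the GLS checks, 12 constructed landscapes × 359
rotations for the availability contrast. Every stochastic entry point takes
an explicit seed; generators are pure functions of (config, seed), and
`scripts/acceptance.py` is byte-reproducible for a fixed `--seed`.

## Known limitations

- Straight-line steps: no behavioural states, no continuous-time correction.
- The GLS likelihood is Gaussian; percentage responses near the boundary are
  not transformed.
- The matched-pair logistic ignores any residual within-bird dependence
  beyond the pair matching (exact only for 1:1 designs, which this is).
- The rotation null treats the map as fixed and the range shape as rigid;
  habitat-driven range-shape plasticity is outside its scope.
- CON depends on a single passibility threshold; no distance-decay variant
  (probability-of-connectivity style indices) is provided.
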