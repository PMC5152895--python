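# trapliner

Three-scale habitat-selection analysis for radio-tracked forest pollinators
(built around the movement ecology of traplining hummingbirds in fragmented
tropical landscapes).

Movement ecologists working with VHF telemetry in forest/pasture mosaics face
the same question at three spatial scales: do animals select forest at the
scale of individual locations, of movement steps, and of whole home ranges —
and does landscape *configuration* (fragmentation, connectivity) matter beyond
landscape *composition* (forest amount)? `trapliner` implements that analysis
as a tested, reproducible pipeline, plus a synthetic-data generator with known
selection coefficients so every stage can be verified by parameter recovery.

## What it computes

**Point scale.** Fixes observed from ≤ 30 m are kept and thinned to > 1 m
separation. For each fix, `Difference` = forest % in a 30-m ("used") buffer
minus forest % in a 500-m ("available") buffer, modelled as

    Difference ~ 1 + TotalForest,   bird random intercept,
    residual Corr(d) ∈ {exponential, gaussian, spherical, rational quadratic}

by REML, with AICc comparing correlation structures and a Moran's I
correlogram of residuals as the diagnostic. Paired used/random vegetation
plots (canopy cover %, flowering-plant counts) are fitted by an exact 1:1
matched conditional logistic regression; with 1:1 matching the pair and
individual intercepts drop out of the likelihood.

**Path scale (step-selection functions).** The fix stream is resampled into
steps ≥ 10 m and ≤ 15 min apart. Each used step is matched with 20 random
steps sharing its origin, drawn from leave-one-out step-length/turning-angle
pools of the remaining birds and required to end in forest. A conditional
logistic regression (own Newton–Raphson maximizer of the matched
case-control likelihood)

    ℓ(β) = Σ_strata [ β·x_used − log Σ_j exp(β·x_j) ]

estimates selection against gap exposure (`TotGap`, `MeanGap`, `NumGap`,
`PropInFor`, `ForAm`) and for stream proximity (`Stream`), with
pasture-interaction terms; 14 candidate models are ranked by AICc, a
random-coefficients (mixed) variant integrates per-bird deviations by
simulated maximum likelihood, and a second-stage OLS explains per-bird
coefficients by forest amount, connectivity and sex.

**Connectivity.** The Landscape Coincidence Probability index over forest
patches with a binary passibility rule (edge-to-edge distance ≤ 162 m, the
maximum observed gap crossing):

    CON = Σᵢ Σⱼ (aᵢ aⱼ c_ij / A_L²) × 100

plus a graph-component variant (c_ij = 1 within connected components).

**Home-range scale.** 95% LoCoH (k-method) home ranges; availability by a
rotation null model (polygon rotated 1°…359° about its centroid, forest %,
CON and mean patch size re-measured per rotation); paired Wilcoxon
signed-rank (exact by full enumeration up to n = 15) for forest selection; a
forest-matched (± 5 percentage points) connectivity contrast; and OLS of
log home-range area on forest %, mean patch size and sex.

**Synthetic data.** Seeded landscapes (clump-grown forest, riparian corridors
10–40 m wide along random-walk streams, ~90:5 pasture:other matrix), movement
simulated from the same step-selection model the pipeline fits (gamma step
lengths, von Mises turns, candidate choice ∝ exp(β·x), GPS noise), and
vegetation-plot pairs generated from the exact paired-logit model.

## Worked example

```python
import numpy as np
import trapliner as tl

cfg = tl.SimulationConfig(seed=11, gps_noise_sd=0.0, usable_fraction=1.0,
                          total_fixes=1000, n_birds=12, n_candidates=200)
lcmap, streams = tl.gen_landscape(cfg)            # 300x300 cells at 5 m
fixes, truth = tl.simulate_fixes(cfg, lcmap, streams)

steps = tl.resample_to_steps(tl.filter_and_dedupe(fixes))
pool = tl.synthetic.kernel_move_distributions(cfg)
strata, log = tl.build_strata(steps, lcmap, streams, seed=12,
                              covariates=("TotGap", "Stream"), pools=pool)
fit = tl.fit_conditional_logit(tl.assemble_design(strata, "Stream + TotGap"),
                               strata, model="Stream + TotGap")
print(fit.params[["coef", "se", "or"]].round(4))
```

prints

```
          coef      se      or
Stream -0.0213  0.0015  0.9789
TotGap -0.0195  0.0076  0.9807
```

The simulating coefficients were β_Stream = −0.020 and β_TotGap = −0.019 per
meter: both estimates sit within two standard errors of the truth, and the
odds ratios say each extra meter of gap (or of distance from a stream) along
a candidate step multiplies its selection odds by ≈ 0.98 — a 50-m gap roughly
halves to one-third the odds of a step being taken.

The same objects drive the CLI:
`trapliner simulate --seed 11 --out sim/`, then
`trapliner ssf --fixes sim/fixes.csv --landcover sim/landcover.asc
--streams sim/streams.geojson --seed 12 --out ssf/`.

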