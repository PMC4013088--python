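# Methods

This note documents the models, the numerical choices, and what the
synthetic tests do and do not demonstrate.

## Spatial model

All computation happens on one north-up grid of square cells in projected
metres (default 250 m; a cell is 0.0625 km²). Cells are half-open —
`[x, x+cs) × (y−cs, y]` with row 0 the northern edge — so a point on a
shared edge belongs to exactly one cell. Nodata is NaN in memory and is
excluded from every statistic; the only places nodata is read as 0 are the
ones the metric definitions require (binary presence before the diversity
products, and evenness on either side of ΔE). Geographic (degree) inputs
are not reprojected; coordinates are assumed projected. Rasters are
single-band float32 GeoTIFFs with ModelPixelScale/ModelTiepoint/GDAL_NODATA
tags written through `tifffile`; round-trips are value-exact for
float32-representable values.

## Predictors

Five bioclimatic summaries are computed from 12 monthly layers of minimum
temperature, maximum temperature (°C) and precipitation (mm):

| name | definition | units |
|---|---|---|
| Bio1 | mean over months of (tmax+tmin)/2 | °C |
| Bio2 | mean diurnal range, mean of (tmax−tmin) | °C |
| Bio4 | sample sd of monthly means × 100 | — |
| Bio12 | annual precipitation total | mm |
| Bio15 | 100 × sample sd of monthly precip / (1 + Bio12/12) | CV |

Bio12 is interpreted as the annual total (the standard bioclim reading of
an ambiguous "mean monthly annual precipitation" label); a
`bio12_mode="monthly_mean"` switch provides the other reading. Bio15 uses
the ANUCLIM-style (1 + mean) denominator so arid cells stay finite. All
standard deviations are sample (n−1) sd, matching common bioclim
implementations.

Two topographic indices come from a DEM: TRI (Riley), the root of the sum
of squared elevation differences to the eight neighbours (edge cells use
the neighbours that exist); and TRASP (Roberts–Cooper),
`(1 − cos(aspect − 30°))/2`, a 0–1 radiation load index that is 0 on cool
NNE slopes and 1 on hot SSW slopes. Aspect uses Horn's 3×3 finite
differences on an edge-replicated pad; flat cells have no aspect and get
the neutral value 0.5.

Collinearity screening computes pairwise Pearson r over cells valid in
both layers and greedily drops, among variables in a pair violating the
|r| < 0.63 bound, the one with the largest mean |r| to the remaining set.
A `forced_keep` list reproduces any expert-chosen set: forced pairs above
the bound are kept with a warning rather than dropped, because in practice
variable selection mixes the statistical screen with ecological judgment.

Future covariates use additive delta downscaling: the change between a
coarse simulated future and baseline is bilinearly interpolated to the
fine grid (clamped at the coarse cell-center hull) and added to the
observed baseline. Precipitation-flagged outputs are floored at 0; a
multiplicative mode exists for precipitation only.

## Per-species ensembles

Occurrences are thinned to one record per species per cell (first record
in input order wins — the choice is arbitrary but deterministic), because
presence-only modelling is Boolean and repeated collections would
otherwise act as weights. Pseudo-absences are the *target-group
background*: every thinned cell of every other species, minus cells
containing the focal species, one per cell and without subsampling. Since
all species were collected under the same spatially biased effort, this
puts the same bias in both classes and lets the learners see niche signal
rather than collection signal.

Each of `n_reps` replicates draws a stratified random 20/80 test/train
split and fits three learners: an L2-penalized logistic regression on
standardized covariates capped at 100 iterations (a maximum-entropy-style
learner), a 100-tree random forest, and a 100-tree gradient-boosted
classifier (scikit-learn implementations; the bespoke logic here is the
replicate design, evaluation, thresholding and weighting, not the tree
internals — tree-count selection by internal cross-validation in other
toolkits is not replicated). Held-out AUC uses the Mann–Whitney
formulation with ties counting ½. The presence/absence threshold is the
observed score minimizing |sensitivity − specificity|, ties broken by
larger TSS then by the lower threshold; TSS is evaluated at that
threshold. The production default is 500 replicates; tests and the
acceptance script run 10 (problem sizes are chosen so the full suite runs
in well under a minute of model fitting).

Replicates with AUC strictly above 0.5 (no better than random) enter the
ensembles. The weighted mean uses weights proportional to AUC (linear
weighting; `weight_mode` documents the choice). The committee average is
the mean of member binary maps, each at its own threshold, and doubles as
an agreement map. The ensemble's own threshold is *recomputed* on the
weighted-mean scores at the training presences and pseudo-absences —
whether to recompute or inherit is genuinely open, and recomputing keeps
the threshold consistent with the surface it binarizes. Future projection
re-predicts the fitted members on the future covariates, keeping weights
and thresholds from the baseline fit, as a fitted niche model is normally
projected.

Variable importance is permutation-based: 1 − Pearson r between reference
predictions and predictions with one covariate's column shuffled, averaged
over shuffles and clipped at 0. Response curves sweep one covariate over
its observed range with the others held at their medians.

## Niche overlap

Warren's *I* normalizes each suitability surface to sum to 1 over shared
valid cells and computes `1 − ½ Σ(√p₁ − √p₂)²`; it is symmetric and
invariant to positive rescaling. The equivalency test refits both models
on pooled, randomly repartitioned occurrences and compares observed *I*
one-tailed against the null: `p = (1 + #{I_null ≤ I_obs}) / (n_reps + 1)`,
with rejection when observed overlap is *low* (Warren's convention; the
direction is a documented choice). Two departures from the main pipeline
keep the test desk-scale and well-defined: the refits use a reduced
configuration (by default one replicate of the logistic learner), and the
background is a seeded random sample of grid cells shared by all fits —
the target-group background is degenerate inside a two-species test when
the sets coincide (each species' background would be empty). The observed
models use the same reduced configuration so observed and null *I* are
comparable.

## Diversity and invasibility

With scaled suitability `sᵢ` (min–max rescaled weighted mean, so each
species spans [0, 1]) and binary presence `Bᵢ` (nodata read as 0):

* `pᵢ = sᵢBᵢ / Σⱼ sⱼBⱼ` where the denominator is positive, the species'
  share of presence-masked suitability — suitability standing in for
  relative abundance, the metric's central assumption;
* `H = −Σ pᵢ ln pᵢ` (natural log), nodata where no species is present;
* `S` is **global**: the number of species with ≥1 presence cell in the
  extent. Then `E = H / ln S ∈ [0, 1]` everywhere H is defined. A per-cell
  S mode exists, with E defined 0 where a single species is present; the
  global reading keeps E comparable across cells.
* `ΔE = E_future − E_baseline` with nodata read as 0 on both sides, so −1
  marks currently even, highly invasible habitat with no future
  suitability. (Future minus baseline is the adopted sign convention.)
* `AII = E_baseline + max(ΔE, 0)`, identically `max(E_baseline, E_future)`
  cell-wise — only gains accumulate, on the assumption that degraded
  habitat does not revert.

**Area accounting for E and AII** counts cells where the metric is
*defined* (≥1 species present in the relevant scenario(s)), not where it
is positive: evenness is exactly 0 in genuinely invaded single-species
cells, so positivity would undercount invaded area. The jackknife uses the
same rule: a species' contribution is the fraction of invasible cells
(union over species and scenarios) that it alone accounts for, clipped at
0. Contributions sum to 1 exactly for fully disjoint species and to less
under overlap. This area-based leave-one-out is the operational form of
"proportion of novel habitat per species"; a per-pixel significance test
would need a distributional model the metric does not define.

Summary tables report per-species and per-metric areas (km²) and
proportions over declared extent and focus-region denominators, rounded to
2 decimals for presentation with full precision retained internally;
future-area ranks are computed on unrounded areas with ties broken by
name. The packaged Hawaiian reference tables (17 species; published area
summaries; 16,677 km² and 3,000 km² denominators) drive arithmetic checks
and worked examples.

## Synthetic landscapes

The generator emulates the structure of a real multi-species invasion
dataset: Gaussian-smoothed standardized random fields as covariates
(default range 10 cells on a 100×100 grid); virtual species with logistic
niches `1/(1+exp(−(β₀ + Σβx)/breadth))`; one shared collection-effort
surface (`exp(1.5 ×` smooth field`)`) so all species' samples carry the
same bias; occurrences drawn without replacement with probability ∝
suitability × effort; a full-extent study mask and a contiguous
sub-region mask; and a future stack built through the same
delta-downscaling code path real coarse simulations would take.

The default species set is three distinct single-driver guilds — warm
(Bio1 +5), wet (Bio12 +5) and dry (Bio12 −5), each with intercept −2 so
presences concentrate in an environmental tail — emulating invaders drawn
from dissimilar habitats whose models are expected to be discriminative.
The guild geometry also matters for the background: with few species, a
focal species' target-group background inherits the *other* species' niche
leans, and if those leans align with the climate-shift axis the fitted
model acquires a spurious sensitivity to the shifted covariate. Placing
the wet/dry pair symmetrically off the warming axis keeps each background
balanced in Bio1. Sample sizes are unequal (150/300/200; collection effort
follows management priority, not range size) and the warming scenario
shifts Bio1 by +0.5 sd — comparable to a few degrees of end-of-century
warming against the spatial temperature spread of a high-relief island.
All randomness fans out from one root seed via `SeedSequence`, so the
landscape is invariant to changes in the species list.

**What the synthetic tests show and don't.** Passing recovery tests
(median held-out AUC > 0.8 and TSS > 0.5 per species; Spearman ρ ≥ 0.8
between ensemble and true suitability; ΔE gains enriched in cells that
newly enter a true niche; jackknife equal to an independent set-based
unique-area count) demonstrates that the pipeline is internally correct
and can recover known niches under realistic sampling bias. They do not
demonstrate performance on real data: virtual niches are exactly logistic
in the covariates (no interactions, thresholds or dispersal limits),
occurrences are independent draws (no spatial clustering beyond effort and
suitability), and covariates are stationary Gaussian fields. Recovery
statistics fluctuate across landscape realizations; the test suite pins
one seed and the acceptance script reports whatever its seed produces.

## Numerical notes and limitations

* Thresholds come from finite candidate sets (observed scores), so
  sensitivity = specificity holds only to within one rank step.
* Warren's *I* is clipped into [0, 1] against floating-point drift.
* Zero-variance layers yield NaN correlations and are never silently
  dropped; constant suitability cannot be min–max rescaled and errors.
* `evenness` requires S ≥ 2 (ln S must be positive).
* The equivalency test's p-value is bounded below by 1/(n_reps+1); 30
  null replicates resolve p = 0.032 at best.
* Reprojection, multi-resolution mosaicking, KML export, dispersal and
  demographic dynamics are out of scope.
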