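# invasimap

Stacked ensemble species distribution models (SDMs) and invasibility metrics
for multi-species invasion risk mapping.

## The problem

Conservation managers facing a suite of ecosystem-modifying invasive plants
need to know not just where each invader can live today, but where the
*community* of invaders can establish — now and under a changed climate.
`invasimap` implements a complete pipeline for that question, built around
the Hawaiian archipelago use case (17 high-risk invasive plants, 250 m
grid, a regional end-of-century warming scenario) but applicable to any
projected-metre landscape:

1. **Per-species ensembles.** For each species, occurrences are thinned to
   one point per grid cell and contrasted against a *target-group
   background* — the cells where any *other* surveyed species was recorded —
   so the shared collection bias cancels. Repeated random 20/80 test/train
   splits feed three learners (a maximum-entropy-style penalized logistic
   model, random forests, and boosted trees, 100 trees each). Replicates
   scoring held-out AUC > 0.5 enter two ensembles: the AUC-weighted mean
   suitability and the committee average of thresholded binary maps. Each
   map is thresholded where sensitivity = specificity.
2. **Niche overlap screening.** Warren's *I* between suitability surfaces,
   `I = 1 − ½ Σ(√p₁ − √p₂)²`, with a randomization equivalency test
   (pool both species' occurrences, repartition, refit).
3. **Diversity stacking.** With rescaled suitability *sᵢ* ∈ [0, 1] and binary
   presence *Bᵢ*, each cell gets shares `pᵢ = sᵢBᵢ / Σⱼ sⱼBⱼ`, Shannon
   diversity `H = −Σ pᵢ ln pᵢ`, and evenness `E = H / ln S` where *S* is the
   number of species present in the extent.
4. **Invasibility under climate change.** Future covariates come from delta
   downscaling (coarse simulated change added to the fine baseline). The
   change metric is `ΔE = E_future − E_baseline`, and the **Additive
   Invasibility Index** `AII = E_baseline + max(ΔE, 0)` — equivalently the
   cell-wise max of the two evenness surfaces — assumes degraded habitat
   does not revert. A leave-one-out jackknife attributes invasible area to
   individual species, and area/proportion summaries are reported over the
   full extent and a "critical habitat" region mask.

A seeded synthetic-landscape generator (smooth covariates, virtual species
with known logistic niches, a shared biased collection-effort surface, a
configurable warming shift) makes the whole pipeline testable against
ground truth without any external data.

## Worked example

```python
import invasimap as iv
from invasimap.reporting import project_ensemble
from invasimap.invasibility_metrics import invasibility_analysis

scenario = iv.generate_scenario(seed=7)          # 3 virtual species, 100x100 grid
occ = iv.thin_to_grid(scenario.occurrences, scenario.grid)

ens_b, ens_f = [], []
for i, sp in enumerate(scenario.species):
    em = iv.fit_species_ensemble(occ, sp.species_code, scenario.baseline,
                                 n_reps=10, seed=100 + i)
    ens_b.append(em)
    ens_f.append(project_ensemble(em, scenario.future))

div_b, div_f, aii = invasibility_analysis(ens_b, ens_f)
print(div_b.S_global, round(float(aii.delta_e.values.max()), 3))
print(aii.jackknife)
```

prints

```
3 0.631
   species  contribution
0  WarmSpe      0.309358
1  DrySpec      0.233404
2  WetSpec      0.194419
```

i.e. all three species are present in the baseline extent, the largest
cell-level evenness gain under the warming scenario is +0.63, and the
warm-adapted species uniquely accounts for ~31 % of the invasible area,
with smaller unique shares for the dry and wet specialists. The same
pipeline runs from a TOML config on the command line:

```bash
invasimap run --config cfg.toml --seed 42 --out artifacts/
```

writing suitability/diversity GeoTIFFs, the overlap matrix, the jackknife
table, the area summary and a manifest.

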