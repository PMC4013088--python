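"""Seeded synthetic test worlds: covariates, virtual species, biased sampling,
region masks and a warming scenario.

The generator emulates the structure of a real multi-species invasion study:

* spatially autocorrelated environmental covariates (smoothed Gaussian noise,
  standardized to mean 0, sd 1 per layer);
* virtual species with known logistic niches of varying breadth, so the
  true suitability surface is available to validate recovery;
* one shared collection-effort surface, so every species' occurrence sample
  carries the same spatial bias — the situation target-group pseudo-absences
  are meant to correct;
* a future scenario built by adding a coarse simulated climate shift to the
  baseline through the same delta-downscaling path real inputs would take;
* a study-extent mask and a smaller "critical habitat" sub-region mask.

It does not simulate dispersal, demography, or temporal spread; occurrences
are independent draws weighted by suitability x effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .covariates import CovariateStack, delta_downscale
from .geo_core import Grid, OccurrenceTable, RasterLayer, RegionMask


@dataclass
class VirtualSpecies:
    """A species with a known logistic niche over named covariates.

    true suitability(x) = 1 / (1 + exp(-(intercept + sum coef_j * cov_j(x)) / breadth))

    ``niche_breadth`` > 1 flattens the response (a generalist); < 1 sharpens it.
    """

    species_code: str
    coefficients: dict[str, float]
    intercept: float = 0.0
    niche_breadth: float = 1.0

    def __post_init__(self) -> None:
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be positive")

    def true_suitability(self, stack: CovariateStack) -> RasterLayer:
        eta = np.full(stack.grid.shape, self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            eta = eta + coef * stack[name].values
        s = 1.0 / (1.0 + np.exp(-eta / self.niche_breadth))
        return RasterLayer(stack.grid, s, name=f"true_{self.species_code}")


@dataclass
class SamplingEffort:
    """Non-negative collection-effort surface shared by all species."""

    effort: RasterLayer

    def __post_init__(self) -> None:
        vals = self.effort.filled(0.0)
        if np.any(vals < 0):
            raise ValueError("effort must be non-negative")
        if vals.sum() <= 0:
            raise ValueError("effort must be positive somewhere")


def _smooth_field(grid: Grid, spatial_range: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(grid.shape)
    fld = gaussian_filter(noise, sigma=spatial_range, mode="reflect")
    sd = fld.std()
    if sd == 0:
        return np.zeros(grid.shape)
    return (fld - fld.mean()) / sd


def generate_covariates(
    grid: Grid,
    n_layers: int = 7,
    spatial_range: float = 15.0,
    seed: int = 0,
    names: list[str] | None = None,
) -> CovariateStack:
    """Smooth standardized random fields as a covariate stack.

    Each layer is white noise convolved with a Gaussian kernel of width
    ``spatial_range`` (in cells) and standardized to mean 0, sd 1. With seven
    layers the standard predictor names are used so the stack is a drop-in
    for the real one. Deterministic given ``seed``.
    """
    if spatial_range < 1:
        raise ValueError("spatial_range must be >= 1 cell")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if names is None:
        if n_layers == 7:
            names = ["Bio1", "Bio2", "Bio4", "Bio12", "Bio15", "TRI", "TRASP"]
        else:
            names = [f"cov{i + 1:02d}" for i in range(n_layers)]
    if len(names) != n_layers:
        raise ValueError("names length must equal n_layers")
    rng = np.random.default_rng(seed)
    layers = {
        name: RasterLayer(grid, _smooth_field(grid, spatial_range, rng), name)
        for name in names
    }
    return CovariateStack(layers)


def generate_effort(grid: Grid, spatial_range: float = 20.0, seed: int = 0) -> SamplingEffort:
    """A smooth, strictly positive, spatially biased effort surface."""
    rng = np.random.default_rng(seed)
    fld = _smooth_field(grid, spatial_range, rng)
    return SamplingEffort(RasterLayer(grid, np.exp(1.5 * fld), "effort"))


def sample_occurrences(
    species: VirtualSpecies,
    stack: CovariateStack,
    effort: SamplingEffort,
    n: int,
    seed: int,
) -> OccurrenceTable:
    """Draw ``n`` occurrence cells without replacement, P(cell) ∝ suitability x effort.

    One point per sampled cell, placed at the cell center (the thinned-grid
    representation real collections are reduced to). Deterministic given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    suit = species.true_suitability(stack).values
    w = np.where(np.isfinite(suit), suit, 0.0) * effort.effort.filled(0.0)
    w = w.ravel()
    n_positive = int((w > 0).sum())
    if n > n_positive:
        raise ValueError(
            f"requested {n} occurrences but only {n_positive} cells have positive weight"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(w.size, size=n, replace=False, p=w / w.sum())
    rows, cols = np.unravel_index(idx, stack.grid.shape)
    xs = stack.grid.origin_x + (cols + 0.5) * stack.grid.cell_size
    ys = stack.grid.origin_y - (rows + 0.5) * stack.grid.cell_size
    df = pd.DataFrame({"species": species.species_code, "x": xs, "y": ys})
    return OccurrenceTable(df, thinned=False)


@dataclass
class ScenarioConfig:
    """Parameters of a complete synthetic study.

    Defaults give a 100 x 100 grid of 250 m cells, seven smooth covariates,
    and three virtual species with distinct single-driver niches — warm-,
    wet- and dry-adapted moisture/temperature guilds, emulating species
    drawn from dissimilar habitats whose models are expected to be
    discriminative, and whose pooled occurrences give each focal species a
    target-group background that spans the climate space evenly. Sample
    sizes are unequal (collection effort varies by management priority, not
    by range size), and the future scenario applies a +0.5 sd warming shift
    on Bio1 through a coarse 10 x 10 simulation grid — comparable to an
    end-of-century warming of a few degrees against the spatial temperature
    spread of a high-relief island landscape.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 250.0
    n_layers: int = 7
    spatial_range: float = 10.0
    effort_range: float = 20.0
    species: list[VirtualSpecies] = field(default_factory=lambda: [
        VirtualSpecies("WarmSpe", {"Bio1": 5.0}, intercept=-2.0),
        VirtualSpecies("WetSpec", {"Bio12": 5.0}, intercept=-2.0),
        VirtualSpecies("DrySpec", {"Bio12": -5.0}, intercept=-2.0),
    ])
    n_occurrences: dict[str, int] = field(
        default_factory=lambda: {"WarmSpe": 150, "WetSpec": 300, "DrySpec": 200}
    )
    shift: dict[str, float] = field(default_factory=lambda: {"Bio1": 0.5})
    coarse_factor: int = 10  # coarse simulation grid is shape/coarse_factor


@dataclass
class Scenario:
    """A generated study world, including the ground truth."""

    grid: Grid
    baseline: CovariateStack
    future: CovariateStack
    species: list[VirtualSpecies]
    occurrences: OccurrenceTable
    effort: SamplingEffort
    masks: dict[str, RegionMask]
    seed: int

    def true_suitability(self, code: str, scenario: str = "baseline") -> RasterLayer:
        sp = next(s for s in self.species if s.species_code == code)
        stack = self.baseline if scenario == "baseline" else self.future
        return sp.true_suitability(stack)


def generate_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> Scenario:
    """Build a full reproducible test world from one root seed.

    The root seed is fanned out deterministically: covariates, the effort
    surface, each species' occurrence sample and the mask geometry all get
    independent child seeds, so changing the species list does not perturb
    the landscape.
    """
    config = config or ScenarioConfig()
    grid = Grid(config.n_rows, config.n_cols, config.cell_size)
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(3 + len(config.species))
    seed_cov = int(child[0].generate_state(1)[0] % 2**31)
    seed_eff = int(child[1].generate_state(1)[0] % 2**31)
    seed_mask = int(child[2].generate_state(1)[0] % 2**31)

    baseline = generate_covariates(
        grid, config.n_layers, config.spatial_range, seed=seed_cov
    )
    effort = generate_effort(grid, config.effort_range, seed=seed_eff)

    # future climate through the same delta path real coarse simulations take
    coarse = Grid(
        max(2, config.n_rows // config.coarse_factor),
        max(2, config.n_cols // config.coarse_factor),
        config.cell_size * config.coarse_factor,
        grid.origin_x,
        grid.origin_y,
    )
    future_layers = {}
    for name, lyr in baseline.layers.items():
        delta = config.shift.get(name, 0.0)
        sim_base = RasterLayer(coarse, np.zeros(coarse.shape), f"sim_base_{name}")
        sim_future = RasterLayer(coarse, np.full(coarse.shape, delta), f"sim_future_{name}")
        future_layers[name] = delta_downscale(lyr, sim_base, sim_future)
    future = CovariateStack(future_layers)

    # occurrences: all species share the one effort surface
    tables = []
    for i, sp in enumerate(config.species):
        n = config.n_occurrences.get(sp.species_code)
        if n is None:
            raise ValueError(f"no sample size configured for {sp.species_code}")
        sp_seed = int(child[3 + i].generate_state(1)[0] % 2**31)
        tables.append(sample_occurrences(sp, baseline, effort, n, sp_seed))
    occ = OccurrenceTable(
        pd.concat([t.records for t in tables], ignore_index=True), thinned=False
    )

    # masks: full study extent plus a contiguous "critical habitat" sub-region
    study = RegionMask("study_area", RasterLayer(grid, np.ones(grid.shape), "study_area"))
    rng = np.random.default_rng(seed_mask)
    ch = np.zeros(grid.shape)
    h = max(2, grid.n_rows // 3)
    w = max(2, grid.n_cols // 3)
    r0 = int(rng.integers(0, grid.n_rows - h + 1))
    c0 = int(rng.integers(0, grid.n_cols - w + 1))
    ch[r0 : r0 + h, c0 : c0 + w] = 1.0
    critical = RegionMask("critical_habitat", RasterLayer(grid, ch, "critical_habitat"))

    return Scenario(
        grid=grid,
        baseline=baseline,
        future=future,
        species=list(config.species),
        occurrences=occ,
        effort=effort,
        masks={"study_area": study, "critical_habitat": critical},
        seed=seed,
    )
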