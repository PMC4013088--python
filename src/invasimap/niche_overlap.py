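"""Warren's I niche overlap and the randomization-based equivalency test.

Warren's I compares two suitability surfaces after normalizing each to sum
to one over valid cells, via the Hellinger distance:

    I = 1 - 1/2 * sum_cells (sqrt(p1) - sqrt(p2))^2

so 0 means disjoint suitability and 1 identical (up to positive rescaling).

The equivalency test asks whether two species' modelled niches are more
different than expected if their occurrences were exchangeable: pool both
occurrence sets, randomly repartition into the original sizes, refit both
models, and recompute I. Observed I is compared one-tailed against this
null — niches are declared non-equivalent when the observed overlap is LOW
relative to the null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CovariateStack
from .geo_core import OccurrenceTable, RasterLayer, thin_to_grid
from .sdm_ensemble import TrainingSet, ensemble, fit_replicates


@dataclass
class OverlapResult:
    """Observed overlap, null distribution, and the one-tailed p-value."""

    species_a: str
    species_b: str
    i_value: float
    p_value: float
    null_values: list[float]
    n_reps: int

    @property
    def equivalent(self) -> bool:
        """Niches are treated as equivalent when p > 0.05."""
        return self.p_value > 0.05


def warrens_i(s1: RasterLayer, s2: RasterLayer) -> float:
    """Warren's I between two suitability layers on one grid.

    Each surface is normalized internally to sum to 1 over cells valid in
    both layers; the statistic is invariant to positive rescaling.
    """
    if s1.grid != s2.grid:
        raise ValueError("suitability layers must share a grid")
    valid = s1.valid & s2.valid
    v1 = s1.values[valid]
    v2 = s2.values[valid]
    if np.any(v1 < 0) or np.any(v2 < 0):
        raise ValueError("suitability values must be non-negative")
    t1, t2 = v1.sum(), v2.sum()
    if t1 <= 0 or t2 <= 0:
        raise ValueError("cannot normalize an all-zero suitability layer")
    p1 = v1 / t1
    p2 = v2 / t2
    i_val = 1.0 - 0.5 * np.sum((np.sqrt(p1) - np.sqrt(p2)) ** 2)
    return float(min(1.0, max(0.0, i_val)))


@dataclass
class OverlapFitConfig:
    """Reduced fitting settings for the (many) refits inside the null.

    One hundred full 500-replicate ensembles per species pair is not a
    desk-scale computation; the null refits use few replicates and, by
    default, the fast penalized-logistic learner only. The observed models
    use the same settings so observed and null I are computed on equal
    footing.
    """

    learners: tuple = ("maxent",)
    n_reps: int = 1
    split: float = 0.2
    inclusion_auc: float = 0.0
    n_background: int = 800


def _fit_surface(
    cells: np.ndarray,
    background: np.ndarray,
    stack: CovariateStack,
    cfg: OverlapFitConfig,
    seed: int,
    code: str,
) -> RasterLayer:
    """Fit one reduced model from presence cells and shared background cells."""
    pres_set = set(map(tuple, cells))
    bg = np.array([c for c in map(tuple, background) if c not in pres_set], dtype=int)
    Xp = stack.as_matrix(cells[:, 0], cells[:, 1])
    Xa = stack.as_matrix(bg[:, 0], bg[:, 1])
    ok_p = np.isfinite(Xp).all(axis=1)
    ok_a = np.isfinite(Xa).all(axis=1)
    ts = TrainingSet(
        species_code=code,
        presence=cells[ok_p],
        pseudo_absence=bg[ok_a],
        X=np.vstack([Xp[ok_p], Xa[ok_a]]),
        y=np.concatenate([np.ones(ok_p.sum()), np.zeros(ok_a.sum())]),
        covariate_names=stack.names,
    )
    reps = fit_replicates(
        ts, stack, n_reps=cfg.n_reps, split=cfg.split, seed=seed, learners=cfg.learners
    )
    return ensemble(reps, ts, inclusion_auc=cfg.inclusion_auc).weighted_mean


def equivalency_test(
    occ_a: OccurrenceTable,
    occ_b: OccurrenceTable,
    stack: CovariateStack,
    fit_config: OverlapFitConfig | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> OverlapResult:
    """Niche equivalency test for two species.

    Observed I comes from models fit to the true occurrence partitions; the
    null repartitions the pooled occurrences into the original sizes and
    refits. One-tailed p = (1 + #{null I <= observed I}) / (n_reps + 1).

    Background cells are a seeded random sample of valid grid cells shared by
    every fit (a target-group background drawn only from the pair itself is
    degenerate when the two sets coincide).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = fit_config or OverlapFitConfig()
    grid = stack.grid
    code_a = occ_a.records["species"].iloc[0]
    code_b = occ_b.records["species"].iloc[0]

    def cells_of(occ: OccurrenceTable) -> np.ndarray:
        t = occ if occ.thinned else thin_to_grid(occ, grid)
        from .geo_core import occurrence_cells

        return occurrence_cells(t, grid)[["row", "col"]].to_numpy()

    cells_a = cells_of(occ_a)
    cells_b = cells_of(occ_b)
    n_a, n_b = len(cells_a), len(cells_b)
    if min(n_a, n_b) < 5:
        raise ValueError("each species needs >= 5 thinned presence cells")

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2 * n_reps + 3)]
    rng = np.random.default_rng(seeds[0])

    valid_rows, valid_cols = np.nonzero(stack.valid_mask())
    n_bg = min(cfg.n_background, len(valid_rows))
    bg_idx = rng.choice(len(valid_rows), size=n_bg, replace=False)
    background = np.column_stack([valid_rows[bg_idx], valid_cols[bg_idx]])

    sa = _fit_surface(cells_a, background, stack, cfg, seeds[1], code_a)
    sb = _fit_surface(cells_b, background, stack, cfg, seeds[2], code_b)
    observed = warrens_i(sa, sb)

    pooled = np.vstack([cells_a, cells_b])
    if len(pooled) < n_a + n_b:
        raise ValueError("pooled occurrence set smaller than n_a + n_b")
    null_values: list[float] = []
    for r in range(n_reps):
        perm = np.random.default_rng(seeds[3 + 2 * r]).permutation(len(pooled))
        na_cells = pooled[perm[:n_a]]
        nb_cells = pooled[perm[n_a : n_a + n_b]]
        s1 = _fit_surface(na_cells, background, stack, cfg, seeds[3 + 2 * r], "null_a")
        s2 = _fit_surface(nb_cells, background, stack, cfg, seeds[4 + 2 * r], "null_b")
        null_values.append(warrens_i(s1, s2))

    p = (1 + sum(nv <= observed for nv in null_values)) / (n_reps + 1)
    return OverlapResult(
        species_a=code_a,
        species_b=code_b,
        i_value=observed,
        p_value=float(p),
        null_values=null_values,
        n_reps=n_reps,
    )


def overlap_matrix(
    surfaces: dict[str, RasterLayer],
    results: list[OverlapResult] | None = None,
) -> pd.DataFrame:
    """Pairwise matrix: lower triangle Warren's I, upper triangle p-values.

    ``results`` (optional equivalency outcomes) fill the upper triangle;
    pairs without a test stay NaN there. Diagonal is 1.
    """
    codes = list(surfaces)
    mat = pd.DataFrame(np.nan, index=codes, columns=codes)
    for i, a in enumerate(codes):
        mat.loc[a, a] = 1.0
        for b in codes[i + 1 :]:
            mat.loc[b, a] = warrens_i(surfaces[a], surfaces[b])
    for res in results or ():
        a, b = res.species_a, res.species_b
        if a in codes and b in codes:
            hi, lo = (a, b) if codes.index(a) < codes.index(b) else (b, a)
            mat.loc[hi, lo] = res.p_value
    return mat
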