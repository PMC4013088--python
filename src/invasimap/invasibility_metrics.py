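"""Stacked diversity and invasibility metrics.

Per-species ensembles are stacked into threshold-dependent diversity layers
and a change metric:

* each species' weighted-mean suitability is min-max rescaled to [0, 1] (s_i)
  and paired with its thresholded binary presence (B_i, nodata read as 0);
* p_i = s_i B_i / sum_j s_j B_j at cells where at least one species is
  present — the species' share of summed, presence-masked suitability,
  standing in for relative abundance;
* Shannon diversity H = -sum_{p_i > 0} p_i ln p_i (natural log);
* S is the number of species present anywhere in the extent, and evenness
  E = H / ln S, in [0, 1];
* Delta E = future E - baseline E (nodata read as 0 on either side);
* the Additive Invasibility Index AII = baseline E + max(Delta E, 0), which
  is identically the cell-wise max of the two evenness surfaces — habitat
  already degraded is assumed not to revert, so only gains accumulate.

A leave-one-out jackknife attributes to each species the fraction of
invasible (metric-defined) cells that it alone accounts for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_core import RasterLayer
from .sdm_ensemble import EnsembleModel


@dataclass
class ScaledSuitability:
    """Min-max rescaled suitability for one species, in [0, 1]."""

    species_code: str
    s: RasterLayer


@dataclass
class BinaryPresence:
    """Thresholded presence for one species; nodata replaced by 0."""

    species_code: str
    B: RasterLayer

    def __post_init__(self) -> None:
        vals = self.B.filled(0.0)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError(f"{self.species_code}: binary presence must be 0/1")


@dataclass
class DiversityLayers:
    """Per-scenario diversity bundle: p_i shares, H, global S and E."""

    p_shares: dict[str, RasterLayer]
    H: RasterLayer
    S_global: int
    E: RasterLayer
    scenario: str = "baseline"

    def defined(self) -> np.ndarray:
        """Cells where the metric is defined (>= 1 species present)."""
        return self.H.valid


@dataclass
class AIIResult:
    """Evenness change and the Additive Invasibility Index."""

    delta_e: RasterLayer
    aii: RasterLayer
    jackknife: pd.DataFrame


def rescale_suitability(em: EnsembleModel) -> ScaledSuitability:
    """Min-max rescale the weighted-mean ensemble to [0, 1] over valid cells."""
    vals = em.weighted_mean.values
    finite = vals[np.isfinite(vals)]
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise ValueError(f"{em.species_code}: constant suitability cannot be rescaled")
    return ScaledSuitability(
        em.species_code,
        em.weighted_mean.with_values((vals - lo) / (hi - lo), f"{em.species_code}_scaled"),
    )


def binary_presence(em: EnsembleModel) -> BinaryPresence:
    """The ensemble's thresholded binary map with nodata read as absence."""
    return BinaryPresence(
        em.species_code,
        em.binary.with_values(em.binary.filled(0.0), f"{em.species_code}_B"),
    )


def richness(scaled: list[ScaledSuitability]) -> RasterLayer:
    """Threshold-independent potential richness: cell-wise sum of s_i."""
    if not scaled:
        raise ValueError("need at least one species")
    grid = scaled[0].s.grid
    total = np.zeros(grid.shape)
    for sp in scaled:
        total = total + sp.s.filled(0.0)
    return RasterLayer(grid, total, "richness")


def _presence_weighted(scaled, binary) -> tuple[list[str], np.ndarray, np.ndarray]:
    codes_s = [sp.species_code for sp in scaled]
    codes_b = [bp.species_code for bp in binary]
    if codes_s != codes_b:
        raise ValueError("scaled and binary species lists must match in order")
    sB = np.stack([sp.s.filled(0.0) * bp.B.filled(0.0) for sp, bp in zip(scaled, binary)])
    return codes_s, sB, sB.sum(axis=0)


def shannon_h(
    scaled: list[ScaledSuitability], binary: list[BinaryPresence], scenario: str = "baseline"
) -> DiversityLayers:
    """p_i shares and Shannon H; cells with no species present are nodata.

    Undefined suitability under a presence cell contributes 0 to both the
    numerator and the denominator (all undefined values are read as 0 before
    the raster products are taken).
    """
    codes, sB, denom = _presence_weighted(scaled, binary)
    grid = scaled[0].s.grid
    any_present = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(any_present, sB / np.where(any_present, denom, 1.0), np.nan)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    H = np.where(any_present, -plogp.sum(axis=0), np.nan)
    p_shares = {
        code: RasterLayer(grid, p[i], f"p_{code}") for i, code in enumerate(codes)
    }
    return DiversityLayers(
        p_shares=p_shares,
        H=RasterLayer(grid, H, f"H_{scenario}"),
        S_global=species_count_S(binary),
        E=RasterLayer(grid, np.full(grid.shape, np.nan), f"E_{scenario}"),
        scenario=scenario,
    )


def species_count_S(binary: list[BinaryPresence], mode: str = "global"):
    """Species count S: global (default) or a per-cell richness layer.

    Global S counts species with at least one presence cell anywhere in the
    extent — the denominator ln S then keeps evenness in [0, 1] wherever H is
    defined.
    """
    if mode == "global":
        return int(sum(bp.B.filled(0.0).sum() > 0 for bp in binary))
    if mode == "per_cell":
        grid = binary[0].B.grid
        total = np.zeros(grid.shape)
        for bp in binary:
            total = total + bp.B.filled(0.0)
        return RasterLayer(grid, total, "S_per_cell")
    raise ValueError(f"unknown mode {mode!r}")


def evenness(H: RasterLayer, S: int) -> RasterLayer:
    """Evenness E = H / ln S, in [0, 1]; requires a global S of at least 2."""
    if S < 2:
        raise ValueError(f"evenness needs S >= 2 (ln S must be positive), got S={S}")
    return H.with_values(H.values / np.log(S), H.name.replace("H", "E", 1) or "E")


def diversity_layers(
    scaled: list[ScaledSuitability], binary: list[BinaryPresence], scenario: str = "baseline"
) -> DiversityLayers:
    """Full per-scenario bundle: p_i, H, global S and E in one call."""
    div = shannon_h(scaled, binary, scenario)
    div.E = evenness(div.H, div.S_global)
    div.E.name = f"E_{scenario}"
    return div


def evenness_delta(e_future: RasterLayer, e_baseline: RasterLayer) -> RasterLayer:
    """Delta E = future E - baseline E, reading nodata as 0 on either side.

    -1 marks currently even, highly invasible habitat with no future
    suitability; +1 the largest gains.
    """
    if e_future.grid != e_baseline.grid:
        raise ValueError("evenness layers must share a grid")
    delta = e_future.filled(0.0) - e_baseline.filled(0.0)
    return RasterLayer(e_baseline.grid, delta, "delta_E")


def additive_invasibility(e_baseline: RasterLayer, delta: RasterLayer) -> RasterLayer:
    """AII = baseline E + max(Delta E, 0); equals max(baseline E, future E).

    Only gains are added: degraded habitat is assumed not to revert even
    where projected suitability declines.
    """
    if e_baseline.grid != delta.grid:
        raise ValueError("layers must share a grid")
    aii = e_baseline.filled(0.0) + np.maximum(delta.values, 0.0)
    return RasterLayer(e_baseline.grid, aii, "AII")


def invaded_cells(
    binary_baseline: list[BinaryPresence], binary_future: list[BinaryPresence]
) -> np.ndarray:
    """Cells where the invasibility metric is defined: >= 1 species present
    in either scenario (evenness can be exactly 0 with one species present,
    so area accounting uses definedness, not positivity)."""
    grid = binary_baseline[0].B.grid
    present = np.zeros(grid.shape, dtype=bool)
    for bp in list(binary_baseline) + list(binary_future):
        present |= bp.B.filled(0.0) == 1.0
    return present


def jackknife_contribution(
    binary_baseline: list[BinaryPresence],
    binary_future: list[BinaryPresence],
    species: str,
) -> float:
    """Leave-one-out share of invasible area uniquely due to one species.

    contribution_j = [area(defined, all species) - area(defined, without j)]
                     / area(defined, all species), clipped at 0 — the
    proportion of invasible cells that only species j occupies (in either
    scenario). Contributions over species sum to 1 exactly when presences
    are fully disjoint, and to less when they overlap.
    """
    codes = [bp.species_code for bp in binary_baseline]
    if species not in codes:
        raise KeyError(f"species {species!r} not in the binary stacks")
    all_cells = invaded_cells(binary_baseline, binary_future)
    total = float(all_cells.sum())
    if total == 0:
        raise ValueError("no invasible cells in either scenario")
    wb = [bp for bp in binary_baseline if bp.species_code != species]
    wf = [bp for bp in binary_future if bp.species_code != species]
    if not wb:
        raise ValueError("jackknife needs at least 2 species")
    without = float(invaded_cells(wb, wf).sum())
    return max(0.0, (total - without) / total)


def jackknife_table(
    binary_baseline: list[BinaryPresence], binary_future: list[BinaryPresence]
) -> pd.DataFrame:
    """Jackknife contributions for every species, sorted descending."""
    codes = [bp.species_code for bp in binary_baseline]
    rows = [
        {"species": c, "contribution": jackknife_contribution(binary_baseline, binary_future, c)}
        for c in codes
    ]
    return (
        pd.DataFrame(rows).sort_values("contribution", ascending=False).reset_index(drop=True)
    )


def invasibility_analysis(
    ensembles_baseline: list[EnsembleModel],
    ensembles_future: list[EnsembleModel],
) -> tuple[DiversityLayers, DiversityLayers, AIIResult]:
    """End-to-end stacking: ensembles -> diversity layers -> Delta E and AII."""
    scaled_b = [rescale_suitability(em) for em in ensembles_baseline]
    scaled_f = [rescale_suitability(em) for em in ensembles_future]
    bin_b = [binary_presence(em) for em in ensembles_baseline]
    bin_f = [binary_presence(em) for em in ensembles_future]
    div_b = diversity_layers(scaled_b, bin_b, "baseline")
    div_f = diversity_layers(scaled_f, bin_f, "future")
    delta = evenness_delta(div_f.E, div_b.E)
    aii = additive_invasibility(div_b.E, delta)
    jk = jackknife_table(bin_b, bin_f)
    return div_b, div_f, AIIResult(delta_e=delta, aii=aii, jackknife=jk)
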