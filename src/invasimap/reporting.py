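"""Area and proportion summaries over region masks, and pipeline orchestration.

The summary table has one row per species plus rows for evenness (E) and the
Additive Invasibility Index (AII): baseline/future/delta areas in km² over
the whole extent and within a focus region ("critical habitat"), and the
corresponding proportions of declared denominator areas. Species areas come
from the thresholded ensemble binaries; E and AII areas count the cells
where the metric is defined (>= 1 species present), since evenness can be
exactly zero in genuinely invaded single-species cells.

Reference tables for the 17 Hawaiian ecosystem-modifying invasive plants
(species list with record counts and establishment years; published area
summaries) ship with the package for arithmetic checks and worked examples.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import invasibility_metrics as im
from .geo_core import RegionMask, binary_area, boolean_layer_area, thin_to_grid, write_raster
from .invasibility_metrics import AIIResult, BinaryPresence, DiversityLayers
from .niche_overlap import overlap_matrix
from .sdm_ensemble import EnsembleModel, fit_species_ensemble, replicate_metrics
from .synthetic_landscape import ScenarioConfig, VirtualSpecies, generate_scenario

log = logging.getLogger(__name__)

#: declared land areas used for the Hawaiian proportion columns (km²)
HAWAII_LAND_KM2 = 16677.0
HAWAII_CRITICAL_HABITAT_KM2 = 3000.0


def load_emip_species() -> pd.DataFrame:
    """The 17-species Hawaiian EMIP reference table."""
    with resources.files("invasimap.data").joinpath("hawaii_emip_species.csv").open() as fh:
        return pd.read_csv(fh)


def load_hawaii_area_table() -> pd.DataFrame:
    """Published per-species and per-metric area summaries for Hawaii."""
    with resources.files("invasimap.data").joinpath("hawaii_area_table.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class AreaSummary:
    """Summary table plus the denominators its proportion columns use."""

    table: pd.DataFrame
    extent_area_km2: float
    region_area_km2: float

    def rounded(self) -> pd.DataFrame:
        """Presentation copy: areas and proportions to 2 decimals."""
        out = self.table.copy()
        for col in out.columns:
            if col.endswith("_km2") or col.startswith("prop_"):
                out[col] = out[col].round(2)
        return out


def summary_from_areas(
    areas: pd.DataFrame,
    extent_area_km2: float,
    region_area_km2: float,
    metric_rows: tuple = ("E", "AII"),
) -> AreaSummary:
    """Build the summary arithmetic from raw areas.

    ``areas`` needs columns ``name, baseline_km2, future_km2, ch_baseline_km2,
    ch_future_km2`` (future values may be missing for scenario-free metrics
    such as AII). Delta columns are future - baseline; proportions divide by
    the declared denominators; the future-area rank covers species rows only,
    on unrounded areas, ties broken by name.
    """
    if extent_area_km2 <= 0 or region_area_km2 <= 0:
        raise ValueError("denominator areas must be positive")
    t = areas.copy().reset_index(drop=True)
    t["delta_km2"] = t["future_km2"] - t["baseline_km2"]
    t["ch_delta_km2"] = t["ch_future_km2"] - t["ch_baseline_km2"]
    t["prop_extent_baseline"] = t["baseline_km2"] / extent_area_km2
    t["prop_extent_future"] = t["future_km2"] / extent_area_km2
    t["prop_region_baseline"] = t["ch_baseline_km2"] / region_area_km2
    t["prop_region_future"] = t["ch_future_km2"] / region_area_km2

    species = t[~t["name"].isin(metric_rows)]
    ranked = species.sort_values(["future_km2", "name"], ascending=[False, True])
    rank = pd.Series(np.arange(1, len(ranked) + 1), index=ranked.index)
    t["future_rank"] = rank.reindex(t.index)
    cols = [
        "name", "baseline_km2", "future_km2", "future_rank", "delta_km2",
        "ch_baseline_km2", "ch_future_km2", "ch_delta_km2",
        "prop_extent_baseline", "prop_extent_future",
        "prop_region_baseline", "prop_region_future",
    ]
    return AreaSummary(t[cols], extent_area_km2, region_area_km2)


def headline_increase(summary: AreaSummary) -> tuple[float, float]:
    """Percent of the extent (and region) newly open to invasion: (AII - baseline E)
    over the declared denominators."""
    t = summary.table.set_index("name")
    aii = t.loc["AII"]
    e = t.loc["E"]
    statewide = 100.0 * (aii["baseline_km2"] - e["baseline_km2"]) / summary.extent_area_km2
    region = 100.0 * (aii["ch_baseline_km2"] - e["ch_baseline_km2"]) / summary.region_area_km2
    return float(statewide), float(region)


def summarize(
    binaries_baseline: list[BinaryPresence],
    binaries_future: list[BinaryPresence],
    diversity: tuple[DiversityLayers, DiversityLayers],
    aii: AIIResult,
    region: RegionMask,
    extent_area_km2: float | None = None,
    region_area_km2: float | None = None,
) -> AreaSummary:
    """Measure per-species and per-metric areas from layers and tabulate them.

    ``region`` is the focus sub-region ("critical habitat"); the extent is
    the whole grid. Denominators default to the measured land areas but can
    be declared explicitly (as when comparing against published figures).
    """
    div_b, div_f = diversity
    grid = aii.aii.grid
    if extent_area_km2 is None:
        extent_area_km2 = grid.n_rows * grid.n_cols * grid.cell_area_km2
    if region_area_km2 is None:
        region_area_km2 = region.area_km2()

    codes_b = {bp.species_code: bp for bp in binaries_baseline}
    codes_f = {bp.species_code: bp for bp in binaries_future}
    if set(codes_b) != set(codes_f):
        raise ValueError("baseline and future species sets differ")

    rows = []
    for code in codes_b:
        bb, bf = codes_b[code].B, codes_f[code].B
        rows.append(
            {
                "name": code,
                "baseline_km2": binary_area(bb),
                "future_km2": binary_area(bf),
                "ch_baseline_km2": binary_area(bb, region),
                "ch_future_km2": binary_area(bf, region),
            }
        )
    rows.append(
        {
            "name": "E",
            "baseline_km2": boolean_layer_area(div_b.defined(), grid),
            "future_km2": boolean_layer_area(div_f.defined(), grid),
            "ch_baseline_km2": boolean_layer_area(div_b.defined(), grid, region),
            "ch_future_km2": boolean_layer_area(div_f.defined(), grid, region),
        }
    )
    union = im.invaded_cells(binaries_baseline, binaries_future)
    rows.append(
        {
            "name": "AII",
            "baseline_km2": boolean_layer_area(union, grid),
            "future_km2": np.nan,
            "ch_baseline_km2": boolean_layer_area(union, grid, region),
            "ch_future_km2": np.nan,
        }
    )
    return summary_from_areas(pd.DataFrame(rows), extent_area_km2, region_area_km2)


# ---------------------------------------------------------------------------
# pipeline


def _species_from_config(spec: dict) -> VirtualSpecies:
    return VirtualSpecies(
        species_code=spec["code"],
        coefficients={k: float(v) for k, v in spec.get("coefficients", {}).items()},
        intercept=float(spec.get("intercept", 0.0)),
        niche_breadth=float(spec.get("niche_breadth", 1.0)),
    )


def scenario_config_from_toml(cfg: dict) -> ScenarioConfig:
    syn = cfg.get("synthetic", {})
    kwargs = {}
    for key in ("n_rows", "n_cols", "cell_size", "n_layers", "spatial_range",
                "effort_range", "coarse_factor"):
        if key in syn:
            kwargs[key] = syn[key]
    if "species" in cfg:
        species = [_species_from_config(s) for s in cfg["species"]]
        kwargs["species"] = species
        kwargs["n_occurrences"] = {s["code"]: int(s["n"]) for s in cfg["species"]}
    if "shift" in cfg:
        kwargs["shift"] = {k: float(v) for k, v in cfg["shift"].items()}
    return ScenarioConfig(**kwargs)


def run_pipeline(config_path, seed: int, out_dir) -> Path:
    """Run the full analysis from a TOML config: thin -> ensembles ->
    overlap -> diversity/AII -> summary. Idempotent given the seed.

    The config currently drives the synthetic-scenario source (tables
    ``[synthetic]``, ``[[species]]``, ``[shift]`` and ``[fit]``); all
    artifacts (GeoTIFF layers, CSV tables, a JSON manifest with the config
    hash and seed) land in ``out_dir``.
    """
    t0 = time.time()
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = config_path.read_bytes()
    cfg = tomllib.loads(raw.decode())

    def stage(name):
        log.info("[%s] t=%.1fs", name, time.time() - t0)

    try:
        stage("scenario")
        scenario = generate_scenario(scenario_config_from_toml(cfg), seed=seed)
    except Exception as exc:
        raise RuntimeError(f"[scenario] {exc}") from exc

    fit_cfg = cfg.get("fit", {})
    n_reps = int(fit_cfg.get("n_reps", 10))
    learners = tuple(fit_cfg.get("learners", ["maxent", "rf", "gbm"]))

    try:
        stage("thin")
        occ = thin_to_grid(scenario.occurrences, scenario.grid)
        if len(occ) == 0:
            raise ValueError("no occurrences inside the grid")
    except Exception as exc:
        raise RuntimeError(f"[thin] {exc}") from exc

    ens_b: list[EnsembleModel] = []
    ens_f: list[EnsembleModel] = []
    try:
        stage("ensembles")
        for i, sp in enumerate(scenario.species):
            em = fit_species_ensemble(
                occ, sp.species_code, scenario.baseline,
                n_reps=n_reps, seed=seed + 1000 + i, learners=learners,
            )
            ens_b.append(em)
            # project the fitted ensemble onto the future covariates
            ens_f.append(project_ensemble(em, scenario.future))
            metrics = replicate_metrics(em.replicates)
            metrics.to_csv(out_dir / f"replicates_{sp.species_code}.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[ensembles] {exc}") from exc

    try:
        stage("overlap")
        surfaces = {em.species_code: em.weighted_mean for em in ens_b}
        overlap = overlap_matrix(surfaces)
        overlap.to_csv(out_dir / "overlap_matrix.csv")
    except Exception as exc:
        raise RuntimeError(f"[overlap] {exc}") from exc

    try:
        stage("diversity")
        div_b, div_f, aii = im.invasibility_analysis(ens_b, ens_f)
        for layer in (div_b.H, div_b.E, div_f.H, div_f.E, aii.delta_e, aii.aii):
            write_raster(layer, out_dir / f"{layer.name}.tif")
        for em in ens_b + ens_f:
            write_raster(em.weighted_mean, out_dir / f"{em.weighted_mean.name}.tif")
        aii.jackknife.to_csv(out_dir / "jackknife.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[diversity] {exc}") from exc

    try:
        stage("summary")
        bin_b = [im.binary_presence(em) for em in ens_b]
        bin_f = [im.binary_presence(em) for em in ens_f]
        summary = summarize(
            bin_b, bin_f, (div_b, div_f), aii, scenario.masks["critical_habitat"]
        )
        summary.rounded().to_csv(out_dir / "summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[summary] {exc}") from exc

    manifest = {
        "config": config_path.name,
        "config_sha256": hashlib.sha256(raw).hexdigest(),
        "seed": seed,
        "n_species": len(scenario.species),
        "n_occurrences": len(scenario.occurrences),
        "n_replicates": n_reps,
        "learners": list(learners),
        "runtime_s": round(time.time() - t0, 1),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    stage("done")
    return out_dir


def project_ensemble(em: EnsembleModel, stack) -> EnsembleModel:
    """Re-predict an ensemble's included members on a new covariate stack.

    Weights, member thresholds and the ensemble threshold are kept from the
    fitted (baseline) ensemble; only the covariates change — the standard way
    a fitted niche model is projected onto a future climate.
    """
    from .geo_core import RasterLayer

    included = [r for r in em.replicates if not r.excluded and r.model is not None
                and r.auc > 0.5]
    if not included:
        included = [r for r in em.replicates if not r.excluded and r.model is not None]
    X, valid = stack.full_matrix()
    weights = np.array([r.auc for r in included])
    weights = weights / weights.sum()
    wmean = np.full(stack.grid.shape, np.nan)
    committee = np.zeros(stack.grid.shape)
    acc = np.zeros(valid.sum())
    for w, r in zip(weights, included):
        pred = r.model.predict_proba(X)[:, 1]
        acc += w * pred
        cb = np.zeros(stack.grid.shape)
        cb[valid] = (pred >= r.threshold).astype(float)
        committee += cb
    wmean[valid] = acc
    committee = np.where(valid, committee / len(included), np.nan)
    binary = np.where(valid, (wmean >= em.threshold).astype(float), np.nan)
    code = em.species_code
    return EnsembleModel(
        species_code=code,
        weighted_mean=RasterLayer(stack.grid, wmean, f"{code}_weighted_mean_future"),
        committee_avg=RasterLayer(stack.grid, committee, f"{code}_committee_avg_future"),
        binary=RasterLayer(stack.grid, binary, f"{code}_binary_future"),
        threshold=em.threshold,
        n_included=len(included),
        replicates=em.replicates,
    )
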