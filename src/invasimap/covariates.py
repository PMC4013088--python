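"""Predictor derivation: bioclimatic indices, terrain indices, collinearity
screening, and delta-method future climate.

Five bioclimatic summaries (Bio1, Bio2, Bio4, Bio12, Bio15) are computed from
monthly minimum/maximum temperature and precipitation, plus two topographic
indices (TRI, TRASP) from a DEM. All standard deviations are sample (n-1)
standard deviations, matching common bioclim implementations. Future
covariates are built by adding a coarse simulated climate change (future
minus baseline simulation, bilinearly resampled) to the fine observed
baseline ("delta downscaling").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .geo_core import Grid, RasterLayer

#: the seven predictors used for every species model
STANDARD_COVARIATES = ("Bio1", "Bio2", "Bio4", "Bio12", "Bio15", "TRI", "TRASP")


@dataclass
class MonthlyClimate:
    """Twelve monthly layers each of tmin, tmax (degC) and precipitation (mm)."""

    tmin: list[RasterLayer]
    tmax: list[RasterLayer]
    precip: list[RasterLayer]

    def __post_init__(self) -> None:
        for name, layers in (("tmin", self.tmin), ("tmax", self.tmax), ("precip", self.precip)):
            if len(layers) != 12:
                raise ValueError(f"{name}: exactly 12 monthly layers required, got {len(layers)}")
            for lyr in layers:
                if lyr.grid != self.tmin[0].grid:
                    raise ValueError(f"{name}: all monthly layers must share one grid")
        tmin = np.stack([l.values for l in self.tmin])
        tmax = np.stack([l.values for l in self.tmax])
        pr = np.stack([l.values for l in self.precip])
        both = np.isfinite(tmin) & np.isfinite(tmax)
        if np.any(tmax[both] < tmin[both]):
            raise ValueError("tmax must be >= tmin cell-wise")
        if np.any(pr[np.isfinite(pr)] < 0):
            raise ValueError("precipitation must be non-negative")

    @property
    def grid(self) -> Grid:
        return self.tmin[0].grid


@dataclass
class CovariateStack:
    """Named, grid-aligned predictor layers with a collinearity bound."""

    layers: dict[str, RasterLayer]
    selection_threshold: float = 0.63

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("covariate stack needs at least one layer")
        grids = {l.grid for l in self.layers.values()}
        if len(grids) > 1:
            raise ValueError("all covariate layers must share one grid")

    @property
    def grid(self) -> Grid:
        return next(iter(self.layers.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> RasterLayer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def valid_mask(self) -> np.ndarray:
        """Cells where every layer is defined."""
        valid = np.ones(self.grid.shape, dtype=bool)
        for lyr in self.layers.values():
            valid &= lyr.valid
        return valid

    def as_matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Covariate matrix (n_points, n_layers) at the given cell indices."""
        return np.column_stack([self.layers[n].values[rows, cols] for n in self.names])

    def full_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, valid) over all cells: X has one row per valid cell, row-major order."""
        valid = self.valid_mask()
        rows, cols = np.nonzero(valid)
        return self.as_matrix(rows, cols), valid

    def subset(self, names) -> "CovariateStack":
        return CovariateStack({n: self.layers[n] for n in names}, self.selection_threshold)


# ---------------------------------------------------------------------------
# bioclim


def bioclim_subset(clim: MonthlyClimate) -> dict[str, RasterLayer]:
    """Bio1, Bio2, Bio4, Bio12, Bio15 from monthly climate.

    Bio1  mean over months of (tmax+tmin)/2                [degC]
    Bio2  mean over months of (tmax - tmin)                [degC]
    Bio4  sample sd of the 12 monthly means x 100          [unitless]
    Bio12 annual precipitation total                       [mm]
    Bio15 100 x sample sd of monthly precip / (1 + Bio12/12)  [CV, unitless]

    The (1 + mean) denominator in Bio15 (ANUCLIM convention) keeps the
    coefficient of variation finite in arid cells. Nodata propagates
    cell-wise. All five are invariant to month ordering.
    """
    grid = clim.grid
    tmin = np.stack([l.values for l in clim.tmin])
    tmax = np.stack([l.values for l in clim.tmax])
    pr = np.stack([l.values for l in clim.precip])
    tmean = (tmax + tmin) / 2.0

    bio1 = tmean.mean(axis=0)
    bio2 = (tmax - tmin).mean(axis=0)
    bio4 = tmean.std(axis=0, ddof=1) * 100.0
    bio12 = pr.sum(axis=0)
    with np.errstate(invalid="ignore"):
        bio15 = 100.0 * pr.std(axis=0, ddof=1) / (1.0 + bio12 / 12.0)
    return {
        "Bio1": RasterLayer(grid, bio1, "Bio1", units="degC"),
        "Bio2": RasterLayer(grid, bio2, "Bio2", units="degC"),
        "Bio4": RasterLayer(grid, bio4, "Bio4"),
        "Bio12": RasterLayer(grid, bio12, "Bio12", units="mm"),
        "Bio15": RasterLayer(grid, bio15, "Bio15"),
    }


def annual_precip(clim: MonthlyClimate, mode: str = "annual_total") -> RasterLayer:
    """Bio12 under either reading of "annual precipitation".

    ``annual_total`` (default, standard bioclim) sums the 12 months;
    ``monthly_mean`` averages them.
    """
    pr = np.stack([l.values for l in clim.precip])
    if mode == "annual_total":
        vals = pr.sum(axis=0)
    elif mode == "monthly_mean":
        vals = pr.mean(axis=0)
    else:
        raise ValueError(f"unknown bio12 mode {mode!r}")
    return RasterLayer(clim.grid, vals, "Bio12", units="mm")


# ---------------------------------------------------------------------------
# terrain

_NEIGHBOUR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def terrain_indices(dem: RasterLayer) -> tuple[RasterLayer, RasterLayer]:
    """Terrain ruggedness (TRI, Riley) and aspect-based radiation index (TRASP).

    TRI is the square root of the sum of squared elevation differences to the
    eight neighbours; edge cells use only the neighbours that exist, and a
    cell whose neighbourhood is entirely nodata is nodata.

    TRASP = (1 - cos((pi/180) * (aspect - 30))) / 2, with aspect (downslope
    azimuth, clockwise from north) from Horn's 3x3 finite differences. It is
    0 for cool NNE-facing slopes and 1 for hot SSW-facing ones. Flat cells
    have no aspect and get the neutral value 0.5.
    """
    z = dem.values
    n_rows, n_cols = z.shape

    # --- TRI: pad with NaN so edges see only real neighbours
    zp = np.full((n_rows + 2, n_cols + 2), np.nan)
    zp[1:-1, 1:-1] = z
    sq_sum = np.zeros_like(z)
    n_avail = np.zeros_like(z)
    for dr, dc in _NEIGHBOUR_OFFSETS:
        nb = zp[1 + dr : 1 + dr + n_rows, 1 + dc : 1 + dc + n_cols]
        diff2 = (nb - z) ** 2
        ok = np.isfinite(diff2)
        sq_sum = np.where(ok, sq_sum + np.where(ok, diff2, 0.0), sq_sum)
        n_avail += ok
    tri = np.sqrt(sq_sum)
    tri[n_avail == 0] = np.nan
    tri[~np.isfinite(z)] = np.nan

    # --- aspect via Horn's method on an edge-replicated pad
    zf = np.where(np.isfinite(z), z, np.nan)
    zp = np.pad(zf, 1, mode="edge")
    a = zp[0:-2, 0:-2]; b = zp[0:-2, 1:-1]; c = zp[0:-2, 2:]
    d = zp[1:-1, 0:-2];                      f = zp[1:-1, 2:]
    g = zp[2:, 0:-2];   h = zp[2:, 1:-1];    i = zp[2:, 2:]
    cs = dem.grid.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)   # east
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)   # north (row 0 is north)
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
        trasp = (1.0 - np.cos(np.radians(aspect - 30.0))) / 2.0
    flat = (dzdx == 0) & (dzdy == 0)
    trasp = np.where(flat, 0.5, trasp)
    trasp[~np.isfinite(z)] = np.nan

    grid = dem.grid
    return (
        RasterLayer(grid, tri, "TRI", units="m"),
        RasterLayer(grid, trasp, "TRASP"),
    )


# ---------------------------------------------------------------------------
# collinearity screening


def correlation_matrix(layers: dict[str, RasterLayer] | CovariateStack) -> pd.DataFrame:
    """Pairwise Pearson r between layers, over cells valid in both.

    Zero-variance layers yield NaN entries.
    """
    if isinstance(layers, CovariateStack):
        layers = layers.layers
    if len(layers) < 2:
        raise ValueError("need at least two layers")
    df = pd.DataFrame({n: l.values.ravel() for n, l in layers.items()})
    corr = df.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    # a zero-variance layer is genuinely undefined even against itself
    for n in corr.columns:
        col = df[n].dropna()
        if len(col) and col.nunique() == 1:
            corr.loc[n, :] = np.nan
            corr.loc[:, n] = np.nan
    return corr


def screen_covariates(
    corr: pd.DataFrame, threshold: float = 0.63, forced_keep: list[str] | None = None
) -> list[str]:
    """Greedy collinearity screen: drop variables until all pairwise |r| < threshold.

    At each step the variable (not in ``forced_keep``) with the largest mean
    |r| to the remaining variables is removed. A forced pair that violates
    the threshold is kept with a warning — this mirrors expert override of a
    purely statistical screen.
    """
    forced = set(forced_keep or ())
    keep = list(corr.columns)

    def offending_pairs(names):
        out = []
        for idx, ni in enumerate(names):
            for nj in names[idx + 1 :]:
                r = corr.loc[ni, nj]
                if np.isfinite(r) and abs(r) >= threshold:
                    out.append((ni, nj))
        return out

    while True:
        pairs = offending_pairs(keep)
        droppable = {n for p in pairs for n in p if n not in forced}
        if not droppable:
            if pairs:
                warnings.warn(
                    f"forced_keep retains correlated pair(s) at |r| >= {threshold}: {pairs}",
                    stacklevel=2,
                )
            break
        mean_abs = {
            n: np.nanmean([abs(corr.loc[n, m]) for m in keep if m != n]) for n in droppable
        }
        worst = max(sorted(mean_abs), key=lambda n: mean_abs[n])
        keep.remove(worst)
    return keep


# ---------------------------------------------------------------------------
# delta downscaling


def delta_downscale(
    baseline_fine: RasterLayer,
    sim_base_coarse: RasterLayer,
    sim_future_coarse: RasterLayer,
    *,
    precip: bool = False,
    mode: str = "additive",
) -> RasterLayer:
    """Future covariate = fine baseline + (coarse simulated future - baseline).

    The coarse delta is bilinearly interpolated to the fine grid (clamped at
    the coarse cell-center extent). Precipitation-flagged outputs are floored
    at zero. ``mode='multiplicative'`` instead scales the baseline by the
    simulated ratio (precipitation only).
    """
    if sim_base_coarse.grid != sim_future_coarse.grid:
        raise ValueError("coarse simulation layers must share a grid")
    if (
        sim_base_coarse.units
        and baseline_fine.units
        and sim_base_coarse.units != baseline_fine.units
    ):
        raise ValueError(
            f"unit mismatch: baseline {baseline_fine.units!r} vs simulation "
            f"{sim_base_coarse.units!r}"
        )

    if mode == "additive":
        delta_coarse = sim_future_coarse.values - sim_base_coarse.values
    elif mode == "multiplicative":
        if not precip:
            raise ValueError("multiplicative delta is offered for precipitation only")
        with np.errstate(divide="ignore", invalid="ignore"):
            delta_coarse = sim_future_coarse.values / sim_base_coarse.values
    else:
        raise ValueError(f"unknown delta mode {mode!r}")

    delta_fine = _bilinear_to(delta_coarse, sim_base_coarse.grid, baseline_fine.grid)
    if mode == "additive":
        out = baseline_fine.values + delta_fine
    else:
        out = baseline_fine.values * delta_fine
    if precip:
        out = np.where(np.isfinite(out), np.maximum(out, 0.0), out)
    return baseline_fine.with_values(out, name=baseline_fine.name)


def _bilinear_to(values: np.ndarray, src: Grid, dst: Grid) -> np.ndarray:
    """Bilinear interpolation from coarse cell centers to fine cell centers."""
    src_y = src.origin_y - (np.arange(src.n_rows) + 0.5) * src.cell_size
    src_x = src.origin_x + (np.arange(src.n_cols) + 0.5) * src.cell_size
    if src.n_rows == 1 and src.n_cols == 1:
        return np.full(dst.shape, values[0, 0])
    # RegularGridInterpolator needs ascending axes; rows run north->south
    interp = RegularGridInterpolator(
        (src_y[::-1], src_x), values[::-1, :], method="linear",
        bounds_error=False, fill_value=None,
    )
    xs, ys = dst.cell_centers()
    ys_c = np.clip(ys, src_y.min(), src_y.max())
    xs_c = np.clip(xs, src_x.min(), src_x.max())
    pts = np.column_stack([ys_c.ravel(), xs_c.ravel()])
    return interp(pts).reshape(dst.shape)


def build_covariate_stack(
    clim: MonthlyClimate,
    dem: RasterLayer,
    *,
    bio12_mode: str = "annual_total",
    corr_threshold: float = 0.63,
) -> CovariateStack:
    """The standard seven-predictor stack from monthly climate and a DEM."""
    layers = bioclim_subset(clim)
    if bio12_mode != "annual_total":
        layers["Bio12"] = annual_precip(clim, bio12_mode)
    tri, trasp = terrain_indices(dem)
    layers["TRI"] = tri
    layers["TRASP"] = trasp
    return CovariateStack(layers, selection_threshold=corr_threshold)
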