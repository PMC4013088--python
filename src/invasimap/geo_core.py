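"""Grid, raster, region-mask and occurrence primitives.

Everything downstream (covariate derivation, the per-species ensembles, the
diversity metrics and the area summaries) works on one shared analysis grid
of square cells in projected metres. Nodata is represented as NaN in memory
and is excluded from every statistic; it is never silently treated as zero.

Raster files are single-band float32 GeoTIFFs carrying the standard
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags, written and read with
:mod:`tifffile`. Region polygons are GeoJSON read with :mod:`shapely`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import shape as shapely_shape
from shapely.ops import unary_union

log = logging.getLogger(__name__)

_NODATA = -9999.0

# TIFF tag codes for georeferencing (GeoTIFF spec / GDAL convention)
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class Grid:
    """A north-up raster grid of square cells in projected metres.

    ``origin_x``/``origin_y`` locate the outer corner of the top-left cell;
    row 0 is the northern edge. Cells are half-open:
    ``[x, x + cell_size) x (y - cell_size, y]``.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_id: str = "local-metres"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive (metres)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of points; points outside the grid get index -1.

        Follows the half-open convention: the northern and western cell edges
        belong to the cell, the southern and eastern edges to the next one.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        # top edge (y == origin_y) is inside row 0
        row = np.where(self.origin_y - y == 0.0, 0, row)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(inside, row, -1), np.where(inside, col, -1)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )


@dataclass
class RasterLayer:
    """A named single-band layer on a :class:`Grid`; NaN marks nodata."""

    grid: Grid
    values: np.ndarray
    name: str = ""
    units: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.grid, values, self.name if name is None else name, self.units)

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with nodata replaced; used only where an operation says so."""
        return np.where(self.valid, self.values, fill)


@dataclass
class OccurrenceTable:
    """Species occurrence points: columns ``species``, ``x``, ``y`` (metres)."""

    records: pd.DataFrame
    thinned: bool = False

    def __post_init__(self) -> None:
        missing = {"species", "x", "y"} - set(self.records.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    def for_species(self, code: str) -> "OccurrenceTable":
        return OccurrenceTable(
            self.records[self.records["species"] == code].copy(), self.thinned
        )


@dataclass
class RegionMask:
    """A labelled {0,1} mask on the analysis grid with at least one set cell."""

    label: str
    mask: RasterLayer

    def __post_init__(self) -> None:
        vals = self.mask.filled(0.0)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError(f"region mask {self.label!r} must be 0/1")
        if vals.sum() == 0:
            raise ValueError(f"region mask {self.label!r} covers no cell")

    @property
    def bool_array(self) -> np.ndarray:
        return self.mask.filled(0.0) == 1.0

    def area_km2(self) -> float:
        return float(self.bool_array.sum()) * self.mask.grid.cell_area_km2


# ---------------------------------------------------------------------------
# raster I/O


def write_raster(layer: RasterLayer, path) -> None:
    """Write a single-band float32 GeoTIFF with grid geometry and nodata tags."""
    data = np.where(layer.valid, layer.values, _NODATA).astype(np.float32)
    g = layer.grid
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(_NODATA)),
    ]
    tifffile.imwrite(
        path,
        data,
        extratags=extratags,
        description=json.dumps({"crs_id": g.crs_id, "name": layer.name}),
    )


def read_raster(path) -> RasterLayer:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or GDAL).

    Rejects multi-band files and non-square cells.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if len(tif.pages) > 1 or page.samplesperpixel > 1:
            raise ValueError("single-band required")
        data = page.asarray().astype(float)
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        if abs(sx - sy) > 1e-9:
            raise ValueError(f"{path}: non-square cells ({sx} x {sy}) not supported")
        tie = tags[_TAG_TIEPOINT].value
        origin_x, origin_y = tie[3], tie[4]
        nodata = _NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        crs_id, name = "local-metres", ""
        if 270 in tags:  # ImageDescription
            try:
                meta = json.loads(tags[270].value)
                crs_id = meta.get("crs_id", crs_id)
                name = meta.get("name", name)
            except (json.JSONDecodeError, TypeError):
                pass
    if data.ndim != 2:
        raise ValueError("single-band required")
    grid = Grid(data.shape[0], data.shape[1], float(sx), float(origin_x), float(origin_y), crs_id)
    values = np.where(data == nodata, np.nan, data)
    return RasterLayer(grid, values, name=name)


def read_occurrences(path) -> OccurrenceTable:
    """Read an occurrence CSV with header ``species,x,y``."""
    return OccurrenceTable(pd.read_csv(path, dtype={"species": str}))


def write_occurrences(occ: OccurrenceTable, path) -> None:
    occ.records.to_csv(path, index=False)


def read_geojson_polygons(path):
    """Load (Multi)Polygon geometries from a GeoJSON file, in projected metres."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shapely_shape(gj["geometry"])]
    else:
        geoms = [shapely_shape(gj)]
    return geoms


# ---------------------------------------------------------------------------
# operations


def rasterize_region(polygons, grid: Grid, label: str) -> RegionMask:
    """Burn polygons to a {0,1} mask: a cell is 1 iff its center is inside.

    ``polygons`` is a shapely geometry or an iterable of them, in the grid's
    coordinate system.
    """
    if polygons is None:
        raise ValueError("empty geometry")
    geoms = list(polygons) if not hasattr(polygons, "geom_type") else [polygons]
    geoms = [g for g in geoms if g is not None and not g.is_empty]
    if not geoms:
        raise ValueError("empty geometry")
    geom = unary_union(geoms)
    xs, ys = grid.cell_centers()
    inside = shapely.contains_xy(geom, xs.ravel(), ys.ravel()).reshape(grid.shape)
    if not inside.any():
        raise ValueError(f"region {label!r}: no cell center falls inside the polygons")
    return RegionMask(label, RasterLayer(grid, inside.astype(float), name=label))


def thin_to_grid(occ: OccurrenceTable, grid: Grid) -> OccurrenceTable:
    """Reduce occurrences to at most one record per species per grid cell.

    Presence-only models use a Boolean notion of presence, so repeated
    collections inside one cell carry no extra information and would
    otherwise act as weights. The first record in input order is kept.
    Points outside the grid are dropped (count logged).
    """
    if occ.thinned:
        raise ValueError("occurrence table already thinned")
    df = occ.records.copy()
    row, col = grid.point_to_cell(df["x"].to_numpy(), df["y"].to_numpy())
    inside = row >= 0
    n_dropped = int((~inside).sum())
    if n_dropped:
        log.info("thin_to_grid: dropped %d point(s) outside the grid", n_dropped)
    df = df[inside].assign(_row=row[inside], _col=col[inside])
    df = df.drop_duplicates(subset=["species", "_row", "_col"], keep="first")
    return OccurrenceTable(df.drop(columns=["_row", "_col"]), thinned=True)


def occurrence_cells(occ: OccurrenceTable, grid: Grid) -> pd.DataFrame:
    """Map occurrences to cell indices: DataFrame(species, row, col), in-grid only."""
    row, col = grid.point_to_cell(occ.records["x"].to_numpy(), occ.records["y"].to_numpy())
    keep = row >= 0
    return pd.DataFrame(
        {
            "species": occ.records["species"].to_numpy()[keep],
            "row": row[keep],
            "col": col[keep],
        }
    )


def binary_area(layer: RasterLayer, mask: RegionMask | None = None) -> float:
    """Area in km² of cells equal to 1, optionally intersected with a mask."""
    if mask is not None and mask.mask.grid != layer.grid:
        raise ValueError("mask grid does not match layer grid")
    ones = layer.filled(0.0) == 1.0
    if mask is not None:
        ones &= mask.bool_array
    return float(ones.sum()) * layer.grid.cell_area_km2


def boolean_layer_area(cells: np.ndarray, grid: Grid, mask: RegionMask | None = None) -> float:
    """Area of a boolean cell array (helper for metric-defined areas)."""
    sel = np.asarray(cells, dtype=bool)
    if sel.shape != grid.shape:
        raise ValueError("boolean array shape does not match grid")
    if mask is not None:
        if mask.mask.grid != grid:
            raise ValueError("mask grid does not match layer grid")
        sel = sel & mask.bool_array
    return float(sel.sum()) * grid.cell_area_km2
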