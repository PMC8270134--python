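"""Grid/vector data model, raster and table I/O, and area accounting.

All analysis happens in one projected, metric CRS. Rasters are GeoTIFFs with
the georeferencing carried in standard GeoTIFF tags (pixel scale, tiepoint,
geokey directory, GDAL nodata); inputs in a geographic (degree) CRS are
rejected rather than silently reprojected, because reprojection resamples
categorical rasters. Polygon membership of a cell is decided by the cell
*centre* (centre rule) everywhere — range intersection and area accounting
therefore always agree.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("rewildmap")

#: Default projected CRS tagged on written rasters (UTM zone 21S, metres).
DEFAULT_EPSG = 32721

#: Integer nodata sentinel for label rasters.
NODATA_LABEL = -1

#: Float nodata sentinel for probability / proportion rasters.
NODATA_FLOAT = -9999.0

#: The ten land-cover classes of the reserve, in fixed channel order.
DEFAULT_CLASSES = (
    "aquatic vegetation",
    "artificial surfaces",
    "bare ground",
    "broadleaf forest",
    "free-standing trees",
    "palms",
    "short grassland",
    "tall grassland",
    "Vernonia shrubland",
    "water",
)

# GeoTIFF tag codes.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113


# ---------------------------------------------------------------------------
# Grid model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A north-up planar raster grid in metres.

    ``(origin_x, origin_y)`` is the *top-left corner* of cell (0, 0); rows
    increase southward, so the centre of cell (r, c) is
    ``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    epsg: int = DEFAULT_EPSG

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of shape (n_rows, n_cols) of cell centres."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing planar points (vectorised)."""
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y, float)) / self.cell_size).astype(int)
        return row, col

    def contains_index(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def envelope(self) -> BaseGeometry:
        """The grid extent as a shapely polygon."""
        return shapely.box(
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )


@dataclass(frozen=True)
class ClassCatalogue:
    """Ordered, unique land-cover class names; order fixes channel order."""

    names: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")
        if not self.names:
            raise ValueError("catalogue must contain at least one class")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class HabitatMap:
    """Categorical land-cover raster; labels index the catalogue or NODATA."""

    grid: GridSpec
    labels: np.ndarray  # int array (n_rows, n_cols), NODATA_LABEL for nodata
    catalogue: ClassCatalogue = field(default_factory=ClassCatalogue)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        valid = self.labels != NODATA_LABEL
        if valid.any():
            mx = int(self.labels[valid].max())
            mn = int(self.labels[valid].min())
            if mn < 0 or mx >= len(self.catalogue):
                raise ValueError("label outside catalogue range")

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.labels == NODATA_LABEL

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == self.catalogue.index(name)


@dataclass
class ProportionRaster:
    """Per-cell fractional cover over catalogue classes (simplex per cell)."""

    grid: GridSpec
    fractions: np.ndarray  # float (n_classes, n_rows, n_cols); NODATA_FLOAT cells
    catalogue: ClassCatalogue = field(default_factory=ClassCatalogue)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, float)
        if self.fractions.ndim != 3 or self.fractions.shape[1:] != self.grid.shape:
            raise ValueError("fractions must be (n_classes, n_rows, n_cols)")
        if self.fractions.shape[0] != len(self.catalogue):
            raise ValueError("band count inconsistent with catalogue")
        valid = ~self.nodata_mask
        if valid.any():
            v = self.fractions[:, valid]
            if (v < -1e-9).any() or np.abs(v.sum(axis=0) - 1.0).max() > 1e-6:
                raise ValueError("per-cell fractions must be >= 0 and sum to 1")

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.any(self.fractions == NODATA_FLOAT, axis=0)

    def band(self, name: str) -> np.ndarray:
        return self.fractions[self.catalogue.index(name)]


@dataclass
class SelectionSurface:
    """Per-cell predicted probability of presence for one species."""

    grid: GridSpec
    probability: np.ndarray  # float (n_rows, n_cols), NODATA_FLOAT for nodata
    species: str = ""

    def __post_init__(self) -> None:
        self.probability = np.asarray(self.probability, float)
        if self.probability.shape != self.grid.shape:
            raise ValueError("probability shape does not match grid")
        valid = self.probability != NODATA_FLOAT
        p = self.probability[valid]
        if p.size and (p.min() < -1e-9 or p.max() > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.probability == NODATA_FLOAT


@dataclass
class TrackingTable:
    """Occurrence records: species, individual, planar x/y, optional timestamp."""

    frame: pd.DataFrame  # columns: species, individual_id, x, y, timestamp

    REQUIRED = ("species", "individual_id", "x", "y")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"tracking table requires column '{col}'")
        if "timestamp" not in self.frame.columns:
            self.frame = self.frame.assign(timestamp=pd.NaT)
        xy = self.frame[["x", "y"]].to_numpy(float)
        if xy.size and not np.isfinite(xy).all():
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.frame)

    def species_list(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def for_species(self, species: str) -> "TrackingTable":
        return TrackingTable(self.frame[self.frame["species"] == species].reset_index(drop=True))

    def points(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy(float)


@dataclass
class BoundaryPolygon:
    """Study-area boundary in the grid's planar CRS."""

    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise ValueError("boundary geometry is invalid (self-intersecting?)")
        if self.geometry.area <= 0:
            raise ValueError("boundary must have positive area")

    @property
    def area_km2(self) -> float:
        return self.geometry.area / 1e6

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return shapely.contains_xy(self.geometry, np.asarray(x, float), np.asarray(y, float))


@dataclass
class AreaTable:
    """Per-label area accounting with percents against a stated denominator."""

    table: pd.DataFrame  # columns: label, area_km2, percent
    denominator_km2: float

    def row(self, label) -> pd.Series:
        hit = self.table[self.table["label"].astype(str) == str(label)]
        if hit.empty:
            raise KeyError(label)
        return hit.iloc[0]

    def total_km2(self) -> float:
        return float(self.row("total")["area_km2"])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Raster I/O (GeoTIFF via tifffile)
# ---------------------------------------------------------------------------

def _geokeys(epsg: int) -> tuple[int, ...]:
    # GeoKeyDirectory: version 1.1.0, 2 keys: model type = projected, PCS = epsg
    return (1, 1, 0, 2, 1024, 0, 1, 1, 3072, 0, 1, int(epsg))


def _geo_extratags(grid: GridSpec, nodata: float | int) -> list[tuple]:
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_TAG_GEOKEYS, "H", 12, _geokeys(grid.epsg)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def write_raster(obj, path: str | Path) -> Path:
    """Write a raster object as a georeferenced GeoTIFF.

    Band order equals catalogue order for multi-band rasters. Integer rasters
    round-trip bit-for-bit through :func:`read_raster`.
    """
    path = Path(path)
    if isinstance(obj, HabitatMap):
        data = obj.labels.astype(np.int16)
        nodata = NODATA_LABEL
    elif isinstance(obj, ProportionRaster):
        data = np.moveaxis(obj.fractions.astype(np.float64), 0, -1)
        nodata = NODATA_FLOAT
    elif isinstance(obj, SelectionSurface):
        data = obj.probability.astype(np.float64)
        nodata = NODATA_FLOAT
    elif hasattr(obj, "grid") and hasattr(obj, "values"):
        # duck-typed single-band float map (integrity / generic score rasters)
        data = np.asarray(obj.values, np.float64)
        nodata = NODATA_FLOAT
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    try:
        tifffile.imwrite(
            path,
            data,
            photometric="minisblack",
            planarconfig="contig" if data.ndim == 3 else None,
            extratags=_geo_extratags(obj.grid, nodata),
        )
    except OSError as exc:
        raise OSError(f"cannot write raster to {path}: {exc}") from exc
    return path


def _grid_from_tags(page, shape: tuple[int, int], path) -> GridSpec:
    tags = page.tags
    if _TAG_GEOKEYS not in tags:
        raise ValueError(f"{path}: missing CRS — projected CRS required")
    keys = tuple(int(v) for v in np.atleast_1d(tags[_TAG_GEOKEYS].value))
    model_type = epsg = None
    # geokey entries are (key id, location, count, value) quadruples after header
    for i in range(4, len(keys) - 3, 4):
        if keys[i] == 1024:
            model_type = keys[i + 3]
        if keys[i] == 3072:
            epsg = keys[i + 3]
    if model_type == 2:
        raise ValueError(f"{path}: geographic (degree) CRS — projected CRS required")
    if model_type != 1:
        raise ValueError(f"{path}: missing CRS — projected CRS required")
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise ValueError(f"{path}: missing geotransform tags")
    sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise ValueError(f"{path}: non-square pixels are not supported")
    tie = tags[_TAG_TIEPOINT].value
    return GridSpec(
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        cell_size=float(sx),
        n_rows=shape[0],
        n_cols=shape[1],
        epsg=int(epsg) if epsg else DEFAULT_EPSG,
    )


def read_raster(
    path: str | Path,
    expected_kind: str,
    catalogue: ClassCatalogue | None = None,
    species: str = "",
):
    """Read a GeoTIFF as a typed raster.

    Parameters
    ----------
    expected_kind
        One of ``"habitat"`` (single integer band), ``"proportions"``
        (one float band per catalogue class) or ``"selection"`` (single
        float probability band).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    catalogue = catalogue or ClassCatalogue()
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        shape = data.shape if data.ndim == 2 else data.shape[:2]
        grid = _grid_from_tags(page, shape, path)

    if expected_kind == "habitat":
        if data.ndim != 2 or not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"{path}: habitat raster must be a single integer band")
        return HabitatMap(grid, data.astype(np.int64), catalogue)
    if expected_kind == "proportions":
        if data.ndim != 3:
            raise ValueError(f"{path}: proportion raster must be multi-band")
        if data.shape[2] != len(catalogue):
            raise ValueError(
                f"{path}: {data.shape[2]} bands inconsistent with "
                f"{len(catalogue)}-class catalogue"
            )
        return ProportionRaster(grid, np.moveaxis(data.astype(float), -1, 0), catalogue)
    if expected_kind == "selection":
        if data.ndim != 2:
            raise ValueError(f"{path}: selection surface must be a single band")
        return SelectionSurface(grid, data.astype(float), species=species)
    raise ValueError(f"unknown expected_kind {expected_kind!r}")


# ---------------------------------------------------------------------------
# Tracking CSV
# ---------------------------------------------------------------------------

def read_tracking_csv(path: str | Path) -> TrackingTable:
    """Read a tracking CSV (species, individual_id, x, y[, date]).

    Exact duplicates are removed; rows with unparseable coordinates or empty
    identifiers are dropped with a logged count. Non-ISO dates become null
    timestamps with a warning (timestamps are unused by the core pipeline).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [c for c in TrackingTable.REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; required header is "
            "species,individual_id,x,y[,date]"
        )
    n0 = len(raw)
    date_col = "date" if "date" in raw.columns else None
    dedup_cols = list(TrackingTable.REQUIRED) + ([date_col] if date_col else [])
    raw = raw.drop_duplicates(subset=dedup_cols)
    n_dup = n0 - len(raw)

    x = pd.to_numeric(raw["x"], errors="coerce")
    y = pd.to_numeric(raw["y"], errors="coerce")
    species = raw["species"].fillna("").str.strip()
    indiv = raw["individual_id"].fillna("").str.strip()
    ok = x.notna() & y.notna() & np.isfinite(x.fillna(np.inf)) & (species != "") & (indiv != "")
    n_bad = int((~ok).sum())
    if n_dup or n_bad:
        logger.warning(
            "read_tracking_csv(%s): removed %d duplicated and %d unidentifiable/unparseable rows",
            path.name, n_dup, n_bad,
        )
    if date_col:
        ts = pd.to_datetime(raw[date_col], errors="coerce", format="ISO8601")
        n_baddate = int((ts.isna() & raw[date_col].notna())[ok].sum())
        if n_baddate:
            logger.warning("read_tracking_csv(%s): %d non-ISO dates set to null", path.name, n_baddate)
    else:
        ts = pd.Series(pd.NaT, index=raw.index)

    frame = pd.DataFrame(
        {
            "species": species[ok],
            "individual_id": indiv[ok],
            "x": x[ok].astype(float),
            "y": y[ok].astype(float),
            "timestamp": ts[ok],
        }
    ).reset_index(drop=True)
    return TrackingTable(frame)


# ---------------------------------------------------------------------------
# GeoJSON vectors
# ---------------------------------------------------------------------------

def read_boundary_geojson(path: str | Path) -> BoundaryPolygon:
    """Read a study-area boundary polygon from GeoJSON (planar coordinates)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in gj["features"]]
        geom = shapely.union_all(geoms)
    elif gj.get("type") == "Feature":
        geom = shapely_shape(gj["geometry"])
    else:
        geom = shapely_shape(gj)
    return BoundaryPolygon(geom)


def write_geojson(geometries: Mapping[str, BaseGeometry], path: str | Path,
                  epsg: int = DEFAULT_EPSG) -> Path:
    """Write named geometries as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {"name": name}, "geometry": shapely_mapping(geom)}
        for name, geom in geometries.items()
    ]
    doc = {
        "type": "FeatureCollection",
        "crs_epsg": epsg,
        "features": features,
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


# ---------------------------------------------------------------------------
# Area accounting
# ---------------------------------------------------------------------------

def _label_arrays(map_obj, field: str | None):
    """Per-cell (label array, nodata mask) for any scoreable map type."""
    # local imports avoid a cycle with rewilding_scores
    from .rewilding_scores import ComplexityMap, IntegrityMap, OccupancyMap

    if isinstance(map_obj, HabitatMap):
        labels = np.where(
            map_obj.nodata_mask, "", np.array(map_obj.catalogue.names, object)[
                np.clip(map_obj.labels, 0, len(map_obj.catalogue) - 1)
            ]
        )
        return labels, map_obj.nodata_mask
    if isinstance(map_obj, OccupancyMap):
        return map_obj.category_names(), map_obj.nodata_mask
    if isinstance(map_obj, ComplexityMap):
        counts = map_obj.realized if field != "potential" else map_obj.potential
        labels = counts.astype(object)
        return labels, map_obj.nodata_mask
    if isinstance(map_obj, IntegrityMap):
        labels = np.round(map_obj.scores, 10).astype(object)
        return labels, map_obj.nodata_mask
    raise TypeError(f"area_summary does not support {type(map_obj).__name__}")


def area_summary(
    map_obj,
    boundary: BoundaryPolygon,
    denominator_mode: str = "site",
    field: str | None = None,
    background: Iterable = (),
) -> AreaTable:
    """Tabulate per-label areas (km²) of a map inside a boundary.

    Cell membership follows the centre rule. NODATA cells never count.
    ``denominator_mode="site"`` takes percents against all counted in-boundary
    cells; ``"predicted"`` against the non-background labels only.
    A totals row (label ``"total"``, excluding background labels) is appended.
    """
    if denominator_mode not in ("site", "predicted"):
        raise ValueError("denominator_mode must be 'site' or 'predicted'")
    labels, nodata = _label_arrays(map_obj, field)
    grid = map_obj.grid
    cx, cy = grid.cell_centers()
    inside = boundary.contains_points(cx.ravel(), cy.ravel()).reshape(grid.shape)
    counted = inside & ~nodata
    if not counted.any():
        raise ValueError("map does not intersect the boundary")

    cell_km2 = grid.cell_area_m2 / 1e6
    vals, counts = np.unique(labels[counted], return_counts=True)
    background = set(background)
    rows = []
    fg_area = 0.0
    for v, n in zip(vals, counts):
        a = n * cell_km2
        rows.append({"label": v, "area_km2": a})
        if v not in background:
            fg_area += a
    site_area = counted.sum() * cell_km2
    denom = site_area if denominator_mode == "site" else fg_area
    for r in rows:
        r["percent"] = 100.0 * r["area_km2"] / denom
    rows.append({"label": "total", "area_km2": fg_area, "percent": 100.0 * fg_area / denom})
    table = pd.DataFrame(rows, columns=["label", "area_km2", "percent"])
    return AreaTable(table, denominator_km2=denom)
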