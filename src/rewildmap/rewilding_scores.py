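"""Occupancy, faunal-complexity and ecological-integrity scoring.

Per species, a cell with predicted probability of presence strictly above
the threshold (default 0.5) is REALIZED occupancy if its centre lies inside
the species' range polygons and POTENTIAL occupancy otherwise; at or below
the threshold it is NOT_PREDICTED. Faunal complexity counts, per cell, the
species with realized (resp. potential) occupancy. Ecological integrity
averages, over species, an indicator that is 0 for unrealized predicted
occupancy (POTENTIAL) and 1 otherwise (REALIZED or NOT_PREDICTED): a cell
scores 1 when every prediction about it — occupancy or absence — is already
realized. The "before rewilding" scenario treats every range as empty, so
every predicted cell is unrealized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .geodata_io import (
    AreaTable,
    BoundaryPolygon,
    GridSpec,
    SelectionSurface,
    area_summary,
)

logger = logging.getLogger("rewildmap")

# occupancy category codes
NOT_PREDICTED = 0
POTENTIAL = 1
REALIZED = 2
NODATA_CAT = -1

_CATEGORY_NAMES = {NOT_PREDICTED: "NOT_PREDICTED", POTENTIAL: "POTENTIAL", REALIZED: "REALIZED"}


@dataclass
class OccupancyMap:
    """Per-cell occupancy category for one species."""

    grid: GridSpec
    categories: np.ndarray  # int codes, NODATA_CAT for nodata
    species: str = ""
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories)
        if self.categories.shape != self.grid.shape:
            raise ValueError("categories shape does not match grid")

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.categories == NODATA_CAT

    def category_names(self) -> np.ndarray:
        out = np.full(self.grid.shape, "", dtype=object)
        for code, name in _CATEGORY_NAMES.items():
            out[self.categories == code] = name
        return out

    def mask(self, code: int) -> np.ndarray:
        return self.categories == code


@dataclass
class ComplexityMap:
    """Per-cell counts of species with realized / potential occupancy."""

    grid: GridSpec
    realized: np.ndarray
    potential: np.ndarray
    n_species: int
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.realized = np.asarray(self.realized, int)
        self.potential = np.asarray(self.potential, int)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, bool)
        if ((self.realized + self.potential) > self.n_species).any():
            raise ValueError("per-cell species counts exceed the species total")


@dataclass
class IntegrityMap:
    """Per-cell ecological-integrity score on the lattice {k/S}."""

    grid: GridSpec
    scores: np.ndarray  # float, np.nan for nodata
    n_species: int
    scenario: str = "after"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        if self.scenario not in ("before", "after"):
            raise ValueError("scenario must be 'before' or 'after'")
        valid = ~np.isnan(self.scores)
        if valid.any():
            k = self.scores[valid] * self.n_species
            if np.abs(k - np.round(k)).max() > 1e-9:
                raise ValueError("integrity scores must lie on the k/S lattice")

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.scores)

    @property
    def values(self) -> np.ndarray:  # for write_raster duck typing
        from .geodata_io import NODATA_FLOAT

        out = self.scores.copy()
        out[np.isnan(out)] = NODATA_FLOAT
        return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def classify_occupancy(surface: SelectionSurface, range_polygons: BaseGeometry | None,
                       threshold: float = 0.5) -> OccupancyMap:
    """Classify each cell as REALIZED / POTENTIAL / NOT_PREDICTED.

    Strict inequality at the threshold; range membership by the cell-centre
    rule. An empty range set makes every predicted cell POTENTIAL.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    grid = surface.grid
    cats = np.full(grid.shape, NODATA_CAT, dtype=int)
    valid = ~surface.nodata_mask
    predicted = valid & (surface.probability > threshold)
    cats[valid] = NOT_PREDICTED
    if range_polygons is None or range_polygons.is_empty:
        in_range = np.zeros(grid.shape, bool)
    else:
        cx, cy = grid.cell_centers()
        in_range = shapely.contains_xy(range_polygons, cx.ravel(), cy.ravel()).reshape(grid.shape)
    cats[predicted & in_range] = REALIZED
    cats[predicted & ~in_range] = POTENTIAL
    return OccupancyMap(grid, cats, species=surface.species, threshold=threshold)


def _check_shared_grid(maps: Sequence[OccupancyMap]) -> GridSpec:
    if not maps:
        raise ValueError("need at least one species occupancy map")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise ValueError("all occupancy maps must share one grid")
    return grid


def faunal_complexity(maps: Sequence[OccupancyMap]) -> ComplexityMap:
    """Per-cell counts of species with REALIZED and with POTENTIAL occupancy."""
    grid = _check_shared_grid(maps)
    realized = np.zeros(grid.shape, int)
    potential = np.zeros(grid.shape, int)
    nodata = np.zeros(grid.shape, bool)
    for m in maps:
        realized += m.mask(REALIZED)
        potential += m.mask(POTENTIAL)
        nodata |= m.nodata_mask
    return ComplexityMap(grid, realized, potential, n_species=len(maps), nodata_mask=nodata)


def ecological_integrity(maps: Sequence[OccupancyMap], scenario: str = "after") -> IntegrityMap:
    """Mean per-species indicator: POTENTIAL -> 0, REALIZED/NOT_PREDICTED -> 1.

    ``scenario="before"`` re-evaluates every map as if its range were empty
    (all predicted cells unrealized); ``"after"`` uses the maps as given.
    """
    grid = _check_shared_grid(maps)
    if scenario not in ("before", "after"):
        raise ValueError("scenario must be 'before' or 'after'")
    total = np.zeros(grid.shape, float)
    nodata = np.zeros(grid.shape, bool)
    for m in maps:
        if scenario == "before":
            indicator = np.where(m.categories == NOT_PREDICTED, 1.0, 0.0)
        else:
            indicator = np.where(m.categories == POTENTIAL, 0.0, 1.0)
        total += indicator
        nodata |= m.nodata_mask
    scores = total / len(maps)
    scores[nodata] = np.nan
    return IntegrityMap(grid, scores, n_species=len(maps), scenario=scenario)


def high_integrity_percent(table: AreaTable, n_species: int | None = None) -> float:
    """Percent of the site with integrity score strictly greater than 0.5."""
    rows = table.table[table.table["label"].astype(str) != "total"]
    pct = 0.0
    for _, r in rows.iterrows():
        if float(r["label"]) > 0.5:
            pct += float(r["percent"])
    return pct


def integrity_delta(before: IntegrityMap, after: IntegrityMap,
                    boundary: BoundaryPolygon) -> dict:
    """Per-score-bin areas for both scenarios plus high-integrity fractions.

    Returns ``{"before": AreaTable, "after": AreaTable,
    "high_integrity_before_pct": ..., "high_integrity_after_pct": ...}``.
    """
    if before.grid != after.grid:
        raise ValueError("before/after integrity maps must share one grid")
    tb = area_summary(before, boundary, denominator_mode="site")
    ta = area_summary(after, boundary, denominator_mode="site")
    return {
        "before": tb,
        "after": ta,
        "high_integrity_before_pct": high_integrity_percent(tb, before.n_species),
        "high_integrity_after_pct": high_integrity_percent(ta, after.n_species),
    }


def realized_fraction(realized_km2: float, potential_km2: float) -> float:
    """Percent of the predicted area (realized + potential) already realized."""
    denom = realized_km2 + potential_km2
    if denom <= 0:
        raise ValueError("realized + potential area must be > 0")
    return round(100.0 * realized_km2 / denom, 1)


def occupancy_polygons(occ: OccupancyMap) -> dict[str, BaseGeometry]:
    """Dissolved REALIZED / POTENTIAL cell polygons (for GeoJSON export)."""
    grid = occ.grid
    out = {}
    for code, name in ((REALIZED, "realized"), (POTENTIAL, "potential")):
        rows, cols = np.nonzero(occ.mask(code))
        if rows.size == 0:
            out[name] = shapely.Polygon()
            continue
        x0 = grid.origin_x + cols * grid.cell_size
        y1 = grid.origin_y - rows * grid.cell_size
        boxes = shapely.box(x0, y1 - grid.cell_size, x0 + grid.cell_size, y1)
        out[name] = shapely.union_all(boxes)
    return out
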