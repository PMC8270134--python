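"""Species-range estimation and pseudo-absence generation.

A species' range (area of occupancy) is the 95% volume contour of a Gaussian
kernel density estimate over its tracking points, computed for all
individuals with more than ``min_obs`` in-boundary observations. Per-
individual contours give a median individual range area; that area sets the
radius of the exclusion discs around presence points outside of which
pseudo-absence (available) points are sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry

from .geodata_io import BoundaryPolygon, GridSpec, TrackingTable

logger = logging.getLogger("rewildmap")

#: Cap on rejection-sampling draws before giving up on pathological geometry.
MAX_REJECTION_DRAWS = 1_000_000


@dataclass
class DensitySurface:
    """Gridded probability density; density x cell area sums to 1."""

    grid: GridSpec
    density: np.ndarray
    bandwidth_m: float

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, float)
        if self.density.shape != self.grid.shape:
            raise ValueError("density shape does not match grid")
        if (self.density < 0).any():
            raise ValueError("density must be nonnegative")
        mass = self.density.sum() * self.grid.cell_area_m2
        if abs(mass - 1.0) > 1e-3:
            raise ValueError(f"density mass {mass:.6f} != 1")


@dataclass
class RangeEstimate:
    """95% (by default) volume-contour range of a species."""

    species: str
    polygons: BaseGeometry
    isopleth: float
    area_km2: float
    per_individual_areas_km2: Mapping[str, float]
    median_individual_area_km2: float
    bandwidth_m: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 < self.isopleth < 1:
            raise ValueError("isopleth must be in (0, 1)")
        if not self.per_individual_areas_km2:
            raise ValueError("per-individual area map must be non-empty")


@dataclass
class PseudoAbsenceSet:
    """Seeded uniform background points outside all presence exclusion discs."""

    species: str
    points: np.ndarray  # (n, 2)
    exclusion_radius_m: float
    seed: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_individuals(table: TrackingTable, species: str,
                       boundary: BoundaryPolygon | None = None,
                       min_obs: int = 10) -> TrackingTable:
    """Keep individuals with *more than* ``min_obs`` in-boundary points.

    Out-of-boundary records are dropped first, then the per-individual count
    filter applies (strict inequality). Raises if no individual survives.
    """
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    sub = table.for_species(species).frame
    if boundary is not None and len(sub):
        inside = boundary.contains_points(sub["x"].to_numpy(), sub["y"].to_numpy())
        n_out = int((~inside).sum())
        if n_out:
            logger.info("filter_individuals(%s): dropped %d points outside boundary",
                        species, n_out)
        sub = sub[inside]
    counts = sub.groupby("individual_id").size()
    keep = counts[counts > min_obs].index
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("filter_individuals(%s): excluded individuals with <= %d obs: %s",
                    species, min_obs, dropped)
    out = sub[sub["individual_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"no individual of {species!r} has more than {min_obs} in-boundary observations"
        )
    return TrackingTable(out)


# ---------------------------------------------------------------------------
# Kernel density estimation
# ---------------------------------------------------------------------------

def scott_bandwidth(points: np.ndarray) -> float:
    """Scott's rule for a 2-D isotropic Gaussian kernel: sigma * n^(-1/6)."""
    points = np.asarray(points, float)
    n = len(points)
    sd = np.sqrt(points.var(axis=0, ddof=1).mean())
    if sd == 0:
        raise ValueError("all points identical: automatic bandwidth is degenerate")
    return float(sd * n ** (-1 / 6))


def kde_grid_for_points(points: np.ndarray, cell_size: float, bandwidth_m: float,
                        pad_bandwidths: float = 3.0) -> GridSpec:
    """Evaluation grid covering the points plus ``pad_bandwidths`` x h margin."""
    points = np.asarray(points, float)
    pad = pad_bandwidths * bandwidth_m
    x0 = points[:, 0].min() - pad
    x1 = points[:, 0].max() + pad
    y0 = points[:, 1].min() - pad
    y1 = points[:, 1].max() + pad
    n_cols = max(int(np.ceil((x1 - x0) / cell_size)), 1)
    n_rows = max(int(np.ceil((y1 - y0) / cell_size)), 1)
    return GridSpec(origin_x=x0, origin_y=y1, cell_size=cell_size,
                    n_rows=n_rows, n_cols=n_cols)


def kde_density(points: np.ndarray, grid: GridSpec,
                bandwidth: float | str = "auto") -> DensitySurface:
    """Isotropic Gaussian KDE evaluated at cell centres, unit mass on the grid.

    ``bandwidth`` is either a kernel standard deviation in metres or
    ``"auto"`` for Scott's rule on the points.
    """
    points = np.asarray(points, float).reshape(-1, 2)
    if len(points) < 2:
        raise ValueError("KDE needs at least two points")
    if bandwidth == "auto":
        h = scott_bandwidth(points)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be > 0")

    cx, cy = grid.cell_centers()
    centres = np.column_stack([cx.ravel(), cy.ravel()])
    # chunk over grid cells to bound memory on big grids
    dens = np.empty(len(centres))
    inv2h2 = 1.0 / (2 * h * h)
    chunk = max(1, int(4e6 // max(len(points), 1)))
    for i in range(0, len(centres), chunk):
        d2 = ((centres[i:i + chunk, None, :] - points[None, :, :]) ** 2).sum(axis=2)
        dens[i:i + chunk] = np.exp(-d2 * inv2h2).sum(axis=1)
    dens = dens.reshape(grid.shape)
    mass = dens.sum() * grid.cell_area_m2
    if mass <= 0:
        raise ValueError("degenerate density: all mass outside the grid")
    return DensitySurface(grid, dens / mass, bandwidth_m=h)


def volume_contour(density: DensitySurface, level: float = 0.95) -> tuple[BaseGeometry, float]:
    """Smallest-area cell set holding >= ``level`` of the density mass.

    Cells are ranked by density and accumulated until the mass reaches the
    level; the selected cells are polygonised (union of cell squares).
    Returns ``(polygons, attained_mass)``; the attained mass lies in
    ``[level, level + mass of one cell]``.
    """
    if not 0 < level < 1:
        raise ValueError("contour level must be in (0, 1)")
    grid = density.grid
    mass = (density.density * grid.cell_area_m2).ravel()
    order = np.argsort(mass)[::-1]
    cum = np.cumsum(mass[order])
    n_sel = int(np.searchsorted(cum, level) + 1)
    sel = order[:n_sel]
    rows, cols = np.unravel_index(sel, grid.shape)
    x0 = grid.origin_x + cols * grid.cell_size
    y1 = grid.origin_y - rows * grid.cell_size
    boxes = shapely.box(x0, y1 - grid.cell_size, x0 + grid.cell_size, y1)
    poly = shapely.union_all(boxes)
    return poly, float(cum[n_sel - 1])


def species_range(table: TrackingTable, species: str, grid: GridSpec,
                  bandwidth: float | str = "auto", level: float = 0.95) -> RangeEstimate:
    """Pooled-KDE species range plus median per-individual range area.

    ``grid`` supplies the evaluation cell size (the KDE grid itself extends
    three bandwidths beyond each point cloud). ``filter_individuals`` is
    expected to have been applied already.
    """
    sub = table.for_species(species)
    pts = sub.points()
    if bandwidth == "auto":
        h = scott_bandwidth(pts)
    else:
        h = float(bandwidth)
    pooled_grid = kde_grid_for_points(pts, grid.cell_size, h)
    pooled = kde_density(pts, pooled_grid, bandwidth=h)
    poly, _ = volume_contour(pooled, level)

    per_indiv: dict[str, float] = {}
    for indiv, g in sub.frame.groupby("individual_id"):
        ipts = g[["x", "y"]].to_numpy(float)
        try:
            ih = scott_bandwidth(ipts) if bandwidth == "auto" else h
        except ValueError:
            logger.warning("species_range(%s): individual %s has degenerate spread; skipped",
                           species, indiv)
            continue
        igrid = kde_grid_for_points(ipts, grid.cell_size, ih)
        ipoly, _ = volume_contour(kde_density(ipts, igrid, bandwidth=ih), level)
        per_indiv[str(indiv)] = ipoly.area / 1e6
    if not per_indiv:
        raise ValueError(f"no individual of {species!r} yielded a usable range")
    return RangeEstimate(
        species=species,
        polygons=poly,
        isopleth=level,
        area_km2=poly.area / 1e6,
        per_individual_areas_km2=per_indiv,
        median_individual_area_km2=float(np.median(list(per_indiv.values()))),
        bandwidth_m=h,
    )


# ---------------------------------------------------------------------------
# Pseudo-absences
# ---------------------------------------------------------------------------

def generate_pseudo_absences(presences: np.ndarray, median_area_km2: float,
                             boundary: BoundaryPolygon, seed: int = 0,
                             species: str = "") -> PseudoAbsenceSet:
    """Sample one background point per presence, outside all exclusion discs.

    A disc whose area equals the median individual range is centred on every
    presence point (radius sqrt(area/pi)); points are drawn uniformly in the
    boundary by seeded rejection sampling and accepted when farther than the
    radius from every presence.
    """
    presences = np.asarray(presences, float).reshape(-1, 2)
    if median_area_km2 <= 0:
        raise ValueError("median_area_km2 must be > 0")
    if len(presences) == 0:
        raise ValueError("need at least one presence point")
    radius = float(np.sqrt(median_area_km2 * 1e6 / np.pi))

    discs = shapely.union_all(shapely.buffer(shapely.points(presences), radius))
    available = boundary.geometry.difference(discs)
    if available.area < 0.01 * boundary.geometry.area:
        raise ValueError("exclusion zone covers study area")

    rng = np.random.default_rng(seed)
    tree = cKDTree(presences)
    minx, miny, maxx, maxy = boundary.geometry.bounds
    need = len(presences)
    accepted: list[np.ndarray] = []
    n_acc = 0
    draws = 0
    while n_acc < need:
        if draws >= MAX_REJECTION_DRAWS:
            raise RuntimeError("pseudo-absence rejection sampling exceeded draw cap")
        batch = min(4 * need + 100, MAX_REJECTION_DRAWS - draws)
        xs = rng.uniform(minx, maxx, batch)
        ys = rng.uniform(miny, maxy, batch)
        draws += batch
        ok = boundary.contains_points(xs, ys)
        if ok.any():
            cand = np.column_stack([xs[ok], ys[ok]])
            d, _ = tree.query(cand, k=1)
            cand = cand[d > radius]
            if len(cand):
                accepted.append(cand[: need - n_acc])
                n_acc += len(accepted[-1])
    points = np.concatenate(accepted)[:need]
    return PseudoAbsenceSet(species=species, points=points,
                            exclusion_radius_m=radius, seed=seed)
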