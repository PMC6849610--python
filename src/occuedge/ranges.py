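"""Species range cell sets and the distance-to-range-edge metric D0 / D'.

A species' occupied range is represented as the set of grid cells that
either contain at least one native record or intersect the species' range
polygon.  For each range cell j we compute D0(j), the geometric mean of the
great-circle distances from j's centroid to the centroids of all *other*
range cells; dividing by the species' largest D0 gives the standardised
range-position score D' in (0, 1].  D' = 1 marks the range edge; interior
cells, being surrounded by nearby cells, have smaller geometric-mean
distances and hence smaller D'.  Single-cell ranges are all edge by
convention (D' = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec

#: Mean Earth radius, km, used for great-circle distances between centroids.
#: Distances are geodesic (projection-independent) rather than projected.
DISTANCE_RADIUS_KM = 6371.0088


class RangeError(ValueError):
    """Raised when a species has no usable range cells."""


@dataclass
class SpeciesRangeCells:
    """Per-species range cells with distance-to-edge scores.

    Attributes
    ----------
    species_id
        Species identifier.
    cells
        Sorted array of range cell ids.
    d0
        Geometric-mean centroid distance per cell, km (NaN for a
        single-cell range, where the mean is over an empty set).
    dprime
        D0 standardised by the species' maximum D0; in (0, 1] with the
        arg-max cell(s) at exactly 1.
    """

    species_id: object
    cells: np.ndarray
    d0: np.ndarray | None = None
    dprime: np.ndarray | None = None

    @property
    def size(self) -> int:
        return int(self.cells.size)

    def dprime_of(self, cell_ids) -> np.ndarray:
        idx = np.searchsorted(self.cells, cell_ids)
        if np.any(idx >= self.cells.size) or np.any(self.cells[np.minimum(idx, self.cells.size - 1)] != cell_ids):
            raise KeyError("cell not in range")
        return self.dprime[idx]


def great_circle_km(lon1, lat1, lon2, lat2, radius_km: float = DISTANCE_RADIUS_KM):
    """Great-circle distance between points in degrees, via haversine."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def build_range_cells(record_cells, polygon_cells, species_id) -> SpeciesRangeCells:
    """Union record-bearing cells with polygon-covered cells.

    ``record_cells`` must already be restricted to native occurrences;
    non-native records never contribute range cells.
    """
    cells = np.union1d(
        np.asarray(list(record_cells), dtype=np.int64),
        np.asarray(list(polygon_cells), dtype=np.int64),
    )
    if cells.size == 0:
        raise RangeError(f"species {species_id!r} has no range cells (no native records, empty polygon)")
    return SpeciesRangeCells(species_id=species_id, cells=cells)


def compute_d0(rng: SpeciesRangeCells, grid: GridSpec) -> np.ndarray:
    """Geometric-mean great-circle distance from each cell to all others, km.

    Vectorised over the full pairwise centroid-distance matrix; the cell's
    own zero distance is excluded from the mean (it would annihilate a
    geometric mean).  Single-cell ranges return NaN (D' is set to 1
    directly by :func:`standardize_dprime`).
    """
    n = rng.size
    if n == 1:
        return np.array([np.nan])
    lon, lat = grid.cell_centroid_lonlat(rng.cells)
    d = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] <= 0.0):
        raise ValueError("distinct cells share a centroid; grid malformed")
    logd = np.where(off, np.log(d, out=np.zeros_like(d), where=off), 0.0)
    return np.exp(logd.sum(axis=1) / (n - 1))


def standardize_dprime(d0: np.ndarray) -> np.ndarray:
    """D' = D0 / max(D0); the arg-max cell gets exactly 1.

    A single-cell range (D0 undefined) is scored D' = 1: a range that
    small is all edge.
    """
    d0 = np.asarray(d0, dtype=float)
    if d0.size == 1 and np.isnan(d0[0]):
        return np.ones(1)
    if np.any(~np.isfinite(d0)) or np.any(d0 <= 0.0):
        raise ValueError("D0 must be positive and finite")
    dprime = d0 / d0.max()
    # guarantee the max is exactly 1 despite floating division
    dprime[np.argmax(d0)] = 1.0
    return dprime


def attach_dprime(rng: SpeciesRangeCells, grid: GridSpec) -> SpeciesRangeCells:
    """Compute and attach d0 and dprime in place; returns the range."""
    rng.d0 = compute_d0(rng, grid)
    rng.dprime = standardize_dprime(rng.d0)
    return rng


def ranges_from_tables(
    records: pd.DataFrame | None,
    species_cells: pd.DataFrame | None,
    grid: GridSpec,
) -> dict:
    """Build scored ranges for every species from the two input routes.

    Parameters
    ----------
    records
        Record table with columns species_id, cell_id, native (may be None).
        Only native records contribute cells.
    species_cells
        Two-column table species_id, cell_id from range polygons
        (may be None).

    Returns
    -------
    dict mapping species_id -> :class:`SpeciesRangeCells` with D0/D' attached.
    """
    rec_cells: dict = {}
    if records is not None and len(records):
        native = records[records["native"].astype(bool)]
        for sp, sub in native.groupby("species_id"):
            rec_cells[sp] = set(int(c) for c in sub["cell_id"])
    poly_cells: dict = {}
    if species_cells is not None and len(species_cells):
        for sp, sub in species_cells.groupby("species_id"):
            poly_cells[sp] = set(int(c) for c in sub["cell_id"])
    out = {}
    for sp in sorted(set(rec_cells) | set(poly_cells), key=str):
        rng = build_range_cells(rec_cells.get(sp, ()), poly_cells.get(sp, ()), sp)
        out[sp] = attach_dprime(rng, grid)
    return out


def polygon_to_cells(polygon, grid: GridSpec) -> np.ndarray:
    """Cells whose projected bounding box intersects a lon/lat polygon.

    The polygon's vertices are projected to the Behrmann plane and the
    intersection test runs in projected space (adequate for the smooth,
    mid-latitude polygons this pipeline consumes).
    """
    from shapely.geometry import box
    from shapely.ops import transform

    proj = transform(lambda x, y: grid.project(x, y), polygon)
    x0, y0, x1, y1 = proj.bounds
    gx0, gy0 = grid.origin
    c0 = max(int(np.floor((x0 - gx0) / grid.cell_edge_km)), 0)
    c1 = min(int(np.floor((x1 - gx0) / grid.cell_edge_km)), grid.n_cols - 1)
    r0 = max(int(np.floor((y0 - gy0) / grid.cell_edge_km)), 0)
    r1 = min(int(np.floor((y1 - gy0) / grid.cell_edge_km)), grid.n_rows - 1)
    hits = []
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            cid = r * grid.n_cols + c
            bx0, by0, bx1, by1 = grid.cell_bounds(cid)
            if proj.intersects(box(bx0, by0, bx1, by1)):
                hits.append(cid)
    return np.asarray(sorted(hits), dtype=np.int64)


def ranges_table(ranges: dict, cell_attrs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flatten ranges to a frame: species_id, cell_id, D0_km, Dprime[, R, C]."""
    parts = []
    for sp, rng in ranges.items():
        parts.append(
            pd.DataFrame(
                {
                    "species_id": sp,
                    "cell_id": rng.cells,
                    "D0_km": rng.d0,
                    "Dprime": rng.dprime,
                }
            )
        )
    df = pd.concat(parts, ignore_index=True)
    if cell_attrs is not None:
        df = df.join(cell_attrs[["R", "C"]], on="cell_id")
    return df
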