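"""Equal-area grid: Behrmann projection, cell indexing, and per-cell covariates.

The analysis grid is a cylindrical equal-area (Behrmann, standard parallel
30°) grid of square cells in projected space.  Point records in geographic
coordinates are projected and binned into half-open cell bounding boxes, so
the grid partitions the projected plane: every point maps to exactly one
cell.  Cells additionally carry two covariates used by the occupancy model:
a biogeographic realm indicator R (0 = Palearctic-like, 1 = Indo-Malaya-like)
and a land-conversion class C (1 when more than one third of the cell's land
has been converted for human use).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Equatorial radius used for the projection, km (WGS84 semi-major axis).
EARTH_RADIUS_KM = 6378.137

#: Fraction of converted land above which a cell counts as human-dominated.
CONVERSION_THRESHOLD = 1.0 / 3.0

#: Realm label -> model coding (R). 0 = Palearctic-like, 1 = Indo-Malaya-like.
DEFAULT_REALM_CODING = {
    "Palearctic": 0,
    "Indo-Malaya": 1,
    "palearctic": 0,
    "indo-malaya": 1,
}


class GridError(ValueError):
    """Raised for points outside the grid or malformed grid input."""


@dataclass(frozen=True)
class GridSpec:
    """Behrmann equal-area grid specification.

    Parameters
    ----------
    cell_edge_km
        Edge length of the (square) projected cells, km.  The default of
        48.24 km corresponds to a 30 arc-minute resolution grid.
    radius_km
        Radius of the spherical Earth model used by the projection, km.
    std_parallel_deg
        Standard parallel of the cylindrical equal-area projection
        (30° for Behrmann).
    """

    cell_edge_km: float = 48.24
    radius_km: float = EARTH_RADIUS_KM
    std_parallel_deg: float = 30.0
    # Projected origin (lower-left corner of cell (0, 0)), km.  Defaults to
    # the lower-left corner of the world extent.
    origin: tuple[float, float] | None = None
    n_cols: int = field(init=False)
    n_rows: int = field(init=False)

    def __post_init__(self) -> None:
        k = np.cos(np.radians(self.std_parallel_deg))
        width = 2.0 * np.pi * self.radius_km * k
        height = 2.0 * self.radius_km / k
        if self.origin is None:
            object.__setattr__(self, "origin", (-width / 2.0, -height / 2.0))
        object.__setattr__(self, "n_cols", int(np.ceil(width / self.cell_edge_km)))
        object.__setattr__(self, "n_rows", int(np.ceil(height / self.cell_edge_km)))

    # -- projection ---------------------------------------------------------

    def project(self, lon, lat):
        """Project geographic coordinates (degrees) to Behrmann x, y in km.

        x = R * lambda * cos(phi_s),  y = R * sin(phi) / cos(phi_s).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 90.0) or np.any(lon < -180.0) or np.any(lon >= 180.0 + 1e-9):
            bad = np.argwhere(
                (np.abs(lat) > 90.0) | (lon < -180.0) | (lon >= 180.0 + 1e-9)
            )
            raise GridError(f"coordinates out of range at positions {bad.ravel().tolist()[:5]}")
        k = np.cos(np.radians(self.std_parallel_deg))
        x = self.radius_km * np.radians(lon) * k
        y = self.radius_km * np.sin(np.radians(lat)) / k
        return x, y

    def unproject(self, x, y):
        """Inverse of :meth:`project`; returns (lon, lat) in degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = np.cos(np.radians(self.std_parallel_deg))
        lon = np.degrees(x / (self.radius_km * k))
        sinphi = np.clip(y * k / self.radius_km, -1.0, 1.0)
        lat = np.degrees(np.arcsin(sinphi))
        return lon, lat

    # -- cell indexing ------------------------------------------------------

    def cell_of_xy(self, x, y):
        """Map projected coordinates to cell ids (half-open boxes).

        A point exactly on a shared edge belongs to the cell on the
        higher-index side, so cells tile the plane without overlap.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_edge_km).astype(np.int64)
        row = np.floor((y - y0) / self.cell_edge_km).astype(np.int64)
        if np.any(col < 0) or np.any(col >= self.n_cols) or np.any(row < 0) or np.any(row >= self.n_rows):
            raise GridError("projected point outside grid extent")
        return row * self.n_cols + col

    def point_to_cell(self, lon, lat):
        """Assign geographic points to grid cells."""
        x, y = self.project(lon, lat)
        return self.cell_of_xy(x, y)

    def rowcol(self, cell_id):
        cell_id = np.asarray(cell_id, dtype=np.int64)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_id(self, row, col):
        row = np.asarray(row, dtype=np.int64)
        col = np.asarray(col, dtype=np.int64)
        if np.any((row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)):
            raise GridError("row/col outside grid")
        return row * self.n_cols + col

    def cell_bounds(self, cell_id):
        """(x0, y0, x1, y1) of the half-open projected bounding box, km."""
        row, col = self.rowcol(cell_id)
        x0 = self.origin[0] + col * self.cell_edge_km
        y0 = self.origin[1] + row * self.cell_edge_km
        return x0, y0, x0 + self.cell_edge_km, y0 + self.cell_edge_km

    def cell_centroid_xy(self, cell_id):
        x0, y0, x1, y1 = self.cell_bounds(cell_id)
        return (x0 + x1) / 2.0, (y0 + y1) / 2.0

    def cell_centroid_lonlat(self, cell_id):
        """Geographic centroid (lon, lat degrees) of cells' projected boxes."""
        x, y = self.cell_centroid_xy(cell_id)
        return self.unproject(x, y)


# -- cell covariates --------------------------------------------------------


def classify_conversion(converted_fraction):
    """Land-conversion class C from the converted-land fraction.

    C = 1 (human-dominated) iff strictly more than one third of the cell's
    land was converted; exactly one third classes as unconverted.
    """
    frac = np.asarray(converted_fraction, dtype=float)
    if np.any((frac < 0.0) | (frac > 1.0)):
        raise ValueError("converted_fraction must lie in [0, 1]")
    return (frac > CONVERSION_THRESHOLD).astype(np.int64)


def assign_realm(labels, coding: dict | None = None):
    """Map realm labels to the model's binary coding R.

    R = 0 for Palearctic-like cells, 1 for Indo-Malaya-like cells.  Labels
    absent from ``coding`` yield -1 (callers exclude such cells).
    """
    coding = DEFAULT_REALM_CODING if coding is None else coding
    ser = pd.Series(labels)
    out = ser.map(coding)
    return out.fillna(-1).astype(np.int64).to_numpy()


def load_cell_attributes(path_or_df, coding: dict | None = None) -> pd.DataFrame:
    """Read a per-cell attribute table (cell_id, realm, converted_fraction).

    Returns a frame indexed by cell_id with columns realm, converted_fraction,
    R and C; cells whose realm label is not recognised are dropped.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    required = {"cell_id", "realm", "converted_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell attribute table missing columns {sorted(missing)}")
    df = df.copy()
    df["R"] = assign_realm(df["realm"], coding)
    df["C"] = classify_conversion(df["converted_fraction"])
    n_bad = int((df["R"] < 0).sum())
    if n_bad:
        import warnings

        warnings.warn(f"excluding {n_bad} cells with unrecognised realm label")
        df = df[df["R"] >= 0]
    return df.set_index("cell_id")
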