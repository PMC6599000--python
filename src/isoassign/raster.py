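"""Regular geographic grids and single-band rasters.

Rasters are stored row 0 = southernmost row (latitude increases with row
index) with NaN as nodata, and serialised as plain-text ESRI ASCII grids
(``.asc``), which store rows north-to-south; the flip is handled on I/O.
Coordinates are geographic WGS84 degrees throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Regular lon/lat grid defined by its lower-left corner and square cells."""

    lon_min: float
    lat_min: float
    cell: float  # cell size, degrees
    ncols: int
    nrows: int

    def __post_init__(self):
        if self.cell <= 0 or self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have positive cell size and dimensions")

    @classmethod
    def from_bbox(cls, bbox, cell):
        """Smallest grid with the given cell size covering (lon_min, lat_min, lon_max, lat_max)."""
        lon_min, lat_min, lon_max, lat_max = bbox
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ValueError("degenerate bounding box")
        ncols = int(np.ceil((lon_max - lon_min) / cell - 1e-9))
        nrows = int(np.ceil((lat_max - lat_min) / cell - 1e-9))
        return cls(lon_min, lat_min, cell, max(ncols, 1), max(nrows, 1))

    @property
    def lon_max(self):
        return self.lon_min + self.cell * self.ncols

    @property
    def lat_max(self):
        return self.lat_min + self.cell * self.nrows

    @property
    def lons(self):
        """Cell-centre longitudes, west to east."""
        return self.lon_min + self.cell * (0.5 + np.arange(self.ncols))

    @property
    def lats(self):
        """Cell-centre latitudes, south to north (matches row order)."""
        return self.lat_min + self.cell * (0.5 + np.arange(self.nrows))

    def meshgrid(self):
        """(lon, lat) arrays of shape (nrows, ncols) at cell centres."""
        return np.meshgrid(self.lons, self.lats)

    @property
    def size(self):
        return self.ncols * self.nrows

    def cell_of(self, lon, lat):
        """(row, col) containing each point; -1 where outside the grid."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell).astype(int)
        row = np.floor((lat - self.lat_min) / self.cell).astype(int)
        # points exactly on the north/east edge belong to the last cell
        col = np.where((lon == self.lon_max) & (col == self.ncols), self.ncols - 1, col)
        row = np.where((lat == self.lat_max) & (row == self.nrows), self.nrows - 1, row)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        return np.where(bad, -1, row), np.where(bad, -1, col)


@dataclass
class Raster:
    """One gridded surface; ``values`` has shape (nrows, ncols), NaN = nodata."""

    grid: Grid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.nrows}, {self.grid.ncols})"
            )

    @property
    def mask(self):
        """True where nodata."""
        return ~np.isfinite(self.values)

    def interp(self, lon, lat):
        """Bilinear interpolation at points, extrapolating linearly past
        the outermost cell centres (so a planar surface stays exact
        everywhere in the grid's extent)."""
        from scipy.interpolate import RegularGridInterpolator

        itp = RegularGridInterpolator(
            (self.grid.lats, self.grid.lons), self.values,
            method="linear", bounds_error=False, fill_value=None,
        )
        pts = np.column_stack([np.atleast_1d(lat), np.atleast_1d(lon)])
        out = itp(pts)
        return out if np.ndim(lon) else float(out[0])

    def sample(self, lon, lat):
        """Value of the containing cell at each point; NaN outside the grid."""
        row, col = self.grid.cell_of(lon, lat)
        out = np.where(row >= 0, self.values[row, col], np.nan)
        return out

    def to_ascii(self, path, nodata=-9999.0):
        """Write as an ESRI ASCII grid (plain text, rows north to south)."""
        path = Path(path)
        vals = np.where(np.isfinite(self.values), self.values, nodata)
        header = (
            f"ncols {self.grid.ncols}\n"
            f"nrows {self.grid.nrows}\n"
            f"xllcorner {float(self.grid.lon_min)!r}\n"
            f"yllcorner {float(self.grid.lat_min)!r}\n"
            f"cellsize {float(self.grid.cell)!r}\n"
            f"NODATA_value {float(nodata)!r}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, vals[::-1], fmt="%.8g")

    @classmethod
    def from_ascii(cls, path):
        path = Path(path)
        with path.open() as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)[::-1].copy()
        vals[vals == hdr["nodata_value"]] = np.nan
        grid = Grid(hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"],
                    int(hdr["ncols"]), int(hdr["nrows"]))
        return cls(grid, vals)
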