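"""Regular lon/lat grid container and plain-text raster I/O.

All gridded layers in the package live on a shared :class:`GridSpec`:
a regular geographic grid with row 0 at the northern edge (raster
convention). Cell areas vary with cos(latitude), so area-weighted
statistics are meaningful at global extents.

Rasters are persisted as ESRI ASCII grids (``.asc``) — a simple,
widely understood text format (header of six key/value lines followed
by whitespace-separated rows, north row first).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: kilometres per degree of latitude on a sphere of radius 6371 km
KM_PER_DEG = 6371.0 * 2 * np.pi / 360.0

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic grid.

    Parameters
    ----------
    nrows, ncols
        Cell counts; row 0 is the northernmost row.
    lon_min, lat_min
        Coordinates of the grid's south-west corner (cell edge), degrees.
    cell_size
        Cell edge length in degrees (square cells).
    """

    nrows: int
    ncols: int
    lon_min: float
    lat_min: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nrows * self.cell_size

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.ncols * self.cell_size

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.ncols) + 0.5) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        """Latitude of cell centroids, row 0 first (northernmost)."""
        return self.lat_max - (np.arange(self.nrows) + 0.5) * self.cell_size

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon2d, lat2d) arrays of cell centroids, shape (nrows, ncols)."""
        lon2d, lat2d = np.meshgrid(self.lon_centers, self.lat_centers)
        return lon2d, lat2d

    def cell_area_km2(self) -> np.ndarray:
        """Per-cell area in km², shrinking with cos(latitude)."""
        _, lat2d = self.centroids()
        dy = self.cell_size * KM_PER_DEG
        dx = self.cell_size * KM_PER_DEG * np.cos(np.radians(lat2d))
        return dx * dy

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col); half-open cell intervals.

        Points off the grid get row/col of -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        row = np.floor((self.lat_max - lat) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray,
                     nodata: float = NODATA, fmt: str = "%.6g") -> None:
    """Write a 2-D layer as an ESRI ASCII grid. NaN becomes ``nodata``."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"layer shape {values.shape} != grid shape {grid.shape}")
    out = np.where(np.isnan(values), nodata, values)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.lon_min:.10g}\n"
        f"yllcorner {grid.lat_min:.10g}\n"
        f"cellsize {grid.cell_size:.10g}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        lon_min=header["xllcorner"],
        lat_min=header["yllcorner"],
        cell_size=header["cellsize"],
    )
    values = values.reshape(grid.shape)
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return grid, values
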