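"""Shared geometry primitives: great-circle distance, equal-area
hexagonal blocking, connected-patch labeling and patch distances.

These back the spatial thinning, spatial-block cross-validation and
the dispersal-constraint clipping used by the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridSpec

EARTH_RADIUS_KM = 6371.0

ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
QUEEN = np.ones((3, 3), dtype=bool)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays of degrees.
    """
    lat1a, lat2a = np.asarray(lat1, float), np.asarray(lat2, float)
    if np.any(np.abs(lat1a) > 90) or np.any(np.abs(lat2a) > 90):
        raise ValueError("latitude out of range [-90, 90]")
    p1, p2 = np.radians(lat1a), np.radians(lat2a)
    dphi = p2 - p1
    dlmb = np.radians(np.asarray(lon2, float) - np.asarray(lon1, float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def pairwise_haversine_km(lon: np.ndarray, lat: np.ndarray,
                          lon2: np.ndarray | None = None,
                          lat2: np.ndarray | None = None) -> np.ndarray:
    """Distance matrix (km) between two sets of points (or one set with itself)."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    if lon2 is None:
        lon2, lat2 = lon, lat
    return haversine_km(lon[:, None], lat[:, None],
                        np.asarray(lon2, float)[None, :],
                        np.asarray(lat2, float)[None, :])


@dataclass
class HexBlocking:
    """Assignment of grid cells to equal-area hexagonal blocks."""

    block_id: np.ndarray          # int, shape (nrows, ncols)
    block_diameter_km: float
    n_blocks: int


def hex_blocks(grid: GridSpec, diameter_km: float) -> HexBlocking:
    """Tile the grid with equal-area hexagons and assign each cell to one.

    Cell centroids are projected with a cylindrical equal-area projection
    whose standard parallel is the grid's mean latitude, then snapped to
    the containing hexagon of a flat-top lattice with corner-to-corner
    diameter ``diameter_km``. Block ids are renumbered in row-major order
    of first appearance, so the labeling is deterministic.
    """
    min_cell_km = grid.cell_size * 111.195 * max(
        np.cos(np.radians(np.abs(grid.lat_centers)).max()), 0.05)
    if diameter_km <= min_cell_km:
        raise ValueError(
            f"hex diameter {diameter_km} km must exceed one cell (~{min_cell_km:.1f} km)")
    lon2d, lat2d = grid.centroids()
    phi0 = np.radians(0.5 * (grid.lat_min + grid.lat_max))
    c0 = np.cos(phi0)
    x = np.radians(lon2d) * EARTH_RADIUS_KM * c0
    y = np.sin(np.radians(lat2d)) * EARTH_RADIUS_KM / c0

    size = diameter_km / 2.0  # hexagon circumradius
    # flat-top axial coordinates with cube rounding (containment test)
    q = (2.0 / 3.0 * x) / size
    r = (-1.0 / 3.0 * x + np.sqrt(3.0) / 3.0 * y) / size
    qi, ri = _cube_round(q, r)

    keys = qi.astype(np.int64) * 1_000_003 + ri.astype(np.int64)
    flat = keys.ravel()
    _, first_idx, inverse = np.unique(flat, return_index=True, return_inverse=True)
    # renumber by row-major first appearance
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    block = rank[inverse].reshape(grid.shape).astype(int)
    return HexBlocking(block_id=block, block_diameter_km=float(diameter_km),
                       n_blocks=int(block.max()) + 1)


def _cube_round(q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = -q - r
    qi, ri, si = np.rint(q), np.rint(r), np.rint(s)
    dq, dr, ds = np.abs(qi - q), np.abs(ri - r), np.abs(si - s)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    qi = np.where(fix_q, -ri - si, qi)
    ri = np.where(fix_r, -qi - si, ri)
    return qi.astype(int), ri.astype(int)


@dataclass
class PatchLabeling:
    """Connected components of a binary presence map.

    ``patch_id`` is 0 on absence cells and 1..n_patches on presence
    cells; components are numbered in row-major order of their first
    cell.
    """

    patch_id: np.ndarray
    n_patches: int

    def cells_of(self, patch: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of the cells of one patch (1-based id)."""
        return np.nonzero(self.patch_id == patch)


def label_patches(binary: np.ndarray, connectivity: str = "queen") -> PatchLabeling:
    """Label contiguous presence patches under rook (4) or queen (8) adjacency."""
    if connectivity not in ("rook", "queen"):
        raise ValueError("connectivity must be 'rook' or 'queen'")
    structure = QUEEN if connectivity == "queen" else ROOK
    labels, n = ndimage.label(np.asarray(binary, bool), structure=structure)
    # scipy already labels in row-major scan order; make that explicit
    if n > 1:
        flat = labels.ravel()
        first = np.full(n + 1, flat.size, dtype=int)
        nz = np.nonzero(flat)[0]
        np.minimum.at(first, flat[nz], nz)
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=int)
        remap[1 + order] = np.arange(1, n + 1)
        labels = remap[labels]
    return PatchLabeling(patch_id=labels, n_patches=int(n))


def patch_min_distance(labeling: PatchLabeling, p1: int, p2: int,
                       grid: GridSpec) -> float:
    """Minimum great-circle distance (km) between two patches' cell centroids."""
    lon2d, lat2d = grid.centroids()
    r1, c1 = labeling.cells_of(p1)
    r2, c2 = labeling.cells_of(p2)
    if r1.size == 0 or r2.size == 0:
        raise ValueError("patch is empty")
    d = pairwise_haversine_km(lon2d[r1, c1], lat2d[r1, c1],
                              lon2d[r2, c2], lat2d[r2, c2])
    return float(d.min())


def min_distance_to_cells(labeling: PatchLabeling, patch: int,
                          cell_mask: np.ndarray, grid: GridSpec) -> float:
    """Minimum distance (km) from a patch to any cell in a boolean mask."""
    lon2d, lat2d = grid.centroids()
    r1, c1 = labeling.cells_of(patch)
    r2, c2 = np.nonzero(cell_mask)
    if r1.size == 0 or r2.size == 0:
        raise ValueError("empty patch or empty cell mask")
    d = pairwise_haversine_km(lon2d[r1, c1], lat2d[r1, c1],
                              lon2d[r2, c2], lat2d[r2, c2])
    return float(d.min())
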