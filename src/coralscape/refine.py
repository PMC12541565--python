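"""Refinement of continuous suitability into binary ranges.

Three ordered steps, each only ever removing presence cells:

1. thresholding at the minimum-training-presence (MTP) cut-off that
   keeps at least 95% of training presences classified present;
2. dispersal clipping — habitat patches are kept only if they contain
   an occurrence record or lie within a maximum dispersal distance
   (default 200 km) of a patch that does; future-scenario maps are
   clipped against present-day occupied patches, assuming larvae cannot
   cross unsuitable habitat;
3. depth clipping to the species' known depth range, falling back to
   genus-level mean limits where no species-level range exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec
from .spatial import PatchLabeling, label_patches, min_distance_to_cells

log = logging.getLogger(__name__)

SENSITIVITY_TARGET = 0.95
DEFAULT_DISPERSAL_KM = 200.0


def mtp_threshold(presence_suitability: np.ndarray,
                  target: float = SENSITIVITY_TARGET) -> tuple[float, float]:
    """Minimum-training-presence threshold with guaranteed sensitivity.

    Returns the largest suitability value ``t`` such that at least
    ``target`` of the training presences have suitability >= t (the
    lower-tie-inclusive 5th-percentile order statistic for the default
    target), together with the sensitivity achieved at ``t``.
    """
    s = np.asarray(presence_suitability, float)
    if s.size == 0:
        raise ValueError("no presence suitabilities")
    if np.isnan(s).any():
        bad = np.nonzero(np.isnan(s))[0]
        raise ValueError(f"undefined suitability at presence records {bad.tolist()}")
    srt = np.sort(s)
    k = int(np.floor((1.0 - target) * s.size))
    k = min(k, s.size - 1)
    t = float(srt[k])
    sens = float((s >= t).mean())
    return t, sens


@dataclass
class DepthRange:
    species_id: str
    depth_min: float
    depth_max: float
    source: str = "species"     # "species" | "genus"

    def __post_init__(self) -> None:
        if not self.depth_min < self.depth_max:
            raise ValueError(f"{self.species_id}: depth_min must be < depth_max")


def resolve_depth_range(species_id: str, genus_id: str,
                        table: pd.DataFrame) -> DepthRange:
    """Look up a species depth range, averaging congener limits when the
    species itself is missing.

    ``table`` columns: species, genus, depth_min_m, depth_max_m.
    """
    hit = table[table["species"] == species_id]
    if len(hit):
        r = hit.iloc[0]
        return DepthRange(species_id, float(r["depth_min_m"]),
                          float(r["depth_max_m"]), source="species")
    congeners = table[table["genus"] == genus_id]
    if len(congeners) == 0:
        raise KeyError(f"no species- or genus-level depth data for {species_id} "
                       f"(genus {genus_id})")
    return DepthRange(species_id,
                      float(congeners["depth_min_m"].mean()),
                      float(congeners["depth_max_m"].mean()),
                      source="genus")


@dataclass
class BinaryRange:
    """Refined presence/absence per scenario with its provenance."""

    species_id: str
    presence: dict[str, np.ndarray]     # scenario -> bool grid
    threshold: float
    sensitivity_at_threshold: float
    steps_applied: list[str] = field(default_factory=list)
    cells_removed: dict[str, dict[str, int]] = field(default_factory=dict)


def dispersal_clip(binary: np.ndarray, source_cells: np.ndarray,
                   grid: GridSpec, max_dispersal_km: float = DEFAULT_DISPERSAL_KM,
                   connectivity: str = "queen"
                   ) -> tuple[np.ndarray, PatchLabeling, list[int]]:
    """Remove habitat patches unreachable from the source cells.

    A patch survives iff it contains a source cell (an occurrence, or —
    for future maps — a cell of a present-day occupied patch) or its
    nearest cell lies within ``max_dispersal_km`` of some source cell.
    Returns (clipped map, patch labeling, kept patch ids).
    """
    binary = np.asarray(binary, bool)
    src = np.asarray(source_cells, bool)
    labeling = label_patches(binary, connectivity)
    if labeling.n_patches == 0:
        return binary.copy(), labeling, []
    if not (binary & src).any() and not src.any():
        log.warning("no source cells: clipped range is empty")
        return np.zeros_like(binary), labeling, []
    occupied = sorted(set(np.unique(labeling.patch_id[src & binary])) - {0})
    kept = list(occupied)
    # reachability is measured to the occupied patches (their whole cells),
    # or directly to the source cells when no patch contains a source
    targets = np.isin(labeling.patch_id, occupied) if occupied else src
    for p in range(1, labeling.n_patches + 1):
        if p in occupied:
            continue
        if targets.any() and min_distance_to_cells(labeling, p, targets, grid) \
                <= max_dispersal_km:
            kept.append(p)
    out = np.isin(labeling.patch_id, kept)
    return out, labeling, sorted(kept)


def depth_clip(binary: np.ndarray, depth_range: DepthRange,
               bathymetry: np.ndarray) -> np.ndarray:
    """Remove presence cells whose depth falls outside the species range."""
    binary = np.asarray(binary, bool)
    if np.isnan(bathymetry[binary]).any():
        raise ValueError("bathymetry undefined on presence cells")
    ok = (bathymetry >= depth_range.depth_min) & (bathymetry <= depth_range.depth_max)
    return binary & ok


def refine_range(species_id: str,
                 suitability: dict[str, np.ndarray],
                 presence_cells: np.ndarray,
                 presence_suitability: np.ndarray,
                 depth_range: DepthRange,
                 bathymetry: np.ndarray,
                 grid: GridSpec,
                 max_dispersal_km: float = DEFAULT_DISPERSAL_KM,
                 connectivity: str = "queen",
                 present: str = "present") -> BinaryRange:
    """Apply the full three-step refinement to every scenario.

    ``presence_cells`` is the boolean grid of cells holding occurrence
    records; ``presence_suitability`` the present-day ensemble
    suitability at those records (defines the MTP threshold). Future
    scenarios are dispersal-clipped against the present-day occupied
    patches.
    """
    thr, sens = mtp_threshold(presence_suitability)
    removed: dict[str, dict[str, int]] = {}
    binmaps = {}
    for scen, suit in suitability.items():
        b0 = np.asarray(suit) >= thr
        removed[scen] = {"threshold": int(np.size(b0) - b0.sum())}
        binmaps[scen] = b0

    present_clipped, labeling, _ = dispersal_clip(
        binmaps[present], presence_cells, grid, max_dispersal_km, connectivity)
    occupied_patches = np.unique(
        labeling.patch_id[np.asarray(presence_cells, bool) & binmaps[present]])
    present_sources = np.isin(labeling.patch_id, sorted(set(occupied_patches) - {0}))

    out = {}
    for scen, b in binmaps.items():
        if scen == present:
            clipped = present_clipped
        else:
            clipped, _, _ = dispersal_clip(b, present_sources, grid,
                                           max_dispersal_km, connectivity)
        removed[scen]["dispersal"] = int(b.sum() - clipped.sum())
        final = depth_clip(clipped, depth_range, bathymetry)
        removed[scen]["depth"] = int(clipped.sum() - final.sum())
        out[scen] = final

    return BinaryRange(species_id=species_id, presence=out, threshold=thr,
                       sensitivity_at_threshold=sens,
                       steps_applied=["mtp_threshold", "dispersal_clip", "depth_clip"],
                       cells_removed=removed)
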