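"""Bioregion delineation by k-means over species-probability vectors.

Every grid cell with any predicted occupancy is a point in species
space (its vector of ensemble occurrence probabilities); k-means
partitions those points into bioregions, the cluster count is selected
from the BCSS/WCSS separation curve, the final centroids are related by
a Ward.D2 dendrogram, and each bioregion is summarised by richness,
endemicity, depth distribution and projected change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans

from .diversity import weighted_quantile

log = logging.getLogger(__name__)


@dataclass
class CellSpeciesMatrix:
    values: np.ndarray          # (n_cells_kept, n_species), in [0, 1]
    cell_index: np.ndarray      # flat grid index of each kept row
    species_ids: list[str]
    grid_shape: tuple[int, int]


def build_matrix(predictions: dict[str, np.ndarray],
                 species_order: list[str] | None = None,
                 mask: np.ndarray | None = None) -> CellSpeciesMatrix:
    """Assemble the cell x species probability matrix.

    Rows with zero probability for every species are always dropped
    (the map's blank areas). Because boosted learners emit small
    nonzero probabilities even in clearly unsuitable habitat, callers
    working from model output should additionally pass ``mask`` — the
    cells with predicted presence of at least one species after range
    refinement — so that the blank areas of the stacked map, not just
    numerically zero rows, stay out of the clustering.
    """
    species = species_order or sorted(predictions)
    shape = predictions[species[0]].shape
    cols = []
    for s in species:
        p = np.asarray(predictions[s], float)
        if p.shape != shape:
            raise ValueError(f"grid mismatch for {s}")
        if np.nanmin(p) < 0 or np.nanmax(p) > 1:
            raise ValueError(f"probabilities outside [0, 1] for {s}")
        cols.append(np.nan_to_num(p, nan=0.0).ravel())
    m = np.column_stack(cols)
    keep = m.sum(axis=1) > 0
    if mask is not None:
        keep &= np.asarray(mask, bool).ravel()
    return CellSpeciesMatrix(values=m[keep], cell_index=np.nonzero(keep)[0],
                             species_ids=list(species), grid_shape=shape)


@dataclass
class BioregionModel:
    k: int
    assignment: np.ndarray              # cluster per kept cell (0-based)
    centroids: np.ndarray               # (k, n_species)
    wcss: float
    bcss: float
    tss: float
    selection_curve: pd.DataFrame       # k, wcss, bcss, ratio
    dendrogram: np.ndarray | None       # scipy linkage matrix (Ward.D2)
    cell_index: np.ndarray
    grid_shape: tuple[int, int]
    species_ids: list[str] = field(default_factory=list)

    def assignment_grid(self) -> np.ndarray:
        """Bioregion id per grid cell (1-based), NaN on blank cells."""
        out = np.full(self.grid_shape[0] * self.grid_shape[1], np.nan)
        out[self.cell_index] = self.assignment + 1.0
        return out.reshape(self.grid_shape)


def fit_bioregions(matrix: CellSpeciesMatrix, k_range: range = range(2, 31),
                   n_init: int = 10, seed: int = 0,
                   selection: str = "silhouette",
                   silhouette_max_cells: int = 4000) -> BioregionModel:
    """Seeded k-means over the probability matrix for every candidate k.

    The separation statistic BCSS/WCSS (with BCSS(1) = 0) rises
    monotonically with k, so the cluster count must come from a
    better-behaved criterion. ``selection='silhouette'`` (default)
    picks the k of maximal mean silhouette width (computed on a seeded
    subsample when the matrix is large); ``selection='elbow'`` picks
    the k of maximal negative curvature of the ratio curve;
    ``selection='ratio_max'`` takes the literal argmax of the ratio.
    The final model satisfies BCSS + WCSS = TSS and nearest-centroid
    assignment with lowest-index tie-breaking.
    """
    X = matrix.values
    n = X.shape[0]
    ks = [k for k in k_range if k <= n]
    if len(ks) < len(list(k_range)):
        log.warning("k_range clipped to number of rows (%d)", n)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    sil_idx = None
    if selection == "silhouette" and n > silhouette_max_cells:
        sil_idx = np.random.default_rng([seed, 42]).choice(
            n, silhouette_max_cells, replace=False)
    models, rows = {}, []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, max_iter=300, tol=1e-6,
                    random_state=_seed32(seed, k), algorithm="lloyd")
        lab = km.fit_predict(X)
        wcss = float(km.inertia_)
        bcss = tss - wcss
        models[k] = (km, lab, wcss, bcss)
        row = {"k": k, "wcss": wcss, "bcss": bcss,
               "ratio": bcss / wcss if wcss > 0 else np.inf}
        if selection == "silhouette":
            sub = slice(None) if sil_idx is None else sil_idx
            labs = lab if sil_idx is None else lab[sil_idx]
            if len(np.unique(labs)) > 1:
                from sklearn.metrics import silhouette_score
                row["silhouette"] = float(silhouette_score(X[sub], labs))
            else:
                row["silhouette"] = float("nan")
        rows.append(row)
    curve = pd.DataFrame(rows)

    ratios = np.concatenate([[0.0], curve["ratio"].to_numpy()])  # prepend k=1
    kvals = np.concatenate([[1], curve["k"].to_numpy()])
    if selection == "ratio_max":
        best_k = int(curve.loc[curve["ratio"].idxmax(), "k"])
    elif selection == "elbow":
        # negative curvature of the ratio curve; needs interior points
        curv = ratios[:-2] - 2 * ratios[1:-1] + ratios[2:]
        best_k = int(kvals[1:-1][np.argmin(curv)]) if len(curv) else int(kvals[-1])
    elif selection == "silhouette":
        best_k = int(curve.loc[curve["silhouette"].idxmax(), "k"])
    else:
        raise ValueError(f"unknown selection rule {selection!r}")

    km, lab, wcss, bcss = models[best_k]
    centroids = km.cluster_centers_
    # enforce deterministic nearest-centroid assignment (lowest index on ties)
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    lab = np.argmin(d2, axis=1)
    dend = linkage(centroids, method="ward") if best_k >= 2 else None
    return BioregionModel(k=best_k, assignment=lab, centroids=centroids,
                          wcss=wcss, bcss=bcss, tss=tss, selection_curve=curve,
                          dendrogram=dend, cell_index=matrix.cell_index,
                          grid_shape=matrix.grid_shape,
                          species_ids=list(matrix.species_ids))


def centroid_dendrogram(model: BioregionModel) -> np.ndarray:
    """Ward.D2 merge tree over the final centroids (scipy linkage matrix).

    scipy's 'ward' linkage on the raw centroid coordinates implements
    the Ward.D2 criterion: merge heights are the square-rooted increase
    in within-cluster squared error, reducing to the Euclidean distance
    for two singletons.
    """
    if model.k < 2:
        raise ValueError("need at least two bioregions for a dendrogram")
    return linkage(model.centroids, method="ward")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as Newick with branch lengths
    derived from merge heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + i] = h
    return nodes[n + len(Z) - 1] + ";"


@dataclass
class BioregionSummary:
    region: int                 # 1-based
    n_cells: int
    area_km2: float
    sr: int                     # species with >= 1 presence cell in region
    endemics: int               # species confined to this region
    mean_depth_m: float
    depth_q05_m: float
    depth_q95_m: float
    #: per future scenario: {"delta_sr": int, "turnover": float}
    change: dict[str, dict[str, float]] = field(default_factory=dict)


def summarize_bioregions(model: BioregionModel,
                         ranges: dict[str, dict[str, np.ndarray]],
                         bathymetry: np.ndarray,
                         cell_area_km2: np.ndarray,
                         present: str = "present") -> list[BioregionSummary]:
    """Per-region richness, endemicity, depth and scenario change.

    ``ranges``: scenario -> species -> binary grid. Region-level losses
    and gains compare the sets of species present anywhere in the
    region between scenarios, and turnover follows the same
    (L+G)/(SR+G) form as the per-cell statistic.
    """
    region_grid = model.assignment_grid()
    species = model.species_ids
    scen_names = [s for s in ranges if s != present]

    # species set per region per scenario
    sets: dict[str, list[set[str]]] = {}
    for scen, by_sp in ranges.items():
        per_region: list[set[str]] = [set() for _ in range(model.k)]
        for sp in species:
            b = np.asarray(by_sp[sp], bool)
            regs = np.unique(region_grid[b & ~np.isnan(region_grid)])
            for r in regs:
                per_region[int(r) - 1].add(sp)
        sets[scen] = per_region

    # endemics from the present scenario
    region_count = {sp: 0 for sp in species}
    for r in range(model.k):
        for sp in sets[present][r]:
            region_count[sp] += 1

    out = []
    flat_bathy = bathymetry.ravel()
    flat_area = cell_area_km2.ravel()
    flat_region = region_grid.ravel()
    for r in range(model.k):
        mask = flat_region == r + 1
        depths = flat_bathy[mask]
        areas = flat_area[mask]
        sr_set = sets[present][r]
        endems = sum(1 for sp in sr_set if region_count[sp] == 1)
        if mask.any():
            q05, q95 = weighted_quantile(depths, areas, [0.05, 0.95])
            mean_d = float((depths * areas).sum() / areas.sum())
        else:
            q05 = q95 = mean_d = float("nan")
        change = {}
        for scen in scen_names:
            fut = sets[scen][r]
            losses = len(sr_set - fut)
            gains = len(fut - sr_set)
            denom = len(sr_set) + gains
            change[scen] = {
                "delta_sr": len(fut) - len(sr_set),
                "turnover": (losses + gains) / denom if denom else float("nan"),
            }
        out.append(BioregionSummary(
            region=r + 1, n_cells=int(mask.sum()), area_km2=float(areas.sum()),
            sr=len(sr_set), endemics=endems, mean_depth_m=mean_d,
            depth_q05_m=q05, depth_q95_m=q95, change=change))
    return out


def _seed32(seed: int, salt: int) -> int:
    return int(np.random.default_rng([seed, 41, salt]).integers(0, 2**31 - 1))
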