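"""Occurrence preparation: spatial-autocorrelation-based thinning and
realm-restricted, climate-clustered pseudo-absence design.

The thinning distance is species-specific: a Mantel-style correlogram
relates predictor similarity to geographic distance, and records are
thinned at the first lag where similarity is no longer significantly
elevated. Pseudo-absences are drawn from cells inside the realms the
species occupies, away from its presences, stratified over k-means
climate clusters, with run structure depending on sample size: species
with more than 1000 presences get a single balanced 1:1 run, all others
get 10 runs of at least 100 pseudo-absences each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .spatial import pairwise_haversine_km
from .synthetic import CLIMATE_PREDICTORS, PREDICTORS, EnvironmentalStack

log = logging.getLogger(__name__)

#: presence-count threshold of the run-structure rule (strictly greater-than)
LARGE_SAMPLE_THRESHOLD = 1000
N_RUNS_SMALL = 10
MIN_PSEUDO_ABSENCES = 100


@dataclass
class Correlogram:
    """Distance-lagged predictor-similarity correlogram."""

    lag_edges_km: np.ndarray        # len n_bins + 1, strictly increasing
    r: np.ndarray                   # Mantel correlation per lag
    p: np.ndarray                   # one-sided permutation p per lag (r > 0)
    thinning_distance_km: float
    fallback: bool = False


@dataclass
class OccurrenceSet:
    """Model-ready records for one species."""

    species_id: str
    presences: pd.DataFrame
    pseudo_absences: pd.DataFrame   # with run_id (1-based) and cluster_id
    thinning_distance_km: float
    n_runs: int
    n_pa_per_run: int

    def run(self, run_id: int) -> pd.DataFrame:
        """Presences + the pseudo-absences of one run, with binary label."""
        pres = self.presences.copy()
        pres["label"] = 1
        pa = self.pseudo_absences[self.pseudo_absences.run_id == run_id].copy()
        pa["label"] = 0
        return pd.concat([pres, pa], ignore_index=True)


def estimate_thinning_distance(presences: pd.DataFrame,
                               stack: EnvironmentalStack,
                               max_lag_km: float = 500.0,
                               n_bins: int = 10,
                               n_permutations: int = 199,
                               alpha: float = 0.05,
                               fallback_km: float | None = None,
                               seed: int = 0) -> Correlogram:
    """Choose the species-specific thinning distance from a correlogram.

    For all presence pairs, predictor similarity (negative standardized
    predictor distance) is correlated, per geographic-distance lag, with
    lag membership (a Mantel correlogram); significance comes from
    permuting record identities. The thinning distance is the lower edge
    of the first lag whose correlation is not significantly positive at
    ``alpha``; if similarity stays elevated through every lag the
    distance is capped at ``max_lag_km``.

    With fewer than 10 presences the correlogram is unreliable and a
    configured fallback (default: one cell diagonal) is returned.
    """
    grid = stack.grid
    if fallback_km is None:
        fallback_km = grid.cell_size * 111.195 * np.sqrt(2.0)
    edges = np.linspace(0.0, max_lag_km, n_bins + 1)
    n = len(presences)
    if n < 10:
        log.warning("only %d presences: falling back to thinning distance %.1f km",
                    n, fallback_km)
        return Correlogram(edges, np.full(n_bins, np.nan), np.full(n_bins, np.nan),
                           float(fallback_km), fallback=True)

    rows = presences["row"].to_numpy()
    cols = presences["col"].to_numpy()
    table = stack.predictor_table("present").reshape(grid.nrows, grid.ncols, -1)
    x = table[rows, cols, :]
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    geo = pairwise_haversine_km(presences["longitude"].to_numpy(),
                                presences["latitude"].to_numpy())
    env = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    geo_v, env_v = geo[iu], env[iu]
    if geo_v.max() <= edges[1]:
        raise ValueError("all point pairs fall in the first lag bin; "
                         "increase n_bins resolution or extent")
    sim = -(env_v - env_v.mean()) / (env_v.std() if env_v.std() > 0 else 1.0)

    rng = np.random.default_rng([seed, 11])
    r_obs = np.full(n_bins, np.nan)
    p_val = np.full(n_bins, np.nan)
    # permutations reshuffle record identities once per permutation and are
    # reused across lags (standard Mantel correlogram procedure)
    sims_p = []
    for _ in range(n_permutations):
        pm = rng.permutation(n)
        env_p = env[np.ix_(pm, pm)][iu]
        sims_p.append(-(env_p - env_p.mean()) / (env_p.std() or 1.0))
    for b in range(n_bins):
        member = ((geo_v > edges[b]) if b else (geo_v >= 0)) & (geo_v <= edges[b + 1])
        if member.sum() < 2 or member.all():
            continue
        mvec = member.astype(float)
        r_obs[b] = _pearson(sim, mvec)
        count = sum(1 for sp in sims_p if _pearson(sp, mvec) >= r_obs[b])
        p_val[b] = (1 + count) / (1 + n_permutations)

    thin = float(max_lag_km)
    for b in range(n_bins):
        if np.isnan(r_obs[b]):
            continue
        if not (r_obs[b] > 0 and p_val[b] < alpha):
            thin = float(edges[b])
            break
    thin = max(thin, float(fallback_km))
    return Correlogram(edges, r_obs, p_val, thin)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def thin_records(presences: pd.DataFrame, distance_km: float,
                 seed: int = 0) -> pd.DataFrame:
    """Random-order greedy thinning: keep a shuffled record iff no
    already-kept record lies within ``distance_km``.

    The kept set is maximal: every removed record is within distance of
    some kept record.
    """
    if distance_km < 0:
        raise ValueError("distance must be non-negative")
    n = len(presences)
    if n == 0 or distance_km == 0:
        return presences.reset_index(drop=True)
    rng = np.random.default_rng([seed, 12])
    order = rng.permutation(n)
    lon = presences["longitude"].to_numpy()
    lat = presences["latitude"].to_numpy()
    d = pairwise_haversine_km(lon, lat)
    kept: list[int] = []
    for i in order:
        if all(d[i, j] >= distance_km for j in kept):
            kept.append(i)
    kept_sorted = sorted(kept)
    return presences.iloc[kept_sorted].reset_index(drop=True)


def generate_pseudo_absences(species_id: str,
                             stack: EnvironmentalStack,
                             thinned_presences: pd.DataFrame,
                             thinning_distance_km: float,
                             n_clusters: int = 5,
                             buffer_km: float | None = None,
                             seed: int = 0) -> OccurrenceSet:
    """Draw climate-cluster-stratified pseudo-absences in occupied realms.

    Candidate cells lie in realms with at least one presence, outside an
    exclusion buffer of ``buffer_km`` around every presence (default:
    one cell diagonal, i.e. the model's spatial grain — this always
    excludes the presence cells themselves). Candidates are k-means
    clustered on standardized climate predictors and each run samples
    cells without replacement, allocated as evenly as possible across
    clusters (counts differ by at most one, remainder spread
    round-robin, shortfalls of exhausted clusters redistributed).
    """
    n_pres = len(thinned_presences)
    if n_pres < 1:
        raise ValueError(f"{species_id}: no presences")
    grid = stack.grid
    if buffer_km is None:
        buffer_km = grid.cell_size * 111.195 * np.sqrt(2.0)
    realms = np.unique(stack.realm_id[thinned_presences["row"],
                                      thinned_presences["col"]])
    in_realm = np.isin(stack.realm_id, realms)

    lon2d, lat2d = grid.centroids()
    d = pairwise_haversine_km(
        lon2d.ravel(), lat2d.ravel(),
        thinned_presences["longitude"].to_numpy(),
        thinned_presences["latitude"].to_numpy())
    near_presence = (d.min(axis=1) < max(buffer_km, 1e-9)).reshape(grid.shape)
    pres_cells = np.zeros(grid.shape, bool)
    pres_cells[thinned_presences["row"], thinned_presences["col"]] = True
    candidate = in_realm & ~near_presence & ~pres_cells
    cand_idx = np.nonzero(candidate.ravel())[0]

    if n_pres > LARGE_SAMPLE_THRESHOLD:
        n_runs, n_pa = 1, n_pres
    else:
        n_runs, n_pa = N_RUNS_SMALL, max(MIN_PSEUDO_ABSENCES, n_pres)
    if cand_idx.size < n_pa:
        raise RuntimeError(
            f"{species_id}: candidate pool ({cand_idx.size}) smaller than "
            f"required pseudo-absences ({n_pa})")

    k = min(n_clusters, cand_idx.size)
    clim_cols = [i for i, p in enumerate(PREDICTORS) if p in CLIMATE_PREDICTORS]
    clim = stack.predictor_table("present")[cand_idx][:, clim_cols]
    clim = (clim - clim.mean(0)) / np.where(clim.std(0) > 0, clim.std(0), 1.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=_seed32(seed, 13))
    cluster = km.fit_predict(clim)

    rng = np.random.default_rng([seed, 14])
    quotas = _equal_allocation(n_pa, k)
    records = []
    rows2d, cols2d = np.unravel_index(cand_idx, grid.shape)
    for run in range(1, n_runs + 1):
        chosen: list[int] = []
        shortfall = 0
        leftovers: list[int] = []
        for c in range(k):
            pool = np.nonzero(cluster == c)[0]
            take = min(quotas[c], pool.size)
            shortfall += quotas[c] - take
            pick = rng.choice(pool, size=take, replace=False)
            chosen.extend(pick.tolist())
            leftovers.extend(np.setdiff1d(pool, pick).tolist())
        if shortfall:
            extra = rng.choice(np.array(leftovers), size=shortfall, replace=False)
            chosen.extend(extra.tolist())
        for j in chosen:
            records.append((run, int(cluster[j]), int(rows2d[j]), int(cols2d[j])))

    pa = pd.DataFrame(records, columns=["run_id", "cluster_id", "row", "col"])
    pa["longitude"] = lon2d[pa["row"], pa["col"]]
    pa["latitude"] = lat2d[pa["row"], pa["col"]]
    pa["depth"] = stack.bathymetry[pa["row"], pa["col"]]
    pa["species"] = species_id
    return OccurrenceSet(species_id=species_id,
                         presences=thinned_presences.reset_index(drop=True),
                         pseudo_absences=pa,
                         thinning_distance_km=float(thinning_distance_km),
                         n_runs=n_runs, n_pa_per_run=n_pa)


def _equal_allocation(total: int, k: int) -> list[int]:
    """Split ``total`` into k parts differing by at most one (round-robin)."""
    base, rem = divmod(total, k)
    return [base + (1 if c < rem else 0) for c in range(k)]


def _seed32(seed: int, salt: int) -> int:
    return int(np.random.default_rng([seed, salt]).integers(0, 2**31 - 1))
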