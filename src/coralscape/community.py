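"""Community-composition significance testing.

Bray-Curtis dissimilarity, the rank-based ANOSIM statistic with a
permutation null, and a randomized-subsampling ANOSIM ensemble for
datasets too large for a single test: repeated runs each draw a random
subset of cells, test bioregion labels against Bray-Curtis
dissimilarities, and report the mean R and the proportion of
significant runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .bioregions import BioregionModel, CellSpeciesMatrix

log = logging.getLogger(__name__)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two
    non-negative composition vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("entries must be non-negative")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(rows: np.ndarray) -> np.ndarray:
    """Condensed-to-square Bray-Curtis distance matrix over row vectors."""
    return squareform(pdist(np.asarray(rows, float), metric="braycurtis"))


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int
    group_sizes: dict


def anosim(dissimilarity: np.ndarray, labels: np.ndarray,
           n_permutations: int = 199, seed: int = 0) -> AnosimResult:
    """Analysis of similarities (Clarke's R) with a permutation null.

    All off-diagonal dissimilarities are ranked with midranks for ties;
    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2, so R is confined to [-1, 1]. The p-value counts
    random relabelings with R at least as large as observed, with the
    (1 + count)/(1 + n_permutations) small-sample convention.
    """
    d = np.asarray(dissimilarity, float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("dissimilarity must be square")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])        # midranks
    denom = (n * (n - 1) / 2) / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(labels)
    rng = np.random.default_rng([seed, 51])
    count = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(labels)) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return AnosimResult(r=r_obs, p=float(p), n_permutations=n_permutations,
                        group_sizes={g: int(c) for g, c in zip(groups, counts)})


def anosim_exact(dissimilarity: np.ndarray, labels: np.ndarray) -> AnosimResult:
    """ANOSIM with the p-value from full enumeration of label
    assignments (small n only)."""
    from itertools import combinations

    d = np.asarray(dissimilarity, float)
    labels = np.asarray(labels)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    denom = (n * (n - 1) / 2) / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) != 2:
        raise ValueError("exact enumeration supports two groups")
    idx = np.arange(n)
    total = 0
    at_least = 0
    for members in combinations(idx, int(counts[0])):
        lab = np.full(n, groups[1], dtype=labels.dtype)
        lab[list(members)] = groups[0]
        total += 1
        if r_stat(lab) >= r_obs - 1e-12:
            at_least += 1
    return AnosimResult(r=r_obs, p=at_least / total, n_permutations=total,
                        group_sizes={g: int(c) for g, c in zip(groups, counts)})


@dataclass
class AnosimEnsemble:
    runs: list[AnosimResult]
    mean_r: float
    prop_significant: float
    subsample_size: int
    n_runs: int
    seed: int
    n_skipped: int = 0


def subsampled_anosim(matrix: CellSpeciesMatrix, model: BioregionModel,
                      n_runs: int = 100, subsample_size: int = 10_000,
                      n_permutations: int = 199, alpha: float = 0.05,
                      seed: int = 0, max_resamples: int = 100) -> AnosimEnsemble:
    """Randomized-subsampling ANOSIM of bioregion labels.

    Each run draws ``subsample_size`` cells without replacement,
    computes Bray-Curtis dissimilarities between their species-
    probability vectors, and tests the bioregion labels; runs whose
    subsample lacks two groups with two members are redrawn (up to
    ``max_resamples``), and zero-variance subsamples are skipped with a
    warning. Reports the mean R and the proportion of runs with
    p < ``alpha``.
    """
    X = matrix.values
    labels_all = model.assignment
    n = X.shape[0]
    size = min(subsample_size, n)
    rng = np.random.default_rng([seed, 52])
    runs: list[AnosimResult] = []
    skipped = 0
    for run in range(n_runs):
        result = None
        for _ in range(max_resamples):
            pick = rng.choice(n, size=size, replace=False)
            lab = labels_all[pick]
            _, counts = np.unique(lab, return_counts=True)
            if len(counts) < 2 or (counts >= 2).sum() < 2:
                continue
            keep_groups = np.unique(lab)[np.unique(lab, return_counts=True)[1] >= 2]
            keep = np.isin(lab, keep_groups)
            sub = X[pick[keep]]
            if np.allclose(sub, sub[0]):
                log.warning("run %d: identical composition rows, skipped", run)
                result = "skip"
                break
            d = bray_curtis_matrix(sub)
            result = anosim(d, lab[keep], n_permutations=n_permutations,
                            seed=int(rng.integers(0, 2**31 - 1)))
            break
        if result is None:
            raise RuntimeError("could not draw a valid subsample: "
                               "degenerate regionalization")
        if result == "skip":
            skipped += 1
            continue
        runs.append(result)
    if not runs:
        raise RuntimeError("all subsampled runs degenerate")
    mean_r = float(np.mean([r.r for r in runs]))
    prop = float(np.mean([r.p < alpha for r in runs]))
    return AnosimEnsemble(runs=runs, mean_r=mean_r, prop_significant=prop,
                          subsample_size=size, n_runs=len(runs), seed=seed,
                          n_skipped=skipped)
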