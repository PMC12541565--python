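"""Stacked richness and per-cell change statistics.

Binary species ranges are stacked into richness maps (SR); contrasting
present and future stacks yields per-cell gains G, losses L, community
turnover TO = (L + G)/(SR + G), and the refugial fraction
(SR - L)/SR — the proportion of resident species retaining suitable
habitat. Turnover and refugia are undefined (NaN) where no community
exists at either time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ChangeMap:
    sr: np.ndarray          # present richness (int)
    sr_future: np.ndarray
    gains: np.ndarray       # G
    losses: np.ndarray      # L
    turnover: np.ndarray    # (L+G)/(SR+G), NaN where SR+G == 0
    refugia: np.ndarray     # (SR-L)/SR, NaN where SR == 0


def stack_richness(ranges: list[np.ndarray]) -> np.ndarray:
    """Per-cell count of species present (sum of binary maps)."""
    if not ranges:
        raise ValueError("no ranges to stack")
    shape = ranges[0].shape
    out = np.zeros(shape, int)
    for r in ranges:
        r = np.asarray(r, bool)
        if r.shape != shape:
            raise ValueError("range grids do not match")
        out += r
    return out


def change_metrics(present: list[np.ndarray],
                   future: list[np.ndarray]) -> ChangeMap:
    """Per-cell gains, losses, turnover and refugia between two stacks.

    The present and future lists must describe the same species in the
    same order.
    """
    if len(present) != len(future):
        raise ValueError("species lists differ between scenarios")
    sr = stack_richness(present)
    gains = np.zeros_like(sr)
    losses = np.zeros_like(sr)
    for p, f in zip(present, future):
        p = np.asarray(p, bool)
        f = np.asarray(f, bool)
        if p.shape != sr.shape or f.shape != sr.shape:
            raise ValueError("range grids do not match")
        gains += (~p) & f
        losses += p & (~f)
    denom = sr + gains
    with np.errstate(invalid="ignore", divide="ignore"):
        turnover = np.where(denom > 0, (losses + gains) / denom, np.nan)
        refugia = np.where(sr > 0, (sr - losses) / np.where(sr > 0, sr, 1), np.nan)
    return ChangeMap(sr=sr, sr_future=sr + gains - losses, gains=gains,
                     losses=losses, turnover=turnover, refugia=refugia)


@dataclass
class RangeSummary:
    area_km2: float
    mean_depth_m: float     # area-weighted; NaN for empty range
    depth_q05_m: float
    depth_q95_m: float


def range_summary(binary: np.ndarray, bathymetry: np.ndarray,
                  cell_area_km2: np.ndarray) -> RangeSummary:
    """Area and area-weighted depth statistics of one binary range."""
    b = np.asarray(binary, bool)
    if not b.any():
        return RangeSummary(0.0, float("nan"), float("nan"), float("nan"))
    w = cell_area_km2[b].astype(float)
    d = bathymetry[b].astype(float)
    if np.isnan(d).any():
        raise ValueError("bathymetry undefined on presence cells")
    area = float(w.sum())
    mean = float((w * d).sum() / w.sum())
    q05, q95 = weighted_quantile(d, w, [0.05, 0.95])
    return RangeSummary(area_km2=area, mean_depth_m=mean,
                        depth_q05_m=q05, depth_q95_m=q95)


def weighted_quantile(values: np.ndarray, weights: np.ndarray,
                      qs: list[float]) -> list[float]:
    """Area-weighted quantiles (inverse of the weighted empirical CDF)."""
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    cdf = np.cumsum(w) / w.sum()
    return [float(v[np.searchsorted(cdf, q, side="left").clip(0, len(v) - 1)])
            for q in qs]
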