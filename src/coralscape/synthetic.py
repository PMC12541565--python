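"""Synthetic benthic world with known ground truth.

Emulates the inputs of a global cold-water-coral style analysis at desk
scale: spatially autocorrelated gridded predictors over a latitude/depth
temperature gradient, biogeographic realms with distinct thermal
regimes, species with known niche functions (thermal windows, rugosity
affinity, depth ranges, realm membership) grouped into two disjoint
assemblage blocks, spatially biased occurrence sampling, and
warming-offset future scenarios. Because every species' niche is known
exactly, model recovery, range refinement and bioregion delineation can
all be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridSpec, write_ascii_grid, read_ascii_grid

#: canonical predictor order used throughout the package
PREDICTORS = [
    "min_temperature", "max_temperature", "salinity", "oxygen", "ph",
    "productivity", "current_speed", "rugosity", "slope",
]

#: predictors that climate scenarios may shift (terrain is invariant)
CLIMATE_PREDICTORS = ["min_temperature", "max_temperature", "salinity",
                      "oxygen", "ph", "productivity", "current_speed"]

PRESENT = "present"


@dataclass
class WorldSpec:
    """Full specification of a synthetic world; one seed fixes everything."""

    grid_nrows: int = 60
    grid_ncols: int = 60
    cell_size: float = 0.5          # degrees
    lon_min: float = -20.0
    lat_min: float = 10.0
    n_species: int = 40
    n_realms: int = 2
    #: per-scenario additive offsets; keys per scenario:
    #: "temperature" (°C, applied to min and max), optional "oxygen", "ph"
    scenario_deltas: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"ssp1": {"temperature": 1.0},
                                 "ssp3": {"temperature": 3.0}})
    noise_sd: float = 0.1           # sd of independent future-layer noise
    autocorr_range_km: float = 150.0
    lat_gradient: float = 0.1       # °C cooling per degree of latitude
    realm_temp_spacing: float = 8.0  # °C offset between adjacent realms
    #: sharp oceanographic structure: a thermal front inside each realm
    #: (cells equatorward of the front are warmer by front_amp) and a
    #: shelf break (productivity drops by shelf_factor below shelf_depth).
    #: Fronts give species' range edges a sharp physical anchor, as real
    #: shelf breaks and surface fronts do.
    front_amp: float = 5.0
    front_quantile: float = 0.4     # fraction of each realm on the warm side
    shelf_depth_m: float = 800.0
    shelf_factor: float = 0.25
    max_depth_m: float = 3000.0
    #: abyssal trench along realm boundaries: half-width in cells and its
    #: depth. The trench is the physical barrier that keeps realms'
    #: habitat disconnected (0 disables it).
    barrier_halfwidth_cells: int = 2
    barrier_depth_m: float = 6000.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.grid_nrows < 8 or self.grid_ncols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_realms < 1:
            raise ValueError("need at least 1 realm")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_nrows, self.grid_ncols,
                        self.lon_min, self.lat_min, self.cell_size)

    @property
    def scenarios(self) -> list[str]:
        return [PRESENT] + sorted(self.scenario_deltas)


@dataclass
class EnvironmentalStack:
    """Gridded predictors per scenario plus bathymetry and realm labels."""

    grid: GridSpec
    #: scenario -> predictor -> (nrows, ncols) array
    layers: dict[str, dict[str, np.ndarray]]
    bathymetry: np.ndarray          # depth m, positive down
    realm_id: np.ndarray            # int per cell
    #: per-predictor (low, high) normalisation anchors from the present layers
    norm: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def scenarios(self) -> list[str]:
        return list(self.layers)

    def predictor_table(self, scenario: str) -> np.ndarray:
        """(n_cells, n_predictors) matrix in canonical predictor order."""
        sc = self.layers[scenario]
        return np.column_stack([sc[p].ravel() for p in PREDICTORS])

    def cell_area_km2(self) -> np.ndarray:
        return self.grid.cell_area_km2()

    def normalized(self, scenario: str, predictor: str) -> np.ndarray:
        """Layer scaled to [0, 1] with the present-day anchors (clipped)."""
        lo, hi = self.norm[predictor]
        return np.clip((self.layers[scenario][predictor] - lo) / (hi - lo), 0.0, 1.0)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_cells: float) -> np.ndarray:
    """Unit-variance, zero-mean spatially autocorrelated field."""
    white = rng.standard_normal(shape)
    if sigma_cells > 0:
        f = ndimage.gaussian_filter(white, sigma=sigma_cells, mode="reflect")
    else:
        f = white
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def generate_environment(spec: WorldSpec) -> EnvironmentalStack:
    """Build the gridded world for the present and every future scenario.

    Present-day temperature declines with |latitude| and with depth and
    carries a per-realm offset so realms are climatically distinct;
    future layers equal present layers plus the scenario's additive
    deltas plus independent N(0, noise_sd) noise on the shifted layers.
    Terrain (rugosity, slope) is scenario-invariant.
    """
    grid = spec.grid
    rng = np.random.default_rng([spec.seed, 0])
    sigma = spec.autocorr_range_km / (
        grid.cell_size * 111.195 *
        max(np.cos(np.radians(np.abs(grid.lat_centers))).mean(), 0.05)) / 2.0

    lon2d, lat2d = grid.centroids()
    shape = grid.shape

    # bathymetry: shallow "coast" at the west edge deepening offshore, with
    # ridges so depth clipping and depth summaries see structure
    col_frac = (np.arange(grid.ncols) + 0.5) / grid.ncols
    base = spec.max_depth_m * col_frac[None, :] ** 1.1
    ridges = 350.0 * np.sin(3 * np.pi * np.linspace(0, 1, grid.nrows))[:, None] \
        * np.sin(2 * np.pi * col_frac)[None, :]
    bathy = np.clip(base + ridges + 150.0 * _smooth_field(rng, shape, sigma), 0.0, None)

    # realms: Voronoi partition from seed points spread along the coast
    # (rows evenly spaced with jitter, columns in the western third), so
    # every realm is a contiguous band containing shelf habitat
    row_centers = (np.arange(spec.n_realms) + 0.5) / spec.n_realms * grid.nrows
    seeds_rc = np.column_stack([
        row_centers + rng.uniform(-0.1, 0.1, spec.n_realms) * grid.nrows,
        rng.uniform(0, grid.ncols / 3, spec.n_realms)])
    rows, cols = np.meshgrid(np.arange(grid.nrows), np.arange(grid.ncols), indexing="ij")
    d2 = ((rows[..., None] - seeds_rc[:, 0]) ** 2
          + (cols[..., None] - seeds_rc[:, 1]) ** 2)
    realm = np.argmin(d2, axis=-1).astype(int)
    realm_offset = (np.arange(spec.n_realms) - (spec.n_realms - 1) / 2.0) \
        * spec.realm_temp_spacing

    # abyssal trench along realm boundaries: deep, cold, unproductive —
    # the physical barrier that keeps the realms' benthic habitat
    # disconnected (as ocean basins are in reality)
    if spec.n_realms > 1 and spec.barrier_halfwidth_cells > 0:
        size = 2 * spec.barrier_halfwidth_cells + 1
        boundary = (ndimage.maximum_filter(realm, size=size)
                    != ndimage.minimum_filter(realm, size=size))
        bathy = np.where(boundary, np.maximum(bathy, spec.barrier_depth_m),
                         bathy)

    depth_frac = bathy / spec.max_depth_m
    max_t = (26.0 - spec.lat_gradient * (np.abs(lat2d) - 10.0)
             - 5.0 * depth_frac
             + realm_offset[realm] + 0.5 * _smooth_field(rng, shape, sigma))
    # thermal front inside each realm: the warm (equatorward) fraction of
    # the realm sits front_amp above the rest, a sharp step as at real
    # surface fronts
    if spec.front_amp > 0:
        for r in range(spec.n_realms):
            mask = realm == r
            if not mask.any():
                continue
            front_lat = np.quantile(lat2d[mask], spec.front_quantile)
            max_t = np.where(mask & (lat2d < front_lat),
                             max_t + spec.front_amp, max_t)
    spread = 3.0 + 1.2 * np.abs(_smooth_field(rng, shape, sigma)) + 0.5
    min_t = max_t - spread

    salinity = 34.5 + 0.4 * _smooth_field(rng, shape, sigma)
    oxygen = np.clip(230.0 - 40.0 * depth_frac + 25.0 * _smooth_field(rng, shape, sigma),
                     1.0, None)
    ph = 8.05 - 0.12 * depth_frac + 0.05 * _smooth_field(rng, shape, sigma)
    # shelf-break step: productivity reaching the sea floor drops sharply
    # below the shelf depth
    productivity = np.clip(
        8.0 * np.exp(-bathy / 2500.0)
        * np.where(bathy <= spec.shelf_depth_m, 1.0, spec.shelf_factor)
        * (1.0 + 0.25 * _smooth_field(rng, shape, sigma)),
        0.01, None)
    current = np.clip(0.15 + 0.08 * np.abs(_smooth_field(rng, shape, sigma)), 0.0, None)

    # terrain from bathymetry: rugosity = local roughness, slope = |gradient|;
    # normalized by an upper quantile (not the max) so extreme barrier
    # walls do not flatten the terrain signal everywhere else
    local_mean = ndimage.uniform_filter(bathy, size=3, mode="reflect")
    local_sq = ndimage.uniform_filter(bathy ** 2, size=3, mode="reflect")
    rugosity = np.sqrt(np.clip(local_sq - local_mean ** 2, 0.0, None))
    rugosity = np.clip(rugosity / max(np.quantile(rugosity, 0.90), 1e-9), 0.0, 1.0)
    gy, gx = np.gradient(bathy)
    slope = np.hypot(gy, gx)
    slope = np.clip(slope / max(np.quantile(slope, 0.90), 1e-9), 0.0, 1.0)

    present = {
        "min_temperature": min_t, "max_temperature": max_t, "salinity": salinity,
        "oxygen": oxygen, "ph": ph, "productivity": productivity,
        "current_speed": current, "rugosity": rugosity, "slope": slope,
    }

    layers: dict[str, dict[str, np.ndarray]] = {PRESENT: present}
    for name in sorted(spec.scenario_deltas):
        deltas = spec.scenario_deltas[name]
        sc = {k: v.copy() for k, v in present.items()}
        rng_s = np.random.default_rng([spec.seed, 1, _stable_int(name)])
        dt = float(deltas.get("temperature", 0.0))
        for key, delta in [("max_temperature", dt), ("min_temperature", dt),
                           ("oxygen", float(deltas.get("oxygen", 0.0))),
                           ("ph", float(deltas.get("ph", 0.0)))]:
            if key in ("max_temperature", "min_temperature") and dt == 0.0 \
                    and spec.noise_sd == 0.0:
                continue
            if key in ("oxygen", "ph") and delta == 0.0 and key not in deltas:
                continue
            noise = rng_s.normal(0.0, spec.noise_sd, sc[key].shape) \
                if spec.noise_sd > 0 else 0.0
            sc[key] = sc[key] + delta + noise
        sc["min_temperature"] = np.minimum(sc["min_temperature"], sc["max_temperature"])
        layers[name] = sc

    norm = {p: (float(present[p].min()), float(max(present[p].max(),
                                                   present[p].min() + 1e-9)))
            for p in PREDICTORS}
    return EnvironmentalStack(grid=grid, layers=layers, bathymetry=bathy,
                              realm_id=realm, norm=norm)


def _stable_int(name: str) -> int:
    """Deterministic small int from a string (independent of PYTHONHASHSEED)."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return h


# ---------------------------------------------------------------------------
# species truths


@dataclass
class SpeciesTruth:
    """Known niche of one synthetic species.

    The environmental suitability is a product of a decreasing plateaued
    ramp in maximum temperature (half-height exactly at ``thermal_upper``),
    an increasing ramp in minimum temperature, a saturating increasing
    term in rugosity, and small increasing effects of the remaining
    predictors — matching the monotone directions the distribution
    models are constrained to.
    """

    species_id: str
    genus_id: str
    realm_set: frozenset[int]
    thermal_lower: float            # °C, on min_temperature
    thermal_upper: float            # °C, on max_temperature
    ramp_width: float               # °C, half-width of the thermal ramps
    rugosity_affinity: float        # in (0, 1): weight of the rugosity term
    depth_min: float                # m
    depth_max: float                # m
    strong_signal: bool             # upper thermal ramp well inside realm support
    block: int                      # planted assemblage block (0 or 1)
    productivity_cut: float = 0.0   # normalized productivity needed (0 = none)
    productivity_width: float = 0.05

    def env_suitability(self, stack: EnvironmentalStack,
                        scenario: str = PRESENT) -> np.ndarray:
        """Suitability in [0, 1] from predictors alone (no realm mask)."""
        sc = stack.layers[scenario]
        w = self.ramp_width
        # product of monotone terms raised to the 4th power: the power
        # keeps every monotone direction but pushes marginal habitat
        # toward zero, so the realised niche is a plateau with steep
        # shoulders — communities are near-binary in space, which is what
        # makes the planted assemblages separable downstream
        s = _ramp_down(sc["max_temperature"], self.thermal_upper, w)
        s = s * _ramp_up(sc["min_temperature"], self.thermal_lower, w)
        if self.productivity_cut > 0:
            s = s * _ramp_up(stack.normalized(scenario, "productivity"),
                             self.productivity_cut, self.productivity_width)
        rug = stack.normalized(scenario, "rugosity")
        s = s * (1.0 - self.rugosity_affinity + self.rugosity_affinity
                 * np.clip(rug / 0.6, 0.0, 1.0))
        for p in ("salinity", "oxygen", "ph", "current_speed", "slope"):
            s = s * (0.995 + 0.005 * stack.normalized(scenario, p))
        return np.clip(s, 0.0, 1.0) ** 4

    def suitability(self, stack: EnvironmentalStack,
                    scenario: str = PRESENT) -> np.ndarray:
        """Realised suitability: environmental suitability inside the
        species' realms, zero outside."""
        mask = np.isin(stack.realm_id, list(self.realm_set))
        return np.where(mask, self.env_suitability(stack, scenario), 0.0)


def _ramp_down(x: np.ndarray, center: float, width: float) -> np.ndarray:
    """1 below center-width, 0 above center+width, linear between;
    value at ``center`` is exactly 0.5."""
    return np.clip((center + width - x) / (2.0 * width), 0.0, 1.0)


def _ramp_up(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.clip((x - (center - width)) / (2.0 * width), 0.0, 1.0)


def generate_species(spec: WorldSpec, stack: EnvironmentalStack,
                     min_occupancy: float = 0.01,
                     max_occupancy: float = 0.12,
                     max_retries: int = 40) -> list[SpeciesTruth]:
    """Draw species niches occupying between ``min_occupancy`` and
    ``max_occupancy`` of the grid at suitability >= 0.5, split into two
    disjoint realm blocks.

    Members of a block share all their limiting edges, with only small
    jitter: a common upper thermal limit near the realm's warm end, a
    cold limit below the realm's temperature range (so it excludes the
    other, colder realm but nothing within the home realm), and a
    common productivity requirement that carves the occupied band. The
    planted assemblages are therefore cohesive communities — block
    members co-occur almost everywhere — which is what makes the
    two-block structure recoverable from co-occurrence patterns
    downstream. Keeping occupancy bounded above matters as much as
    below: with overly broad niches most of a realm is suitable and
    randomly placed pseudo-absences become false absences, destroying
    the separability any model could achieve. The productivity cut is
    adjusted (and if necessary the thermal limit relaxed) up to
    ``max_retries`` times per species to land inside the band.
    """
    rng = np.random.default_rng([spec.seed, 2])
    n_half = (spec.n_realms + 1) // 2
    blocks = [frozenset(range(n_half)),
              frozenset(range(n_half, spec.n_realms)) or frozenset(range(n_half))]
    max_t = stack.layers[PRESENT]["max_temperature"]
    min_t = stack.layers[PRESENT]["min_temperature"]
    prod_norm_full = np.clip(
        (stack.layers[PRESENT]["productivity"] - stack.norm["productivity"][0])
        / (stack.norm["productivity"][1] - stack.norm["productivity"][0]),
        0.0, 1.0)
    n_cells = stack.grid.n_cells

    lon2d, lat2d = stack.grid.centroids()
    on_shelf = stack.bathymetry <= spec.shelf_depth_m

    truths: list[SpeciesTruth] = []
    for i in range(spec.n_species):
        block = 0 if i < spec.n_species / 2 else 1
        realm_set = blocks[block]
        in_realm = np.isin(stack.realm_id, list(realm_set))
        # habitable (non-trench) realm cells for quantile anchors
        habitable = in_realm & (stack.bathymetry <= spec.max_depth_m * 1.2)
        if not habitable.any():
            habitable = in_realm
        width = 0.5

        # niche edges anchored at the realm's sharp physical features:
        # the upper thermal limit sits inside the thermal front's gap and
        # the productivity requirement inside the shelf break's gap, so
        # the whole block shares identical, cleanly learnable range edges
        front_lat = np.quantile(lat2d[in_realm], spec.front_quantile) \
            if spec.front_amp > 0 else -np.inf
        warm = habitable & (lat2d < front_lat)
        cold = habitable & (lat2d >= front_lat)
        if spec.front_amp > 0 and (cold & on_shelf).any():
            # just above the warmest occupied habitat: the warm edge of a
            # range is only identifiable up to the front's temperature
            # gap, so the planted limit sits where the data place it
            t_upper = float(np.quantile(max_t[cold & on_shelf], 0.99)) + 0.4
        else:
            t_upper = float(np.quantile(max_t[habitable], 0.85))
        t_lower = float(np.quantile(min_t[habitable], 0.02)) - 1.5
        if (habitable & on_shelf).any() and (habitable & ~on_shelf).any():
            p_cut = 0.5 * (
                float(np.quantile(prod_norm_full[habitable & on_shelf], 0.05))
                + float(np.quantile(prod_norm_full[habitable & ~on_shelf], 0.95)))
        else:
            p_cut = float(np.quantile(prod_norm_full[habitable], 0.6))
        rug_aff = float(rng.uniform(0.02, 0.05))
        truth = None
        fallback = None
        for attempt in range(max_retries):
            cand = SpeciesTruth(
                species_id=f"sp{i:03d}", genus_id=f"gen{i // 4:02d}",
                realm_set=realm_set, thermal_lower=t_lower,
                thermal_upper=t_upper,
                ramp_width=width, rugosity_affinity=rug_aff,
                depth_min=0.0, depth_max=0.0, strong_signal=False, block=block,
                productivity_cut=max(p_cut, 1e-3), productivity_width=0.03)
            suit = cand.suitability(stack)
            frac = (suit >= 0.5).sum() / n_cells
            if min_occupancy <= frac <= max_occupancy:
                truth = cand
                break
            fallback = fallback or cand
            if frac < min_occupancy:     # free habitat: relax the cuts
                p_cut = max(p_cut - 0.02, 1e-3)
                t_upper += 0.2
            else:                        # tighten the productivity cut
                p_cut = min(p_cut + 0.02, 0.97)
        truth = truth or fallback
        if truth is None:
            raise RuntimeError(f"species {i}: no feasible niche "
                               f"after {max_retries} retries")
        occ = truth.suitability(stack) >= 0.5
        depths = stack.bathymetry[occ]
        truth.depth_min = max(0.0, float(np.quantile(depths, 0.02)) - 100.0)
        truth.depth_max = float(np.quantile(depths, 0.98)) + 300.0
        # the decreasing ramp is learnable only if both its shoulders have
        # support inside the realm
        mx = max_t[habitable]
        above = (mx > truth.thermal_upper).mean()
        below = (mx < truth.thermal_upper - truth.ramp_width).mean()
        truth.strong_signal = bool(above >= 0.08 and below >= 0.08)
        truths.append(truth)
    return truths


def sample_occurrences(truth: SpeciesTruth, stack: EnvironmentalStack,
                       n: int, bias_strength: float = 0.5,
                       seed: int = 0) -> pd.DataFrame:
    """Sample presence records proportional to suitability times a smooth
    spatial sampling-bias field.

    Records are confined to the species' realms and true depth range and
    carry centroid coordinates jittered inside their cell. Returns a
    DataFrame with columns species, genus, longitude, latitude, depth,
    row, col.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([seed, 3])
    suit = truth.suitability(stack)
    ok = (suit > 0) & (stack.bathymetry >= truth.depth_min) \
        & (stack.bathymetry <= truth.depth_max)
    if not ok.any():
        raise RuntimeError(f"{truth.species_id}: no suitable cells to sample")
    weights = np.where(ok, suit, 0.0)
    if bias_strength != 0.0:
        bias = _smooth_field(rng, stack.grid.shape, sigma_cells=3.0)
        weights = weights * np.exp(bias_strength * bias)
    p = weights.ravel() / weights.sum()
    idx = rng.choice(stack.grid.n_cells, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(idx, stack.grid.shape)
    lon2d, lat2d = stack.grid.centroids()
    jit = rng.uniform(-0.45, 0.45, size=(2, n)) * stack.grid.cell_size
    return pd.DataFrame({
        "species": truth.species_id,
        "genus": truth.genus_id,
        "longitude": lon2d[rows, cols] + jit[0],
        "latitude": lat2d[rows, cols] + jit[1],
        "depth": stack.bathymetry[rows, cols],
        "row": rows, "col": cols,
    })


# ---------------------------------------------------------------------------
# disk round-trip in adapter-readable formats


def write_world(outdir: str | Path, stack: EnvironmentalStack,
                truths: list[SpeciesTruth] | None = None,
                occurrences: pd.DataFrame | None = None) -> None:
    """Write rasters (.asc), occurrences CSV and depth-range CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for scen, layers in stack.layers.items():
        for pred, arr in layers.items():
            write_ascii_grid(outdir / f"{scen}__{pred}.asc", stack.grid, arr)
    write_ascii_grid(outdir / "bathymetry.asc", stack.grid, stack.bathymetry)
    write_ascii_grid(outdir / "realms.asc", stack.grid, stack.realm_id, fmt="%d")
    if occurrences is not None:
        occurrences.to_csv(outdir / "occurrences.csv", index=False)
    if truths is not None:
        pd.DataFrame([{
            "species": t.species_id, "genus": t.genus_id,
            "depth_min_m": t.depth_min, "depth_max_m": t.depth_max,
            "source": "species",
        } for t in truths]).to_csv(outdir / "depth_ranges.csv", index=False)
        pd.DataFrame([{
            "species": t.species_id, "genus": t.genus_id,
            "thermal_lower": t.thermal_lower, "thermal_upper": t.thermal_upper,
            "ramp_width": t.ramp_width, "rugosity_affinity": t.rugosity_affinity,
            "depth_min_m": t.depth_min, "depth_max_m": t.depth_max,
            "realm_set": ";".join(map(str, sorted(t.realm_set))),
            "strong_signal": t.strong_signal, "block": t.block,
        } for t in truths]).to_csv(outdir / "species_truth.csv", index=False)


def read_environment(indir: str | Path) -> EnvironmentalStack:
    """Read a stack previously written by :func:`write_world` (or any
    directory following the same ``scenario__predictor.asc`` layout)."""
    indir = Path(indir)
    grid = None
    layers: dict[str, dict[str, np.ndarray]] = {}
    for f in sorted(indir.glob("*__*.asc")):
        scen, pred = f.stem.split("__", 1)
        g, arr = read_ascii_grid(f)
        grid = grid or g
        layers.setdefault(scen, {})[pred] = arr
    if grid is None:
        raise FileNotFoundError(f"no predictor rasters under {indir}")
    _, bathy = read_ascii_grid(indir / "bathymetry.asc")
    _, realm = read_ascii_grid(indir / "realms.asc")
    present = layers[PRESENT]
    norm = {p: (float(present[p].min()), float(max(present[p].max(),
                                                   present[p].min() + 1e-9)))
            for p in PREDICTORS}
    return EnvironmentalStack(grid=grid, layers=layers, bathymetry=bathy,
                              realm_id=realm.astype(int), norm=norm)
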