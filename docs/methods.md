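# Methods

`coralscape` implements an end-to-end stacked species distribution
modelling (SDM) study for benthic taxa — from occurrence records and
gridded environmental predictors to ensemble habitat-suitability maps,
biologically constrained binary ranges, richness/turnover/refugia
projections under warming scenarios, statistically validated
bioregions, and community-significance testing. Because the global
datasets such an analysis consumes are large and external, the package
ships a fully specified synthetic world with known ground truth; every
stage is validated by recovering what was planted.

## The synthetic world

A regular lon/lat grid (default 60x60 cells of 0.5 deg spanning
10-40 N) carries nine benthic predictors: minimum and maximum
temperature, salinity, dissolved oxygen, pH, primary productivity,
current speed, and two terrain variables (rugosity, slope) derived from
a bathymetry that deepens from a western "coast" toward an offshore
basin with ridges. Temperature declines with latitude and depth and is
perturbed by a spatially autocorrelated field (Gaussian-smoothed white
noise, correlation length `autocorr_range_km`, default 150 km).

Three sharp physical structures organise the world, mirroring the role
that basins, fronts and shelf breaks play in real ocean biogeography:

- **Realms.** The grid is split into biogeographic realms (default 2)
  — contiguous north/south coastal bands (Voronoi regions seeded along
  the coast) with a strong additive temperature offset (spacing
  8 degC) and an **abyssal trench** (depth 6000 m, ~5 cells wide)
  along their boundary. The offset makes realms climatically distinct;
  the trench is the physical barrier that keeps their habitat
  disconnected, so dispersal clipping confines ranges to their realm.
- **Thermal fronts.** Inside each realm the equatorward 40% of cells
  sits a sharp 5 degC above the rest. Species' upper thermal limits
  lie inside the front's temperature gap, so the warm edge of every
  range coincides with a physical discontinuity: wherever a fitted
  model places its cut inside the gap, it classifies exactly the same
  cells.
- **Shelf break.** Sea-floor productivity drops by a factor 4 below
  800 m. Species' productivity requirements sit inside that gap, so
  the deep edge of every range anchors on the shelf break the same
  way.

Future scenarios (default `ssp1`: +1 degC, `ssp3`: +3 degC) equal the
present layers plus additive deltas plus independent N(0, `noise_sd`)
noise; terrain is scenario-invariant, and zero deltas with zero noise
reproduce the present exactly (the identity scenario used for
validation).

Each species' environmental suitability is a product of monotone
terms raised to the 4th power, so the realised niche is a plateau with
steep shoulders: a decreasing ramp in maximum temperature (half-height
exactly at the species' upper thermal limit), an increasing ramp in
minimum temperature (its cold limit sits below the home realm's range,
so it excludes only the colder realm), an increasing ramp in
productivity at the shelf-break gap, a weakly increasing saturating
rugosity response, and very small increasing effects of the remaining
predictors. These directions match the constraints imposed on the
models, so constraint-respecting learners can recover the truth.

Species split into two assemblage blocks confined to disjoint realms,
and members of a block share their niche edges: the planted
assemblages are cohesive communities (near-uniform richness inside
their territory), not mere label sets. This matters for recovery:
independently drawn narrow niches make composition turn over within a
realm as strongly as between realms, and smooth (front-free) climate
leaves every species with a wide fringe of partial membership —
either way, Euclidean k-means over probability vectors then finds
richness strata rather than the planted assemblages. An occupancy
controller bounds each species' suitable area (suitability >= 0.5) to
1-12% of the grid: the lower bound keeps species modellable, the
upper bound keeps randomly placed pseudo-absences from landing on
suitable habitat, which would destroy the separability any model
could achieve. Occurrences are sampled with probability proportional
to suitability times a smooth sampling-bias field
(`exp(bias_strength * field)`), confined to the species' realms and
true depth range, with coordinates jittered inside the cell.

What the generator does **not** emulate: water-mass dynamics,
mechanistic larval transport, depth-stratified sampling artifacts,
taxonomic error, ecologically individualistic species (block members
are deliberately near-equivalent), or the heavy-tailed prevalence
distribution of real occurrence datasets. Passing recovery tests here
demonstrates the pipeline's correctness and its ability to recover
planted signal at realistic sample sizes — not field performance on
any particular real dataset.

## Occurrence preparation

Thinning distance is species-specific: a Mantel-style correlogram
correlates predictor similarity (negative standardized Euclidean
distance between standardized predictor vectors) with lag membership
over point pairs, tested one-sided by 199 seeded permutations of record
identity; the thinning distance is the lower edge of the first lag
whose correlation is not significantly positive (alpha = 0.05), floored
at one cell diagonal and capped at the largest examined lag
(`max_lag_km`, default 120 km over 4 bins). The cap matters: this
world's deterministic gradients keep similarity elevated at every
distance (a correlogram over a smooth gradient never dies), so the cap
is the effective thinning distance, chosen at roughly twice the
nominal autocorrelation range. Records are then thinned by seeded
random-order greedy elimination, which yields a maximal set with no
pair closer than the distance. Species with fewer than 10 presences
skip the correlogram and use the one-cell-diagonal fallback.

Pseudo-absences are drawn from cells in the realms the species
occupies, outside an exclusion buffer around every presence. The buffer
defaults to one cell diagonal — the model's spatial grain — rather
than the thinning distance: a thinned presence set is a maximal packing
of suitable habitat, so thinning-distance disks around it blanket the
realm and empty the candidate pool. Run structure follows sample size:
species with more than 1000 presences (strictly) get one run balanced
1:1; all others get 10 runs of max(100, n_presences) pseudo-absences.
Candidates are k-means clustered (default k=5) on standardized climate
predictors and each run samples cells without replacement, allocated
evenly across clusters (counts differ by at most one; shortfalls of
exhausted clusters are redistributed). Cluster ids are recorded per
record so the clusters can also be used as covariates if desired.

## Ensemble models

Three boosted learners are fitted per species:

| slot | implementation | grid axes |
|---|---|---|
| `brt` | LightGBM | learning rate, tree complexity (max depth), number of trees |
| `xgb_like` | XGBoost | gamma, interaction depth, shrinkage, rounds |
| `adaboost_like` | sklearn HistGradientBoosting, depth-1 stumps | iterations, degrees of freedom, shrinkage |

All three enforce hard monotone constraints: non-increasing in maximum
temperature, non-decreasing in every other predictor. The
`adaboost_like` slot is a boosted additive model (stumps have no
interactions); its "degrees of freedom" axis maps to L2 regularization
(`l2 = 1/df`) since stumps expose no smoothness knob. `grid_mode=
"full"` exposes the complete grids (about 7,000 BRT combinations);
the default `grid_mode="coarse"` subsamples each axis to at most two
values, which is where a desk-scale study should run.

Cross-validation uses 10 spatial-block folds: the grid is tiled with
equal-area hexagons (cylindrical equal-area projection; diameter =
the species' thinning distance, floored at 150 km) and whole blocks are
dealt to folds balancing record counts. Grid search maximizes mean
held-out AUC; the winner is re-evaluated fold by fold for AUC,
sensitivity (at the minimum-training-presence threshold learned on the
training folds) and the continuous Boyce index, and additionally on the
pooled out-of-fold predictions — the pooled metrics are the robust
summary when single folds hold few presences, and are what the
acceptance checks use. The Boyce index slides 101 windows of width
0.1x the suitability range and Spearman-correlates window midpoint with
the presence/background frequency ratio.

Hyperparameters are searched once per algorithm on the first
pseudo-absence run; the winning combination is then refitted on every
run, giving one ensemble member per (algorithm x run) — integrating
across algorithms and pseudo-absence realizations without multiplying
the search cost by the run count (runs share presences, so re-searching
per run adds cost but no information). Member weight is
max(0, AUC - 0.5) of its algorithm's cross-validation mean,
renormalized; members no better than random contribute nothing, and if
every weight vanishes an unweighted mean is used with a warning.
Collinearity (VIF = 1/(1-R^2)) is reported per species but collinear
predictors are retained. Predictor contributions are permutation
importances (drop in AUC over 10 seeded shuffles, clipped at zero,
normalized to 100%, weight-averaged over members); partial-dependence
curves fix one predictor on a 50-point grid and average predictions
over the fitting data. Final-model metrics are resubstitution values
on the fitting data and are optimistic by construction; the
cross-validation metrics are the honest ones.

## Range refinement

Three ordered steps, each only removing cells:

1. **Thresholding.** The minimum-training-presence threshold is the
   largest suitability t with >= 95% of training presences at or above
   t — the lower-tie-inclusive 5th-percentile order statistic — so the
   sensitivity guarantee holds exactly.
2. **Dispersal clipping.** Habitat patches (connected components,
   queen adjacency by default) are kept if they contain an occurrence
   record, or lie within 200 km (minimum centroid-to-centroid distance)
   of a patch that does. Future maps are clipped against the
   present-day occupied patches: larvae cannot cross unsuitable
   habitat, so no gains appear beyond 200 km of currently reachable
   range. Patch connectivity and the distance convention (centroids,
   not edges) are configurable and documented because the choice
   changes what "within 200 km" means at cell resolution.
3. **Depth clipping.** Presence is removed where bathymetry falls
   outside the species' known depth range; species without their own
   range use genus-level means across congeners.

## Stacking and change metrics

Binary ranges are summed into per-cell richness SR. Against a future
scenario, per-cell gains G and losses L give turnover
TO = (L+G)/(SR+G) and the refugial fraction (SR-L)/SR. Both are
undefined (NaN, not 0) where no community exists at either time —
global means stay interpretable and blank map areas stay blank. Depth
and area summaries weight cells by their cos(latitude) area so
poleward cells do not bias the statistics.

## Bioregionalization

Each cell with at least one species present (after refinement) is a
vector of ensemble occurrence probabilities, masked to each species'
refined range: suitability in unreachable habitat is not part of a
species' predicted distribution, and leaving it in blurs every
compositional boundary (an unmasked matrix cannot distinguish a realm
boundary from a within-realm gradient). k-means (Lloyd, n_init=10,
seeded) runs for k = 2..30 on raw probabilities (no standardization —
columns share the [0,1] scale). BCSS/WCSS rises monotonically with k,
so the cluster count needs a better-behaved criterion: the default
selection maximises the mean silhouette width (computed on a seeded
subsample above 4000 cells) — the standard model-free selector, and
one that is insensitive to the low-mass fringe clusters (partial-
membership cells at range edges) that dominate the curvature of the
exploding ratio curve. `selection="ratio_max"` gives the literal
argmax of the ratio, `selection="elbow"` its maximal negative
curvature (with BCSS(1) = 0 prepended); the selection curve — ratio
and silhouette per k — is always written out so the choice is
auditable. Final centroids are related by a Ward.D2 dendrogram (scipy's
`linkage(..., "ward")` on centroid coordinates, which implements the
Ward.D2 criterion on Euclidean distances), exported as Newick. Regions
are summarised by richness (species with >= 1 presence cell in the
region), endemics (species whose whole range sits in one region),
area-weighted depth statistics, and region-level change (losses/gains
of the region's species set, same turnover form as per-cell).

## Community significance

ANOSIM on Bray-Curtis dissimilarities between cell probability
vectors: all off-diagonal dissimilarities are ranked with midranks,
R = (mean between-group rank - mean within-group rank)/(M/2),
M = n(n-1)/2; the permutation p-value uses the
(1+count)/(1+n_permutations) convention so p is never 0, with 199
permutations by default (matching 0.01-granularity reporting). Because
a full-dataset ANOSIM is quadratic in cells, the ensemble version runs
repeated seeded subsamples (100 runs x 10,000 cells at full scale;
20 x 500 in the desk configuration) and reports the mean R and the
proportion of significant runs. Degenerate subsamples (fewer than two
groups with two members) are redrawn; zero-variance subsamples are
skipped with a warning.

## Pipeline, seeds, determinism

Ten stages (simulate, thin, pseudoabs, fit, predict, refine, stack,
change, bioregions, anosim) run inside one output directory. Each
stage writes its outputs plus a marker recording a dependency hash
(configuration + checksums of the upstream stage's files); a rerun
recomputes a stage only if the marker is missing or dependencies
changed, so deleting one stage's outputs rebuilds only that stage (and
anything whose inputs actually changed). A single master seed fans out
to per-stage, per-species 31-bit child seeds by SHA-256 hashing of
`(master, stage, unit)`; two runs with the same master seed produce
byte-identical stage checksums. Rasters are ESRI ASCII grids (plain
text) with NaN as nodata — blank "no species" areas are nodata, not 0.

## Problem sizes and defaults

The desk configuration (`desk_config`) is the study the tests and the
acceptance script run: a 60x60-cell world, 40 species in two
20-member blocks, 500 raw occurrences per species (thinning to ~40
presences at the 120-km cap), coarse grids, k searched over 2..30,
ANOSIM as 20 runs x 500 cells x 199 permutations. A full run takes
about 7-8 minutes on one CPU. The full-scale parameters (complete
grids, 100 x 10,000 ANOSIM) remain available in `RunConfig` for
larger worlds.

## Known limitations

- The correlogram's stopping rule degenerates to the examined-lag cap
  whenever predictors carry global gradients; the cap is therefore a
  real parameter, not a technicality.
- Final-model metrics are resubstitution values (no held-back final
  evaluation set) and should not be quoted as skill.
- Euclidean k-means on probability vectors is magnitude-sensitive:
  richness gradients compete with compositional boundaries, which is
  why range masking matters (and why very unequal block richness can
  still split a realm before merging two realms).
- Patch distances use cell centroids; at coarse grids the effective
  dispersal reach is up to one cell diagonal smaller than nominal.
- ANOSIM R under heterogeneous within-group dispersion can be inflated;
  the ensemble reports dispersion of R across runs, not a correction.
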