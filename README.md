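# coralscape

Stacked species distribution modelling (SDM) for benthic biodiversity
under climate-change scenarios: from occurrence records and gridded
environmental predictors to ensemble habitat-suitability maps,
dispersal- and depth-constrained binary ranges, richness / turnover /
climate-refugia projections, statistically validated bioregions, and
community-significance tests.

The pipeline mirrors the workflow used in global deep-sea (e.g.,
cold-water coral) biodiversity assessments:

- **Occurrence preparation** — correlogram-based spatial thinning at a
  species-specific distance; realm-restricted pseudo-absences,
  stratified over k-means climate clusters, with 10 runs of >= 100
  pseudo-absences for data-poor species and a single 1:1 balanced run
  for species with more than 1000 presences.
- **Ensemble SDMs** — three boosted learners (LightGBM, XGBoost, and a
  boosted additive stump learner) with *hard monotonicity constraints*
  (suitability non-increasing in maximum temperature, non-decreasing in
  every other predictor), grid-searched under 10-fold spatial-block
  cross-validation on equal-area hexagons, evaluated with AUC,
  sensitivity and the continuous Boyce index, and combined by
  AUC-based weights.
- **Range refinement** — minimum-training-presence thresholding with a
  >= 0.95 sensitivity guarantee; removal of habitat patches farther
  than 200 km from any patch holding occurrences (future maps clipped
  against present-day occupied patches); clipping to known depth ranges
  with genus-level fallback.
- **Biodiversity change** — stacked richness SR; per-cell gains G and
  losses L; turnover TO = (L+G)/(SR+G); refugial fraction (SR-L)/SR.
- **Bioregionalization** — k-means over per-cell species-probability
  vectors (masked to refined ranges) for k = 2..30, selected from the
  BCSS/WCSS separation curve; Ward.D2 dendrogram of the centroids;
  per-region richness, endemicity, depth and projected change.
- **Community significance** — ANOSIM (Clarke's R, midranks,
  permutation p) on Bray-Curtis dissimilarities, run as a randomized
  subsampling ensemble reporting mean R and the proportion of
  significant runs.

Because the real inputs of such a study (global occurrence databases,
environmental layer stacks, bathymetry) are external and large, the
package ships a **synthetic world generator** with full ground truth:
autocorrelated predictors over latitude/depth gradients, biogeographic
realms separated by an abyssal trench, species with known thermal
niches arranged in two cohesive assemblage blocks, biased occurrence
sampling, and warming-offset future scenarios. Every stage is
validated by recovering what was planted. See `docs/methods.md` for the
model details and design choices.

## Worked example

Run the default desk-scale study (60x60-cell world, 40 species in two
planted assemblage blocks, two warming scenarios), either step by step
via the analysis scripts or in one shot:

```bash
python analysis/01_simulate_world.py      # -> results/run/simulate/
python analysis/02_prepare_occurrences.py
python analysis/03_fit_ensembles.py
python analysis/04_refine_ranges.py
python analysis/05_biodiversity_change.py
python analysis/06_bioregions.py
python analysis/07_community_significance.py
# or equivalently:
coralscape run --out results/run --seed 7
```

Stages cache their outputs, so each script reuses everything already
computed. With seed 7 the fitting step prints:

```
cross-validation means by algorithm:
               oof_auc  oof_boyce  oof_sensitivity
algorithm
adaboost_like    0.943      0.271            0.734
brt              0.945      0.454            0.769
xgb_like         0.926      0.664            0.858

per-species held-out AUC: median 0.939 (IQR 0.928-0.949)
final-model (resubstitution) AUC mean 0.979, sensitivity mean 0.956
```

meaning the spatial-block held-out discrimination of the ensemble
members is high for essentially every species, and the presence-only
calibration (Boyce) is well above random. The change step summarises
the warming scenarios:

```
present richness: max 20 species/cell; occupied cells 645 of 3600
total suitable area: 1,748,151 km2
ssp1: mean turnover 0.595, mean refugia 41.4%, gains 123, losses 5088
ssp3: mean turnover 0.994, mean refugia 0.6%, gains 2, losses 9883
```

— mild warming erodes the warm range edges (41% of resident species
persist per cell on average), while strong warming pushes nearly every
cell past the planted thermal limits. The bioregion step prints:

```
selected k = 2 (max mean silhouette width)
adjusted Rand vs planted realm partition: 1.000
```

the clustering put every occupied cell into the bioregion matching the
realm block it was planted in, and the community test confirms the
split:

```
20 ANOSIM runs of 500 cells each:
mean R = 0.989; 100% of runs significant (p < 0.05)
```

(Exact numbers vary with the seed; these are the values the code
prints for seed 7.)

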