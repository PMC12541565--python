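"""Estimate species-specific thinning distances from predictor
correlograms, thin the occurrence records, and draw realm-restricted,
climate-cluster-stratified pseudo-absences.

Prints per-species sample sizes and the run structure implied by the
1000-presence rule.
"""

import sys

import pandas as pd

from coralscape.pipeline import desk_config, run_pipeline

OUT = "results/run"


def main(seed: int = 7) -> None:
    cfg = desk_config(OUT, seed=seed)
    run_pipeline(cfg, through="pseudoabs")
    thinned = pd.read_csv(f"{OUT}/thin/thinned_occurrences.csv")
    pa = pd.read_csv(f"{OUT}/pseudoabs/pseudo_absences.csv")
    counts = thinned.groupby("species").size()
    dists = thinned.groupby("species")["thinning_distance_km"].first()
    print(f"thinned presences per species: min {counts.min()}, "
          f"median {int(counts.median())}, max {counts.max()}")
    print(f"thinning distances (km): {sorted(float(d) for d in dists.unique())}")
    runs = pa.groupby("species")["run_id"].max()
    print(f"pseudo-absence runs per species: {runs.unique().tolist()} "
          f"(all species below the 1000-presence threshold)" if
          (runs == 10).all() else f"run structure: {runs.to_dict()}")
    print(f"pseudo-absences per run: "
          f"{pa.groupby(['species', 'run_id']).size().median():.0f} (median)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
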