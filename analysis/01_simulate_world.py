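"""Simulate the synthetic benthic world: gridded predictors for the
present and two warming scenarios, bathymetry, two biogeographic
realms, 40 species with known niches, and biased occurrence records.

Writes rasters and CSVs under results/run/simulate/ and prints a short
summary of what was planted.
"""

import sys

import numpy as np
import pandas as pd

from coralscape.pipeline import desk_config, run_pipeline

OUT = "results/run"


def main(seed: int = 7) -> None:
    cfg = desk_config(OUT, seed=seed)
    run_pipeline(cfg, through="simulate")
    truth = pd.read_csv(f"{OUT}/simulate/species_truth.csv")
    occ = pd.read_csv(f"{OUT}/simulate/occurrences.csv")
    print(f"world: {cfg.world.grid_nrows}x{cfg.world.grid_ncols} cells, "
          f"{cfg.world.n_realms} realms, scenarios {cfg.world.scenarios}")
    print(f"species: {len(truth)} in blocks "
          f"{truth.groupby('block').size().to_dict()}")
    print(f"upper thermal limits: {truth.thermal_upper.min():.1f} to "
          f"{truth.thermal_upper.max():.1f} degC")
    print(f"occurrences: {len(occ)} records, "
          f"median depth {occ.depth.median():.0f} m")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
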