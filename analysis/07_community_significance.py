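"""Test whether species composition differs among the bioregions:
repeated subsampled ANOSIM runs on Bray-Curtis dissimilarities between
cell probability vectors.

Prints the mean R statistic and the proportion of significant runs.
"""

import json
import sys

import pandas as pd

from coralscape.pipeline import desk_config, run_pipeline

OUT = "results/run"


def main(seed: int = 7) -> None:
    cfg = desk_config(OUT, seed=seed)
    run_pipeline(cfg, through="anosim")
    runs = pd.read_csv(f"{OUT}/anosim/anosim_runs.csv")
    summary = json.loads(open(f"{OUT}/anosim/anosim_summary.json").read())
    print(f"{summary['n_runs']} ANOSIM runs of {summary['subsample_size']} "
          f"cells each:")
    print(f"mean R = {summary['mean_r']:.3f}; "
          f"{100 * summary['prop_significant']:.0f}% of runs significant "
          f"(p < 0.05)")
    print(f"R range: {runs.r.min():.3f} to {runs.r.max():.3f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
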