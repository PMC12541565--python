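import warnings

import numpy as np
import pytest

from coralscape.pipeline import desk_config, run_pipeline
from coralscape.synthetic import (WorldSpec, generate_environment,
                                  generate_species)

warnings.filterwarnings("ignore", message="X does not have valid feature names")


@pytest.fixture(scope="session")
def small_spec() -> WorldSpec:
    return WorldSpec(grid_nrows=24, grid_ncols=24, n_species=4, seed=11)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return generate_environment(small_spec)


@pytest.fixture(scope="session")
def small_truths(small_spec, small_stack):
    return generate_species(small_spec, small_stack)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The default synthetic study (60x60 grid, 40 species in two
    assemblage blocks, seed 7, coarse grids), run once per session."""
    out = tmp_path_factory.mktemp("default_world")
    cfg = desk_config(out, seed=7)
    manifest = run_pipeline(cfg)
    return cfg, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
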