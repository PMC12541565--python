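"""Thinning-distance estimation, record thinning and pseudo-absence
design rules."""

import numpy as np
import pandas as pd
import pytest

from coralscape.grids import GridSpec
from coralscape.occurrences import (Correlogram, estimate_thinning_distance,
                                    generate_pseudo_absences, thin_records,
                                    _equal_allocation)
from coralscape.spatial import pairwise_haversine_km
from coralscape.synthetic import (PRESENT, PREDICTORS, EnvironmentalStack,
                                  WorldSpec, generate_environment)


def _presences_on(stack, cells, species="spX"):
    lon2d, lat2d = stack.grid.centroids()
    rows = np.array([r for r, _ in cells])
    cols = np.array([c for _, c in cells])
    return pd.DataFrame({
        "species": species, "genus": "genX",
        "longitude": lon2d[rows, cols], "latitude": lat2d[rows, cols],
        "depth": stack.bathymetry[rows, cols], "row": rows, "col": cols})


def _white_noise_stack(seed=0, n=20):
    """Stack whose predictors carry no spatial structure at all."""
    spec = WorldSpec(grid_nrows=n, grid_ncols=n, n_species=2, seed=seed,
                     autocorr_range_km=0.0)
    stack = generate_environment(spec)
    rng = np.random.default_rng(seed)
    for pred in PREDICTORS:
        stack.layers[PRESENT][pred] = rng.standard_normal((n, n))
    return stack


class TestThinningDistance:
    def test_white_predictors_give_first_lag(self, rng):
        stack = _white_noise_stack()
        cells = [(int(r), int(c)) for r, c in
                 zip(rng.integers(0, 20, 60), rng.integers(0, 20, 60))]
        pres = _presences_on(stack, cells)
        cg = estimate_thinning_distance(pres, stack, max_lag_km=400, n_bins=8,
                                        seed=1)
        # no autocorrelation to detect: the stopping rule fires at the first
        # lag (lower edge 0), floored at the one-cell-diagonal minimum
        assert not cg.fallback
        assert cg.thinning_distance_km == pytest.approx(
            stack.grid.cell_size * 111.195 * np.sqrt(2), rel=0.01)

    def test_smooth_gradient_caps_at_max_lag(self, rng):
        spec = WorldSpec(grid_nrows=20, grid_ncols=20, n_species=2, seed=1)
        stack = generate_environment(spec)
        lon2d, _ = stack.grid.centroids()
        for pred in PREDICTORS:   # one global smooth gradient, no noise
            stack.layers[PRESENT][pred] = lon2d * 1.0
        cells = [(int(r), int(c)) for r, c in
                 zip(rng.integers(0, 20, 50), rng.integers(0, 20, 50))]
        cg = estimate_thinning_distance(_presences_on(stack, cells), stack,
                                        max_lag_km=500, n_bins=10, seed=2)
        # similarity stays significantly elevated through (almost) every lag;
        # the final sparse lag can lack permutation power, so the selected
        # distance is at or just below the cap
        assert cg.thinning_distance_km >= 0.8 * 500.0
        assert (cg.p[:8] < 0.05).all()

    def test_few_presences_fall_back(self, small_stack):
        pres = _presences_on(small_stack, [(1, 1), (2, 2), (3, 3)])
        cg = estimate_thinning_distance(pres, small_stack, seed=3)
        assert cg.fallback
        assert cg.thinning_distance_km == pytest.approx(
            small_stack.grid.cell_size * 111.195 * np.sqrt(2))


class TestThinning:
    def test_distance_zero_keeps_everything(self, small_stack):
        pres = _presences_on(small_stack, [(0, 0), (0, 1), (5, 5)])
        assert len(thin_records(pres, 0.0, seed=1)) == 3

    def test_two_close_records_leave_one(self, small_stack):
        pres = _presences_on(small_stack, [(5, 5), (5, 6)])  # ~ 50 km apart
        assert len(thin_records(pres, 100.0, seed=1)) == 1

    def test_pairwise_guarantee_and_maximality(self, small_stack, rng):
        cells = list({(int(r), int(c)) for r, c in
                      zip(rng.integers(0, 24, 80), rng.integers(0, 24, 80))})
        pres = _presences_on(small_stack, cells)
        dist = 150.0
        kept = thin_records(pres, dist, seed=5)
        d = pairwise_haversine_km(kept["longitude"], kept["latitude"])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= dist
        # maximality: every removed record is within dist of a kept one
        removed = pres[~pres.index.isin(
            pres.reset_index().merge(kept, on=["row", "col"])["index"])]
        if len(removed):
            dd = pairwise_haversine_km(removed["longitude"], removed["latitude"],
                                       kept["longitude"], kept["latitude"])
            assert (dd.min(axis=1) < dist).all()


@pytest.fixture(scope="module")
def big_stack():
    spec = WorldSpec(grid_nrows=80, grid_ncols=80, n_species=2,
                     n_realms=1, seed=13)
    return generate_environment(spec)


class TestPseudoAbsences:
    def _pres(self, stack, n):
        cells = [(r, c) for r in range(0, 80, 2) for c in range(0, 80, 2)][:n]
        return _presences_on(stack, cells)

    @pytest.mark.parametrize("n,expected_runs,expected_pa", [
        (999, 10, 999), (1000, 10, 1000), (1001, 1, 1001)])
    def test_run_structure_around_1000(self, big_stack, n, expected_runs,
                                       expected_pa):
        occ = generate_pseudo_absences("spX", big_stack, self._pres(big_stack, n),
                                       thinning_distance_km=10.0,
                                       buffer_km=10.0, seed=1)
        assert occ.n_runs == expected_runs
        counts = occ.pseudo_absences.groupby("run_id").size()
        assert len(counts) == expected_runs
        assert (counts == expected_pa).all()

    def test_small_sample_gets_ten_runs_of_100(self, big_stack):
        occ = generate_pseudo_absences("spX", big_stack, self._pres(big_stack, 30),
                                       thinning_distance_km=10.0,
                                       buffer_km=10.0, seed=2)
        assert occ.n_runs == 10
        assert (occ.pseudo_absences.groupby("run_id").size() == 100).all()

    def test_cluster_stratification_even(self, big_stack):
        occ = generate_pseudo_absences("spX", big_stack, self._pres(big_stack, 30),
                                       thinning_distance_km=10.0,
                                       n_clusters=4, buffer_km=10.0, seed=3)
        run1 = occ.pseudo_absences[occ.pseudo_absences.run_id == 1]
        per = run1.groupby("cluster_id").size()
        assert per.sum() == 100
        assert per.max() - per.min() <= 1
        assert (per == 25).all()   # 100 over 4 clusters exactly

    def test_no_overlap_with_presences_and_realm_restriction(self, small_stack,
                                                             small_truths):
        from coralscape.synthetic import sample_occurrences
        t = small_truths[0]
        pres = sample_occurrences(t, small_stack, 40, seed=6) \
            .drop_duplicates(["row", "col"]).reset_index(drop=True)
        occ = generate_pseudo_absences(t.species_id, small_stack, pres,
                                       thinning_distance_km=80.0, seed=7)
        pa = occ.pseudo_absences
        pres_cells = set(zip(pres["row"], pres["col"]))
        pa_cells = set(zip(pa["row"], pa["col"]))
        assert pres_cells.isdisjoint(pa_cells)
        realms = set(np.unique(small_stack.realm_id[pres["row"], pres["col"]]))
        assert set(np.unique(small_stack.realm_id[pa["row"], pa["col"]])) <= realms


def test_equal_allocation_arithmetic():
    assert _equal_allocation(100, 4) == [25, 25, 25, 25]
    assert _equal_allocation(10, 3) == [4, 3, 3]
    assert sum(_equal_allocation(999, 7)) == 999
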