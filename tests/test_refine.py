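"""Binary-range refinement: MTP thresholding order statistics, the
dispersal rule, depth clipping with genus fallback, and the
only-ever-remove property of the full chain."""

import numpy as np
import pandas as pd
import pytest

from coralscape.grids import GridSpec
from coralscape.refine import (BinaryRange, DepthRange, depth_clip,
                               dispersal_clip, mtp_threshold, refine_range,
                               resolve_depth_range)
from coralscape.spatial import label_patches


class TestMtpThreshold:
    def test_twenty_evenly_spaced_presences(self):
        s = np.arange(0.05, 1.001, 0.05)   # 0.05, 0.10, ..., 1.00
        thr, sens = mtp_threshold(s)
        assert thr == pytest.approx(0.10)
        assert sens == pytest.approx(0.95)

    def test_single_presence(self):
        thr, sens = mtp_threshold(np.array([0.7]))
        assert thr == 0.7 and sens == 1.0

    def test_threshold_bounded_by_max_and_sensitivity_guaranteed(self, rng):
        for _ in range(20):
            s = rng.random(rng.integers(1, 60))
            thr, sens = mtp_threshold(s)
            assert thr <= s.max()
            assert sens >= 0.95
            assert (s >= thr).mean() == sens

    def test_nan_suitability_rejected(self):
        with pytest.raises(ValueError, match="records"):
            mtp_threshold(np.array([0.5, np.nan, 0.7]))


def _two_patch_world(gap_cols: int, cell_size=0.5):
    """Binary map with an occupied west patch and an unoccupied east patch
    separated by ``gap_cols`` empty columns (~55 km each at the equator)."""
    ncols = 4 + gap_cols + 4
    grid = GridSpec(6, ncols, 0.0, -1.5, cell_size)
    binary = np.zeros((6, ncols), bool)
    binary[2:4, 0:4] = True
    binary[2:4, 4 + gap_cols:] = True
    occ = np.zeros_like(binary)
    occ[2, 1] = True
    return grid, binary, occ


class TestDispersalClip:
    def test_single_occupied_patch_unchanged(self):
        grid, binary, occ = _two_patch_world(0)
        clipped, _, _ = dispersal_clip(binary, occ, grid)
        assert np.array_equal(clipped, binary)

    def test_patch_within_200km_retained_beyond_removed(self):
        # centroid-to-centroid gaps: 2 empty columns -> ~167 km (retained);
        # 4 empty columns -> ~278 km (removed)
        grid, binary, occ = _two_patch_world(2)
        clipped, _, _ = dispersal_clip(binary, occ, grid, 200.0)
        assert clipped[2, -1]
        grid, binary, occ = _two_patch_world(4)
        clipped, _, _ = dispersal_clip(binary, occ, grid, 200.0)
        assert not clipped[2, -1]
        assert clipped[2, 1]    # occupied patch always kept

    def test_idempotent_and_never_drops_occupied(self, rng):
        grid = GridSpec(12, 12, 0.0, 0.0, 0.5)
        for _ in range(10):
            binary = rng.random((12, 12)) < 0.3
            occ = binary & (rng.random((12, 12)) < 0.3)
            once, lab, _ = dispersal_clip(binary, occ, grid)
            twice, _, _ = dispersal_clip(once, occ, grid)
            assert np.array_equal(once, twice)
            occupied_ids = set(np.unique(lab.patch_id[occ & binary])) - {0}
            for p in occupied_ids:
                r, c = lab.cells_of(int(p))
                assert once[r, c].all()

    def test_every_kept_patch_occupied_or_reachable(self, rng):
        from coralscape.spatial import min_distance_to_cells
        grid = GridSpec(15, 15, 0.0, 0.0, 0.5)
        binary = rng.random((15, 15)) < 0.25
        occ = binary & (rng.random((15, 15)) < 0.2)
        clipped, _, _ = dispersal_clip(binary, occ, grid, 120.0)
        lab = label_patches(clipped, "queen")
        occupied_mask = np.zeros_like(binary)
        full_lab = label_patches(binary, "queen")
        occ_ids = set(np.unique(full_lab.patch_id[occ & binary])) - {0}
        occupied_mask = np.isin(full_lab.patch_id, sorted(occ_ids))
        for p in range(1, lab.n_patches + 1):
            r, c = lab.cells_of(p)
            if not occ[r, c].any():
                assert min_distance_to_cells(lab, p, occupied_mask, grid) <= 120.0


class TestDepthClip:
    def test_full_range_unchanged_and_out_of_range_removed(self):
        binary = np.ones((3, 3), bool)
        bathy = np.array([[100, 500, 900], [1500, 200, 700], [50, 2500, 400]],
                         float)
        dr = DepthRange("sp", 0.0, 5000.0)
        assert np.array_equal(depth_clip(binary, dr, bathy), binary)
        dr2 = DepthRange("sp", 200.0, 1000.0)
        out = depth_clip(binary, dr2, bathy)
        assert not out[1, 0] and not out[2, 1] and not out[2, 0]
        assert out[0, 1] and out[1, 1]

    def test_genus_fallback_mean_of_congeners(self):
        table = pd.DataFrame({
            "species": ["a", "b", "c"], "genus": ["G", "G", "G"],
            "depth_min_m": [100.0, 200.0, 300.0],
            "depth_max_m": [1000.0, 1200.0, 800.0]})
        dr = resolve_depth_range("zz", "G", table)
        assert dr.source == "genus"
        assert dr.depth_min == pytest.approx(200.0)
        assert dr.depth_max == pytest.approx(1000.0)

    def test_missing_species_and_genus_raises(self):
        table = pd.DataFrame({"species": ["a"], "genus": ["G"],
                              "depth_min_m": [0.0], "depth_max_m": [100.0]})
        with pytest.raises(KeyError, match="zz"):
            resolve_depth_range("zz", "H", table)


class TestFullRefinement:
    def test_each_step_only_removes(self, rng):
        grid = GridSpec(12, 12, 0.0, 0.0, 0.5)
        suit = rng.random((12, 12))
        pres_cells = suit > 0.6
        pres_suit = suit[pres_cells]
        bathy = rng.uniform(0, 2000, (12, 12))
        dr = DepthRange("sp", 100.0, 1500.0)
        out = refine_range("sp", {"present": suit, "future": suit * 0.9},
                           pres_cells, pres_suit, dr, bathy, grid)
        assert isinstance(out, BinaryRange)
        for scen in ("present", "future"):
            thresholded = suit * (1.0 if scen == "present" else 0.9) \
                >= out.threshold
            assert not (out.presence[scen] & ~thresholded).any()
        assert out.sensitivity_at_threshold >= 0.95
        assert out.steps_applied == ["mtp_threshold", "dispersal_clip",
                                     "depth_clip"]

    def test_deterministic(self, rng):
        grid = GridSpec(10, 10, 0.0, 0.0, 0.5)
        suit = rng.random((10, 10))
        pres = suit > 0.5
        bathy = np.full((10, 10), 500.0)
        dr = DepthRange("sp", 0.0, 1000.0)
        a = refine_range("sp", {"present": suit}, pres, suit[pres], dr,
                         bathy, grid)
        b = refine_range("sp", {"present": suit}, pres, suit[pres], dr,
                         bathy, grid)
        assert np.array_equal(a.presence["present"], b.presence["present"])
        assert a.threshold == b.threshold
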