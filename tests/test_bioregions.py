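"""Bioregionalization: matrix assembly, k-means identities, planted-blob
recovery, Ward.D2 dendrogram against a brute-force Lance-Williams
oracle, and per-region summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from coralscape.bioregions import (BioregionModel, build_matrix,
                                   centroid_dendrogram, fit_bioregions,
                                   linkage_to_newick, summarize_bioregions)


def _ward_d2_oracle(points):
    """Brute-force agglomerative Ward.D2: greedy merges minimizing the
    Lance-Williams-updated distance, starting from Euclidean distances."""
    n = len(points)
    active = {i: [i] for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(np.linalg.norm(points[i] - points[j]))
    sizes = {i: 1 for i in range(n)}
    merges = []
    nxt = n
    while len(active) > 1:
        (a, b), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((a, b, h, sizes[a] + sizes[b]))
        new = nxt
        nxt += 1
        sizes[new] = sizes[a] + sizes[b]
        del active[a], active[b]
        dab = h
        newd = {}
        for k in active:
            dak = d[(min(a, k), max(a, k))]
            dbk = d[(min(b, k), max(b, k))]
            na, nb, nk = sizes[a], sizes[b], sizes[k]
            # Ward.D2 Lance-Williams update
            newd[(min(k, new), max(k, new))] = float(np.sqrt(
                ((na + nk) * dak ** 2 + (nb + nk) * dbk ** 2 - nk * dab ** 2)
                / (na + nb + nk)))
        d = {key: v for key, v in d.items()
             if a not in key and b not in key}
        d.update(newd)
        active[new] = True
    return merges


class TestBuildMatrix:
    def test_drops_all_zero_rows(self):
        p = {"a": np.array([[0.2, 0.0], [0.5, 0.0]]),
             "b": np.array([[0.1, 0.0], [0.0, 0.3]])}
        m = build_matrix(p)
        assert m.values.shape == (3, 2)                 # 4 cells, 1 all-zero
        assert m.cell_index.tolist() == [0, 2, 3]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            build_matrix({"a": np.array([[1.2]])})

    def test_deterministic_row_order(self, rng):
        p = {"a": rng.random((5, 5)), "b": rng.random((5, 5))}
        m1, m2 = build_matrix(p), build_matrix(p)
        assert np.array_equal(m1.values, m2.values)
        assert np.array_equal(m1.cell_index, m2.cell_index)


class TestFitBioregions:
    def _blob_matrix(self, rng, n=120, sep=4.0):
        a = rng.normal(0, 0.05, (n // 2, 6)) + 0.1
        b = rng.normal(0, 0.05, (n // 2, 6)) + 0.1
        b[:, :3] += sep * 0.1
        X = np.clip(np.vstack([a, b]), 0, 1)
        p = {f"s{j}": X[:, j].reshape(-1, 1) for j in range(6)}
        return build_matrix(p), np.repeat([0, 1], n // 2)

    def test_two_planted_blobs_recovered_exactly(self, rng):
        matrix, truth = self._blob_matrix(rng)
        model = fit_bioregions(matrix, k_range=range(2, 6), seed=1)
        assert model.k == 2
        same = (model.assignment == model.assignment[0])
        assert np.array_equal(same, truth == truth[0]) \
            or np.array_equal(same, truth != truth[0])

    def test_tss_identity_every_k(self, rng):
        X = rng.random((60, 5))
        matrix = build_matrix({f"s{j}": X[:, j].reshape(-1, 1)
                               for j in range(5)})
        for k in range(2, 8):
            m = fit_bioregions(matrix, k_range=range(k, k + 1), seed=2,
                               selection="ratio_max")
            assert m.bcss + m.wcss == pytest.approx(m.tss, rel=1e-6)

    def test_nearest_centroid_assignment_with_low_index_ties(self, rng):
        matrix, _ = self._blob_matrix(rng)
        model = fit_bioregions(matrix, k_range=range(2, 5), seed=3)
        d2 = ((matrix.values[:, None, :] - model.centroids[None]) ** 2).sum(-1)
        assert np.array_equal(model.assignment, np.argmin(d2, axis=1))

    def test_duplicate_rows_share_cluster(self, rng):
        X = np.vstack([np.full((10, 4), 0.3), np.full((10, 4), 0.8)])
        matrix = build_matrix({f"s{j}": X[:, j].reshape(-1, 1)
                               for j in range(4)})
        model = fit_bioregions(matrix, k_range=range(2, 3), seed=4)
        assert len(set(model.assignment[:10])) == 1
        assert len(set(model.assignment[10:])) == 1


class TestDendrogram:
    def test_two_singletons_merge_at_euclidean_distance(self):
        model = BioregionModel(
            k=2, assignment=np.array([0, 1]),
            centroids=np.array([[0.0, 0.0], [3.0, 4.0]]),
            wcss=0, bcss=0, tss=0, selection_curve=pd.DataFrame(),
            dendrogram=None, cell_index=np.arange(2), grid_shape=(1, 2))
        Z = centroid_dendrogram(model)
        assert Z[0, 2] == pytest.approx(5.0)

    def test_heights_monotone_and_matches_scipy(self, rng):
        pts = rng.random((5, 4))
        Z = linkage(pts, method="ward")
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_matches_brute_force_ward_oracle(self, k, rng):
        pts = rng.random((k, 6))
        Z = linkage(pts, method="ward")
        oracle = _ward_d2_oracle(pts)
        ours_heights = sorted(Z[:, 2])
        oracle_heights = sorted(h for _, _, h, _ in oracle)
        assert ours_heights == pytest.approx(oracle_heights, rel=1e-9)

    def test_newick_serialization_parses(self):
        pts = np.array([[0.0, 0], [1.0, 0], [0.5, 2.0]])
        Z = linkage(pts, method="ward")
        nwk = linkage_to_newick(Z, ["r1", "r2", "r3"])
        assert nwk.endswith(";") and nwk.count("(") == 2
        import dendropy
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 3


class TestSummaries:
    def _model_and_ranges(self):
        # 1x4 grid, two regions of two cells each
        assignment = np.array([0, 0, 1, 1])
        model = BioregionModel(
            k=2, assignment=assignment, centroids=np.zeros((2, 3)),
            wcss=0, bcss=0, tss=0, selection_curve=pd.DataFrame(),
            dendrogram=None, cell_index=np.arange(4), grid_shape=(1, 4),
            species_ids=["a", "b", "c"])
        mk = lambda cells: np.array([[c in cells for c in range(4)]])
        ranges = {
            "present": {"a": mk({0, 1}), "b": mk({0, 2}), "c": mk({3})},
            "warm": {"a": mk({0, 1}), "b": mk({2}), "c": mk(set())},
        }
        return model, ranges

    def test_richness_endemicity_and_region_change(self):
        model, ranges = self._model_and_ranges()
        bathy = np.array([[100.0, 200.0, 300.0, 400.0]])
        area = np.ones((1, 4))
        s = summarize_bioregions(model, ranges, bathy, area)
        r1, r2 = s
        assert r1.sr == 2 and r2.sr == 2      # region1: a,b; region2: b,c
        assert r1.endemics == 1               # a only in region 1
        assert r2.endemics == 1               # c only in region 2
        # region 1 loses b under "warm": L=1,G=0 -> TO = 1/2
        assert r1.change["warm"]["turnover"] == pytest.approx(0.5)
        assert r1.change["warm"]["delta_sr"] == -1
        # region 2 loses c: TO = 1/2
        assert r2.change["warm"]["turnover"] == pytest.approx(0.5)

    def test_unchanged_scenario_zero_region_turnover(self):
        model, ranges = self._model_and_ranges()
        ranges["same"] = {k: v.copy() for k, v in ranges["present"].items()}
        del ranges["warm"]
        s = summarize_bioregions(model, ranges, np.ones((1, 4)), np.ones((1, 4)))
        for region in s:
            assert region.change["same"]["turnover"] == 0.0
            assert region.change["same"]["delta_sr"] == 0
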