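"""Model fitting machinery: VIF against a least-squares oracle, spatial
folds, grid search, monotone constraints, Boyce index behaviour and
ensemble weighting."""

import numpy as np
import pandas as pd
import pytest

from coralscape.ensemble import (COARSE_GRIDS, FULL_GRIDS, ALGORITHMS,
                                 FoldAssignment, LearnerSpec,
                                 assign_spatial_folds, boyce_index,
                                 compute_vif, ensemble_predict,
                                 grid_search_fit, make_estimator,
                                 partial_dependence, predictor_contribution)
from coralscape.grids import GridSpec
from coralscape.spatial import hex_blocks
from coralscape.synthetic import PREDICTORS


class TestVif:
    def test_orthogonal_predictors_give_one(self):
        n = 64
        X = np.zeros((n, 3))
        # exactly orthogonal, zero-mean columns
        X[:, 0] = np.tile([1, -1], n // 2)
        X[:, 1] = np.tile([1, 1, -1, -1], n // 4)
        X[:, 2] = np.tile([1, 1, 1, 1, -1, -1, -1, -1], n // 8)
        rep = compute_vif(X)
        for v in rep.vif.values():
            assert v == pytest.approx(1.0, abs=1e-6)
        assert rep.flagged == []

    def test_duplicated_predictor_flagged(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, x, rng.standard_normal(50)])
        rep = compute_vif(X, names=["a", "b", "c"])
        assert "a" in rep.flagged and "b" in rep.flagged

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((80, 3))
        X[:, 2] += 0.7 * X[:, 0]
        rep = compute_vif(X)
        for j, name in enumerate(rep.vif):
            others = np.column_stack([np.ones(80), np.delete(X, j, axis=1)])
            # explicit normal equations
            beta = np.linalg.solve(others.T @ others, others.T @ X[:, j])
            resid = X[:, j] - others @ beta
            r2 = 1 - resid @ resid / ((X[:, j] - X[:, j].mean()) ** 2).sum()
            assert rep.vif[name] == pytest.approx(1 / (1 - r2), rel=1e-9)

    def test_constant_predictor_infinite(self, rng):
        X = np.column_stack([np.ones(30), rng.standard_normal(30)])
        rep = compute_vif(X, names=["const", "x"])
        assert np.isinf(rep.vif["const"])
        assert "const" in rep.flagged


class TestSpatialFolds:
    grid = GridSpec(30, 30, 0.0, 0.0, 0.5)

    def test_blocks_never_split_and_partition(self, rng):
        blocking = hex_blocks(self.grid, 200.0)
        rows = rng.integers(0, 30, 300)
        cols = rng.integers(0, 30, 300)
        fa = assign_spatial_folds(rows, cols, blocking, n_folds=10, seed=1)
        df = pd.DataFrame({"block": fa.block_id, "fold": fa.fold_id})
        assert (df.groupby("block")["fold"].nunique() == 1).all()
        assert set(np.unique(fa.fold_id)) <= set(range(1, fa.n_folds + 1))
        assert len(fa.fold_id) == 300

    def test_balance_within_factor_two(self, rng):
        blocking = hex_blocks(self.grid, 150.0)
        rows = rng.integers(0, 30, 500)
        cols = rng.integers(0, 30, 500)
        fa = assign_spatial_folds(rows, cols, blocking, n_folds=5, seed=2)
        sizes = np.bincount(fa.fold_id)[1:]
        assert sizes.max() <= 2 * sizes.min()


def _planted_data(rng, n=240):
    """Binary response driven by a decreasing ramp in max_temperature."""
    X = rng.standard_normal((n, len(PREDICTORS)))
    j = PREDICTORS.index("max_temperature")
    logit = -2.5 * X[:, j] + 0.8 * X[:, PREDICTORS.index("rugosity")]
    p = 1 / (1 + np.exp(-logit))
    y = (rng.random(n) < p).astype(int)
    return X, y


class TestGridSearch:
    def test_single_combination_grid_returned(self, rng):
        X, y = _planted_data(rng)
        grid = {"gamma": [0], "interaction_depth": [2], "shrinkage": [0.3],
                "n_rounds": [50]}
        spec = LearnerSpec("xgb_like", grid)
        folds = FoldAssignment(fold_id=rng.integers(1, 6, len(y)),
                               block_id=np.zeros(len(y)), n_folds=5)
        res = grid_search_fit(X, y, folds, spec, seed=0)
        assert res.converged
        assert res.best_params == {"gamma": 0, "interaction_depth": 2,
                                   "shrinkage": 0.3, "n_rounds": 50}

    def test_planted_signal_recovered(self, rng):
        X, y = _planted_data(rng, n=400)
        folds = FoldAssignment(fold_id=rng.integers(1, 6, len(y)),
                               block_id=np.zeros(len(y)), n_folds=5)
        spec = LearnerSpec("brt", COARSE_GRIDS["brt"])
        res = grid_search_fit(X, y, folds, spec, seed=1)
        assert res.mean_auc > 0.8

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_monotone_constraint_enforced(self, algo, rng):
        """Predictions never increase as max_temperature rises, and never
        decrease as rugosity rises, with everything else held fixed."""
        X, y = _planted_data(rng, n=300)
        params = {k: v[0] for k, v in COARSE_GRIDS[algo].items()}
        est = make_estimator(algo, params, seed=0)
        est.fit(X, y)
        probe = np.tile(np.median(X, axis=0), (60, 1))
        jt = PREDICTORS.index("max_temperature")
        probe[:, jt] = np.linspace(X[:, jt].min(), X[:, jt].max(), 60)
        p = est.predict_proba(probe)[:, 1]
        assert (np.diff(p) <= 1e-9).all()
        probe = np.tile(np.median(X, axis=0), (60, 1))
        jr = PREDICTORS.index("rugosity")
        probe[:, jr] = np.linspace(X[:, jr].min(), X[:, jr].max(), 60)
        p = est.predict_proba(probe)[:, 1]
        assert (np.diff(p) >= -1e-9).all()


class TestFullGrids:
    def test_grid_axes_and_sizes(self):
        g = FULL_GRIDS["brt"]
        assert len(g["learning_rate"]) == 91      # 0.01..0.1 step 0.001
        assert g["tree_complexity"] == [1, 2, 3, 4]
        assert g["n_trees"][0] == 50 and g["n_trees"][-1] == 1000
        a = FULL_GRIDS["adaboost_like"]
        assert a["n_iterations"] == [50, 100, 150, 200, 250]
        assert a["degrees_of_freedom"] == list(range(1, 13))
        assert a["shrinkage"] == [0.25, 0.5, 0.75, 1.0]
        x = FULL_GRIDS["xgb_like"]
        assert x["gamma"] == [0, 1, 2, 3, 4, 5]
        assert x["shrinkage"] == [0.1, 0.2, 0.3, 0.4, 0.5]
        assert x["n_rounds"] == list(range(10, 101, 10))

    def test_coarse_grids_subsample_full_axes(self):
        for algo, grid in COARSE_GRIDS.items():
            for axis, values in grid.items():
                assert len(values) <= 4
                assert set(values) <= set(FULL_GRIDS[algo][axis])


class TestBoyce:
    def test_well_calibrated_predictions_score_high(self, rng):
        suit = rng.random(4000)
        pres = suit[rng.random(4000) < suit][:600]
        assert boyce_index(pres, suit) > 0.9

    def test_anticalibrated_predictions_negative(self, rng):
        back = rng.random(2000)
        pres = rng.uniform(0, 0.05, 100)   # presences in the worst cells
        assert boyce_index(pres, back) < 0

    def test_permuted_predictions_near_zero(self):
        vals = []
        for s in range(20):
            r = np.random.default_rng(s)
            back = r.random(2000)
            pres = r.choice(back, 200)     # presences random wrt suitability
            vals.append(boyce_index(pres, back))
        assert np.nanmax(np.abs(vals)) < 0.3 or abs(np.nanmean(vals)) < 0.15

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(boyce_index(np.full(20, 0.5), np.full(100, 0.5)))


class TestEnsemble:
    def test_identical_members_idempotent(self, rng):
        p = rng.random(100)
        ens = ensemble_predict([p, p, p], [0.9, 0.8, 0.7])
        assert np.allclose(ens.probability, p)

    def test_auc_weights_two_to_one(self, rng):
        a, b = rng.random(50), rng.random(50)
        ens = ensemble_predict([a, b], [0.9, 0.7])
        assert ens.weights == pytest.approx([2 / 3, 1 / 3])
        assert np.allclose(ens.probability, (2 * a + b) / 3)

    def test_convexity_bounds(self, rng):
        members = [rng.random(200) for _ in range(4)]
        ens = ensemble_predict(members, [0.9, 0.85, 0.6, 0.75])
        lo = np.min(members, axis=0)
        hi = np.max(members, axis=0)
        assert (ens.probability >= lo - 1e-12).all()
        assert (ens.probability <= hi + 1e-12).all()

    def test_all_random_members_fall_back_to_equal(self, rng):
        with pytest.warns(UserWarning):
            ens = ensemble_predict([rng.random(10), rng.random(10)], [0.4, 0.5])
        assert ens.weights == pytest.approx([0.5, 0.5])


class TestContributions:
    def test_sum_to_100_and_signal_dominates_noise(self, rng):
        X, y = _planted_data(rng, n=400)
        est = make_estimator("xgb_like",
                             {k: v[0] for k, v in COARSE_GRIDS["xgb_like"].items()},
                             seed=0)
        est.fit(X, y)
        contrib = predictor_contribution([est], np.array([1.0]), X, y, seed=0)
        assert contrib.sum() == pytest.approx(100.0, abs=1e-6)
        assert contrib["max_temperature"] > contrib["salinity"]

    def test_partial_dependence_monotone_in_max_temperature(self, rng):
        X, y = _planted_data(rng, n=300)
        est = make_estimator("brt",
                             {k: v[0] for k, v in COARSE_GRIDS["brt"].items()},
                             seed=0)
        est.fit(X, y)
        _, curve = partial_dependence([est], np.array([1.0]), X,
                                      "max_temperature")
        assert (np.diff(curve) <= 1e-9).all()
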