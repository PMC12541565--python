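"""Monotone-constrained boosted species distribution models.

Three boosted learners are grid-searched per species under 10-fold
spatial-block cross-validation, evaluated with AUC, sensitivity (at the
minimum-training-presence threshold) and the continuous Boyce index,
and combined into performance-weighted ensembles. Ecological realism is
enforced through hard monotonicity constraints: suitability must be
non-increasing in maximum temperature (warming beyond tolerance is
never beneficial) and non-decreasing in every other predictor.

The learner slots are a classic gradient-boosted tree machine
(LightGBM, searched over learning rate / tree complexity / tree count),
a second boosted-tree variant (XGBoost, searched over gamma / depth /
shrinkage / rounds) and a boosted additive stump learner
(scikit-learn's histogram gradient boosting restricted to depth-1
trees, searched over iterations / shrinkage / regularization). All
three support native monotone constraints.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import roc_auc_score

from .refine import mtp_threshold
from .spatial import HexBlocking
from .synthetic import PREDICTORS

log = logging.getLogger(__name__)

#: ecological monotone directions: warming past tolerance is harmful,
#: everything else is (weakly) favourable
MONOTONE_SIGNS = {p: (-1 if p == "max_temperature" else 1) for p in PREDICTORS}

ALGORITHMS = ("brt", "xgb_like", "adaboost_like")

#: complete hyperparameter grids of the full-scale study design
FULL_GRIDS: dict[str, dict[str, list]] = {
    "brt": {
        "learning_rate": [round(v, 3) for v in np.arange(0.01, 0.1001, 0.001)],
        "tree_complexity": [1, 2, 3, 4],
        "n_trees": list(range(50, 1001, 50)),
    },
    "adaboost_like": {
        "n_iterations": list(range(50, 251, 50)),
        "degrees_of_freedom": list(range(1, 13)),
        "shrinkage": [0.25, 0.5, 0.75, 1.0],
    },
    "xgb_like": {
        "gamma": [0, 1, 2, 3, 4, 5],
        "interaction_depth": [1, 2, 3, 4],
        "shrinkage": [0.1, 0.2, 0.3, 0.4, 0.5],
        "n_rounds": list(range(10, 101, 10)),
    },
}

#: desk-scale grids: each axis subsampled to at most two values
COARSE_GRIDS: dict[str, dict[str, list]] = {
    "brt": {"learning_rate": [0.05, 0.1], "tree_complexity": [2],
            "n_trees": [100, 300]},
    "adaboost_like": {"n_iterations": [100, 250], "degrees_of_freedom": [2],
                      "shrinkage": [0.5, 1.0]},
    "xgb_like": {"gamma": [0], "interaction_depth": [2],
                 "shrinkage": [0.1, 0.3], "n_rounds": [50, 100]},
}


@dataclass
class LearnerSpec:
    """One algorithm slot: its grid and per-predictor constraint signs."""

    algorithm_id: str
    grid: dict[str, list]
    monotone: dict[str, int] = field(default_factory=lambda: dict(MONOTONE_SIGNS))

    def __post_init__(self) -> None:
        if self.algorithm_id not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm_id}")
        if not all(self.grid.values()):
            raise ValueError("hyperparameter grid axes must be non-empty")
        missing = [p for p in PREDICTORS if p not in self.monotone]
        if missing:
            raise ValueError(f"missing monotone signs for {missing}")

    def combinations(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, vals))
                for vals in itertools.product(*(self.grid[k] for k in keys))]


def default_learners(grid_mode: str = "coarse") -> list[LearnerSpec]:
    grids = {"full": FULL_GRIDS, "coarse": COARSE_GRIDS}[grid_mode]
    return [LearnerSpec(a, grids[a]) for a in ALGORITHMS]


def make_estimator(algorithm_id: str, params: dict, seed: int,
                   monotone: dict[str, int] | None = None):
    """Instantiate a constrained boosted classifier for one grid point."""
    signs = [int((monotone or MONOTONE_SIGNS)[p]) for p in PREDICTORS]
    if algorithm_id == "brt":
        import lightgbm as lgb
        depth = int(params["tree_complexity"])
        return lgb.LGBMClassifier(
            learning_rate=float(params["learning_rate"]),
            max_depth=depth, num_leaves=min(2 ** depth, 31),
            n_estimators=int(params["n_trees"]),
            monotone_constraints=signs, min_child_samples=15,
            deterministic=True, force_row_wise=True,
            n_jobs=1, random_state=seed, verbose=-1)
    if algorithm_id == "xgb_like":
        import xgboost as xgb
        return xgb.XGBClassifier(
            gamma=float(params["gamma"]),
            max_depth=int(params["interaction_depth"]),
            learning_rate=float(params["shrinkage"]),
            n_estimators=int(params["n_rounds"]),
            monotone_constraints=tuple(signs), min_child_weight=5,
            n_jobs=1, random_state=seed, verbosity=0,
            tree_method="hist", eval_metric="logloss")
    if algorithm_id == "adaboost_like":
        return HistGradientBoostingClassifier(
            max_iter=int(params["n_iterations"]),
            learning_rate=float(params["shrinkage"]),
            l2_regularization=1.0 / float(params["degrees_of_freedom"]),
            max_depth=1, monotonic_cst=signs, min_samples_leaf=15,
            early_stopping=False, random_state=seed)
    raise ValueError(algorithm_id)


# ---------------------------------------------------------------------------
# collinearity


@dataclass
class CollinearityReport:
    vif: dict[str, float]
    flagged: list[str]


def compute_vif(design: np.ndarray, names: list[str] | None = None,
                threshold: float = 10.0) -> CollinearityReport:
    """Variance inflation factors VIF_j = 1/(1 - R²_j) from regressing
    each predictor on all others (with intercept). Constant predictors
    get infinite VIF and are flagged."""
    X = np.asarray(design, float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("need at least p + 2 records for VIF")
    names = names or [f"x{j}" for j in range(p)]
    vif: dict[str, float] = {}
    for j in range(p):
        yj = X[:, j]
        if yj.std() == 0:
            vif[names[j]] = float("inf")
            continue
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vif[names[j]] = float(np.inf) if r2 >= 1.0 else 1.0 / (1.0 - r2)
    flagged = [k for k, v in vif.items() if v > threshold]
    return CollinearityReport(vif=vif, flagged=flagged)


# ---------------------------------------------------------------------------
# spatial folds


@dataclass
class FoldAssignment:
    fold_id: np.ndarray     # 1..n_folds per record
    block_id: np.ndarray    # hex block per record
    n_folds: int


def assign_spatial_folds(rows: np.ndarray, cols: np.ndarray,
                         blocking: HexBlocking, n_folds: int = 10,
                         seed: int = 0) -> FoldAssignment:
    """Deal whole hexagonal blocks to folds, balancing record counts.

    All records of one block share a fold. If fewer non-empty blocks
    than folds exist the fold count is reduced with a warning.
    """
    block = blocking.block_id[np.asarray(rows), np.asarray(cols)]
    uniq, counts = np.unique(block, return_counts=True)
    if uniq.size < n_folds:
        log.warning("only %d non-empty blocks; reducing folds from %d",
                    uniq.size, n_folds)
        n_folds = max(2, int(uniq.size))
    rng = np.random.default_rng([seed, 21])
    order = rng.permutation(uniq.size)
    fold_of_block: dict[int, int] = {}
    load = np.zeros(n_folds, int)
    # largest shuffled blocks first, to the lightest fold
    for i in sorted(order, key=lambda i: -counts[i]):
        f = int(np.argmin(load))
        fold_of_block[int(uniq[i])] = f + 1
        load[f] += counts[i]
    fold = np.array([fold_of_block[int(b)] for b in block])
    return FoldAssignment(fold_id=fold, block_id=block, n_folds=n_folds)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ModelPerformance:
    auc: float
    sensitivity: float
    boyce: float
    converged: bool = True


def boyce_index(pred_presence: np.ndarray, pred_background: np.ndarray,
                n_windows: int = 101, window_frac: float = 0.1) -> float:
    """Continuous Boyce index of presence-only calibration.

    Moving windows of width ``window_frac`` of the suitability range
    slide across it; per window the predicted-to-expected ratio
    P/E = (fraction of presences in window) / (fraction of background
    in window) is computed, and the index is the Spearman rank
    correlation between window midpoint and P/E over windows with
    background support. Ranges from -1 (presences sit in the least
    suitable cells) through 0 (random) to 1.
    """
    pres = np.asarray(pred_presence, float)
    back = np.asarray(pred_background, float)
    if pres.size < 10:
        return float("nan")
    lo, hi = float(back.min()), float(back.max())
    if hi - lo <= 0:
        warnings.warn("zero-variance predictions: Boyce undefined")
        return float("nan")
    width = window_frac * (hi - lo)
    centers = np.linspace(lo + width / 2, hi - width / 2, n_windows)
    ratio, mids = [], []
    for c in centers:
        a, b = c - width / 2, c + width / 2
        e = ((back >= a) & (back <= b)).mean()
        if e <= 0:
            continue
        p = ((pres >= a) & (pres <= b)).mean()
        ratio.append(p / e)
        mids.append(c)
    if len(ratio) < 3 or np.std(ratio) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(mids, ratio)
    return float(rho)


# ---------------------------------------------------------------------------
# grid search


@dataclass
class GridSearchResult:
    algorithm_id: str
    best_params: dict
    fold_metrics: pd.DataFrame      # fold, auc, sensitivity, boyce
    mean_auc: float
    mean_sensitivity: float
    mean_boyce: float
    converged: bool
    #: metrics over out-of-fold predictions pooled across the rotation —
    #: robust when single folds hold too few presences for Boyce
    oof_auc: float = float("nan")
    oof_sensitivity: float = float("nan")
    oof_boyce: float = float("nan")


def grid_search_fit(X: np.ndarray, y: np.ndarray, folds: FoldAssignment,
                    learner: LearnerSpec, seed: int = 0) -> GridSearchResult:
    """Exhaustive grid search under rotating spatial-block CV.

    Every hyperparameter combination is trained on nine folds and
    scored on the held-out fold in rotation; the combination with the
    highest mean held-out AUC wins (the threshold-free reading of
    "minimizing prediction error"). The winner is then re-evaluated to
    collect sensitivity (at the training-presence MTP threshold) and
    Boyce alongside AUC per fold.
    """
    combos = learner.combinations()
    best_auc, best_params = -np.inf, None
    for params in combos:
        aucs = _cv_auc(X, y, folds, learner.algorithm_id, params, seed)
        if aucs and np.mean(aucs) > best_auc:
            best_auc, best_params = float(np.mean(aucs)), params
    if best_params is None:
        return GridSearchResult(learner.algorithm_id, {}, pd.DataFrame(),
                                np.nan, np.nan, np.nan, converged=False)
    rows = []
    oof_pred = np.full(len(y), np.nan)
    oof_hit = np.full(len(y), np.nan)     # presence >= fold threshold
    for f in range(1, folds.n_folds + 1):
        m = _eval_fold(X, y, folds.fold_id == f, learner.algorithm_id,
                       best_params, seed)
        if m is not None:
            rows.append({"fold": f, "auc": m["auc"],
                         "sensitivity": m["sensitivity"], "boyce": m["boyce"]})
            test = folds.fold_id == f
            oof_pred[test] = m["pred"]
            pres_test = test & (y == 1)
            oof_hit[pres_test] = (oof_pred[pres_test] >= m["threshold"])
    fm = pd.DataFrame(rows)
    have = ~np.isnan(oof_pred)
    pres = have & (y == 1)
    oof_auc = float(roc_auc_score(y[have], oof_pred[have])) \
        if len(np.unique(y[have])) == 2 else float("nan")
    return GridSearchResult(
        learner.algorithm_id, best_params, fm,
        mean_auc=float(fm["auc"].mean()),
        mean_sensitivity=float(fm["sensitivity"].mean()),
        mean_boyce=float(fm["boyce"].mean(skipna=True)) if fm["boyce"].notna().any()
        else float("nan"),
        converged=True,
        oof_auc=oof_auc,
        oof_sensitivity=float(np.nanmean(oof_hit)) if pres.any() else float("nan"),
        oof_boyce=boyce_index(oof_pred[pres], oof_pred[have]))


def _cv_auc(X, y, folds: FoldAssignment, algo: str, params: dict,
            seed: int) -> list[float]:
    aucs = []
    for f in range(1, folds.n_folds + 1):
        test = folds.fold_id == f
        ytr, yte = y[~test], y[test]
        if len(np.unique(ytr)) < 2:
            log.debug("fold %d: single-class training split skipped", f)
            continue
        if len(np.unique(yte)) < 2:
            continue
        try:
            est = make_estimator(algo, params, seed)
            est.fit(X[~test], ytr)
            p = est.predict_proba(X[test])[:, 1]
        except Exception as exc:       # non-converged combination
            log.warning("%s %s fold %d failed: %s", algo, params, f, exc)
            continue
        aucs.append(float(roc_auc_score(yte, p)))
    return aucs


def _eval_fold(X, y, test: np.ndarray, algo: str, params: dict,
               seed: int) -> dict | None:
    ytr, yte = y[~test], y[test]
    if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
        return None
    est = make_estimator(algo, params, seed)
    est.fit(X[~test], ytr)
    p_tr = est.predict_proba(X[~test])[:, 1]
    p_te = est.predict_proba(X[test])[:, 1]
    thr, _ = mtp_threshold(p_tr[ytr == 1])
    sens = float((p_te[yte == 1] >= thr).mean())
    return {"auc": float(roc_auc_score(yte, p_te)),
            "sensitivity": sens,
            "boyce": boyce_index(p_te[yte == 1], p_te),
            "pred": p_te, "threshold": thr}


# ---------------------------------------------------------------------------
# ensembling


@dataclass
class EnsemblePrediction:
    probability: np.ndarray          # same shape as the member predictions
    weights: np.ndarray
    member_ids: list[str]


def ensemble_predict(member_predictions: list[np.ndarray],
                     member_aucs: list[float],
                     member_ids: list[str] | None = None) -> EnsemblePrediction:
    """Performance-weighted convex combination of member predictions.

    Weights are (AUC - 0.5) clipped at zero and renormalized, so
    members no better than random contribute nothing; if every weight
    vanishes an unweighted mean is used with a warning.
    """
    if not member_predictions:
        raise ValueError("need at least one member")
    w = np.clip(np.asarray(member_aucs, float) - 0.5, 0.0, None)
    if w.sum() <= 0:
        warnings.warn("all ensemble weights zero; falling back to equal weights")
        w = np.ones(len(member_predictions))
    w = w / w.sum()
    prob = np.tensordot(w, np.stack(member_predictions), axes=1)
    return EnsemblePrediction(probability=np.clip(prob, 0.0, 1.0), weights=w,
                              member_ids=member_ids
                              or [f"m{i}" for i in range(len(w))])


def predictor_contribution(members: list, weights: np.ndarray,
                           X: np.ndarray, y: np.ndarray,
                           n_repeats: int = 10, seed: int = 0) -> pd.Series:
    """Permutation importance as percent contribution.

    Per member, the drop in AUC when one predictor's column is permuted
    (mean over ``n_repeats`` seeded shuffles, clipped at zero) is
    normalized to sum to 100 across predictors; member profiles are
    averaged by ensemble weight.
    """
    rng = np.random.default_rng([seed, 31])
    n = len(y)
    perms = [rng.permutation(n) for _ in range(n_repeats)]
    w = np.clip(np.asarray(weights, float), 0.0, None)
    if w.sum() <= 0:
        w = np.ones_like(w)
    w = w / w.sum()
    total = np.zeros(len(PREDICTORS))
    for est, wi in zip(members, w):
        if wi <= 0:
            continue
        base = roc_auc_score(y, est.predict_proba(X)[:, 1])
        drops = np.zeros(len(PREDICTORS))
        for j in range(len(PREDICTORS)):
            stacked = np.vstack([_permute_col(X, j, pm) for pm in perms])
            p = est.predict_proba(stacked)[:, 1].reshape(n_repeats, n)
            aucs = [roc_auc_score(y, p[r]) for r in range(n_repeats)]
            drops[j] = max(0.0, base - float(np.mean(aucs)))
        if drops.sum() <= 0:
            drops = np.ones(len(PREDICTORS))
        total += wi * (100.0 * drops / drops.sum())
    total = 100.0 * total / total.sum()
    return pd.Series(total, index=PREDICTORS)


def _permute_col(X: np.ndarray, j: int, perm: np.ndarray) -> np.ndarray:
    Xp = X.copy()
    Xp[:, j] = Xp[perm, j]
    return Xp


def partial_dependence(members: list, weights: np.ndarray, X: np.ndarray,
                       predictor: str, n_points: int = 50
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble partial-dependence curve for one predictor.

    The predictor is fixed at each of ``n_points`` values spanning its
    observed range while all other columns keep their data values; the
    curve is the weight-averaged mean prediction.
    """
    j = PREDICTORS.index(predictor)
    vals = np.linspace(X[:, j].min(), X[:, j].max(), n_points)
    n = X.shape[0]
    big = np.repeat(X[None, :, :], n_points, axis=0).reshape(-1, X.shape[1])
    big[:, j] = np.repeat(vals, n)
    w = np.clip(np.asarray(weights, float), 0.0, None)
    if w.sum() <= 0:
        w = np.ones_like(w)
    w = w / w.sum()
    curve = np.zeros(n_points)
    for est, wi in zip(members, w):
        if wi <= 0:
            continue
        p = est.predict_proba(big)[:, 1].reshape(n_points, n)
        curve += wi * p.mean(axis=1)
    return vals, curve
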