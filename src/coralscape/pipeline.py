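"""End-to-end orchestration: simulate -> thin -> pseudoabs -> fit ->
predict -> refine -> stack -> change -> bioregions -> anosim.

Every stage is idempotent and resumable: it writes its outputs plus a
``done.json`` recording a dependency hash (configuration + checksums of
the upstream outputs it consumed); a rerun recomputes a stage only if
its marker is missing or its dependencies changed. The run manifest
records parameter values, seeds and per-stage output checksums, so two
runs with the same master seed can be compared byte for byte.

A single master seed fans out to per-stage, per-species child seeds by
stable integer hashing, keeping stages reproducible independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# LightGBM's sklearn wrapper records auto-generated feature names at fit
# time and sklearn then warns on every numpy-array predict; harmless noise
warnings.filterwarnings("ignore",
                        message="X does not have valid feature names")

from . import bioregions as br
from . import community as cs
from . import diversity as dv
from . import ensemble as es
from . import occurrences as op
from . import refine as rf
from .grids import write_ascii_grid, read_ascii_grid
from .spatial import hex_blocks
from .synthetic import (PRESENT, EnvironmentalStack, WorldSpec,
                        generate_environment, generate_species,
                        sample_occurrences, write_world, read_environment)

log = logging.getLogger(__name__)

STAGES = ["simulate", "thin", "pseudoabs", "fit", "predict", "refine",
          "stack", "change", "bioregions", "anosim"]


@dataclass
class RunConfig:
    """All pipeline parameters. Defaults mirror the full study design
    (200 km dispersal, 0.95 sensitivity, k tested over 2..30, ANOSIM as
    100 runs x 10,000 cells); :func:`desk_config` scales the stochastic
    stages to desk size."""

    outdir: str = "run"
    seed: int = 7
    world: WorldSpec = field(default_factory=WorldSpec)
    n_occurrences: int = 500
    bias_strength: float = 0.5
    # thinning / correlogram: lags examined up to ~2x the predictors'
    # nominal autocorrelation range; this also caps the thinning distance
    # (the stopping rule caps at the last lag when, as here, large-scale
    # gradients keep similarity elevated at every examined distance)
    max_lag_km: float = 120.0
    n_lag_bins: int = 4
    correlogram_permutations: int = 199
    # pseudo-absences
    n_pa_clusters: int = 5
    # model fitting
    grid_mode: str = "coarse"           # "coarse" | "full"
    n_folds: int = 10
    min_hex_diameter_km: float = 150.0
    #: per-species permutation importances and partial-dependence curves
    #: (skippable for faster exploratory runs)
    predict_diagnostics: bool = True
    # refinement
    max_dispersal_km: float = 200.0
    connectivity: str = "queen"
    # bioregions
    k_min: int = 2
    k_max: int = 30
    kmeans_n_init: int = 10
    selection: str = "silhouette"
    # anosim
    anosim_runs: int = 100
    anosim_subsample: int = 10_000
    anosim_permutations: int = 199

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "world" in d and isinstance(d["world"], dict):
            d["world"] = WorldSpec(**d["world"])
        return cls(**d)


def desk_config(outdir: str | Path, seed: int = 7, **overrides) -> RunConfig:
    """The default desk-scale study: 60x60 grid, 40 species in two
    assemblage blocks, coarse hyperparameter grids, ANOSIM scaled to
    20 runs x 500 cells."""
    cfg = RunConfig(outdir=str(outdir), seed=seed,
                    world=WorldSpec(seed=seed),
                    anosim_runs=20, anosim_subsample=500)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def child_seed(master: int, stage: str, unit: str | int = "") -> int:
    """Stable 31-bit child seed from (master, stage, unit)."""
    h = hashlib.sha256(f"{master}:{stage}:{unit}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _dir_checksums(d: Path, exclude: tuple[str, ...] = ("done.json",)) -> dict:
    out = {}
    for f in sorted(d.rglob("*")):
        if f.is_file() and f.name not in exclude:
            out[str(f.relative_to(d))] = _sha256(f)
    return out


class Runner:
    """Executes the staged pipeline inside one output directory."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.stages_run: list[str] = []
        self._cache: dict = {}

    # -- caching machinery -------------------------------------------------

    def _stage_dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(exist_ok=True)
        return d

    def _depends_hash(self, stage: str) -> str:
        idx = STAGES.index(stage)
        payload = {"config": json.dumps(self.cfg.to_dict(), sort_keys=True)}
        if idx > 0:
            prev = self.out / STAGES[idx - 1]
            payload["upstream"] = _dir_checksums(prev) if prev.exists() else {}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()

    def _is_done(self, stage: str) -> bool:
        marker = self.out / stage / "done.json"
        if not marker.exists():
            return False
        rec = json.loads(marker.read_text())
        return rec.get("depends") == self._depends_hash(stage)

    def _mark_done(self, stage: str) -> None:
        d = self.out / stage
        marker = {"stage": stage, "depends": self._depends_hash(stage),
                  "checksums": _dir_checksums(d)}
        (d / "done.json").write_text(json.dumps(marker, indent=1, sort_keys=True))

    def run(self, through: str = "anosim") -> dict:
        """Run stages in order up to and including ``through``; returns
        the manifest dict (also written to manifest.json)."""
        limit = STAGES.index(through)
        t0 = time.time()
        for stage in STAGES[: limit + 1]:
            if self._is_done(stage):
                log.info("stage %s: cached, skipping", stage)
                continue
            log.info("stage %s: running", stage)
            getattr(self, f"stage_{stage}")()
            self._mark_done(stage)
            self.stages_run.append(stage)
        manifest = {
            "config": self.cfg.to_dict(),
            "master_seed": self.cfg.seed,
            "stages": {s: json.loads((self.out / s / "done.json").read_text())
                       ["checksums"]
                       for s in STAGES[: limit + 1]},
            "completed": STAGES[: limit + 1],
            "stages_recomputed": self.stages_run,
            "elapsed_s": round(time.time() - t0, 2),
        }
        (self.out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        return manifest

    # -- shared loaders ----------------------------------------------------

    def stack(self) -> EnvironmentalStack:
        if "stack" not in self._cache:
            self._cache["stack"] = read_environment(self.out / "simulate")
        return self._cache["stack"]

    def truths(self) -> pd.DataFrame:
        return pd.read_csv(self.out / "simulate" / "species_truth.csv")

    def species_ids(self) -> list[str]:
        return sorted(self.truths()["species"])

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.cfg
        stack = generate_environment(cfg.world)
        truths = generate_species(cfg.world, stack)
        occ = pd.concat([
            sample_occurrences(t, stack, cfg.n_occurrences, cfg.bias_strength,
                               seed=child_seed(cfg.seed, "simulate", t.species_id))
            for t in truths], ignore_index=True)
        write_world(self._stage_dir("simulate"), stack, truths, occ)

    def stage_thin(self) -> None:
        cfg = self.cfg
        stack = self.stack()
        occ = pd.read_csv(self.out / "simulate" / "occurrences.csv")
        occ["row"] = occ["row"].astype(int)
        occ["col"] = occ["col"].astype(int)
        thinned, correlo = [], []
        for sp, group in occ.groupby("species", sort=True):
            group = group.reset_index(drop=True)
            cg = op.estimate_thinning_distance(
                group, stack, max_lag_km=cfg.max_lag_km, n_bins=cfg.n_lag_bins,
                n_permutations=cfg.correlogram_permutations,
                seed=child_seed(cfg.seed, "thin", sp))
            t = op.thin_records(group, cg.thinning_distance_km,
                                seed=child_seed(cfg.seed, "thin2", sp))
            t = t.assign(thinning_distance_km=cg.thinning_distance_km)
            thinned.append(t)
            correlo.append(pd.DataFrame({
                "species": sp, "lag_lower_km": cg.lag_edges_km[:-1],
                "lag_upper_km": cg.lag_edges_km[1:], "r": cg.r, "p": cg.p,
                "thinning_distance_km": cg.thinning_distance_km,
                "fallback": cg.fallback}))
        d = self._stage_dir("thin")
        pd.concat(thinned, ignore_index=True).to_csv(
            d / "thinned_occurrences.csv", index=False)
        pd.concat(correlo, ignore_index=True).to_csv(
            d / "correlograms.csv", index=False)

    def stage_pseudoabs(self) -> None:
        cfg = self.cfg
        stack = self.stack()
        thinned = pd.read_csv(self.out / "thin" / "thinned_occurrences.csv")
        frames = []
        for sp, group in thinned.groupby("species", sort=True):
            occ_set = op.generate_pseudo_absences(
                sp, stack, group.reset_index(drop=True),
                float(group["thinning_distance_km"].iloc[0]),
                n_clusters=cfg.n_pa_clusters,
                seed=child_seed(cfg.seed, "pseudoabs", sp))
            frames.append(occ_set.pseudo_absences)
        d = self._stage_dir("pseudoabs")
        pd.concat(frames, ignore_index=True).to_csv(
            d / "pseudo_absences.csv", index=False)

    def _occurrence_sets(self) -> dict[str, op.OccurrenceSet]:
        thinned = pd.read_csv(self.out / "thin" / "thinned_occurrences.csv")
        pa = pd.read_csv(self.out / "pseudoabs" / "pseudo_absences.csv")
        sets = {}
        for sp, group in thinned.groupby("species", sort=True):
            sp_pa = pa[pa["species"] == sp].reset_index(drop=True)
            n_runs = int(sp_pa["run_id"].max()) if len(sp_pa) else 0
            sets[sp] = op.OccurrenceSet(
                species_id=sp, presences=group.reset_index(drop=True),
                pseudo_absences=sp_pa,
                thinning_distance_km=float(group["thinning_distance_km"].iloc[0]),
                n_runs=n_runs,
                n_pa_per_run=int((sp_pa["run_id"] == 1).sum()) if len(sp_pa) else 0)
        return sets

    def stage_fit(self) -> None:
        cfg = self.cfg
        stack = self.stack()
        sets = self._occurrence_sets()
        learners = es.default_learners(cfg.grid_mode)
        d = self._stage_dir("fit")
        (d / "models").mkdir(exist_ok=True)
        cv_rows, sel_rows, vif_rows = [], [], []
        table = {sc: stack.predictor_table(sc) for sc in stack.scenarios}
        shape = stack.grid.shape
        for sp in sorted(sets):
            oset = sets[sp]
            seed = child_seed(cfg.seed, "fit", sp)
            run1 = oset.run(1)
            X1 = table[PRESENT].reshape(*shape, -1)[
                run1["row"].astype(int), run1["col"].astype(int), :]
            y1 = run1["label"].to_numpy()
            vif = es.compute_vif(
                (X1 - X1.mean(0)) / np.where(X1.std(0) > 0, X1.std(0), 1.0),
                names=list(es.PREDICTORS))
            for name, v in vif.vif.items():
                vif_rows.append({"species": sp, "predictor": name, "vif": v,
                                 "flagged": name in vif.flagged})
            # hexagons match the inferred autocorrelation distance
            diam = max(oset.thinning_distance_km, cfg.min_hex_diameter_km)
            blocking = hex_blocks(stack.grid, diam)
            folds = es.assign_spatial_folds(
                run1["row"].astype(int).to_numpy(),
                run1["col"].astype(int).to_numpy(),
                blocking, n_folds=cfg.n_folds, seed=seed)
            members = []
            for learner in learners:
                gs = es.grid_search_fit(X1, y1, folds, learner, seed=seed)
                sel_rows.append({"species": sp, "algorithm": learner.algorithm_id,
                                 "converged": gs.converged,
                                 "mean_auc": gs.mean_auc,
                                 "mean_sensitivity": gs.mean_sensitivity,
                                 "mean_boyce": gs.mean_boyce,
                                 "oof_auc": gs.oof_auc,
                                 "oof_sensitivity": gs.oof_sensitivity,
                                 "oof_boyce": gs.oof_boyce,
                                 "best_params": json.dumps(gs.best_params)})
                if not gs.converged:
                    continue
                for _, row in gs.fold_metrics.iterrows():
                    cv_rows.append({"species": sp,
                                    "algorithm": learner.algorithm_id, **row})
                for run_id in range(1, oset.n_runs + 1):
                    data = oset.run(run_id)
                    Xr = table[PRESENT].reshape(*shape, -1)[
                        data["row"].astype(int), data["col"].astype(int), :]
                    yr = data["label"].to_numpy()
                    est = es.make_estimator(learner.algorithm_id, gs.best_params,
                                            seed=seed)
                    est.fit(Xr, yr)
                    members.append({"algorithm": learner.algorithm_id,
                                    "run_id": run_id, "auc": gs.mean_auc,
                                    "estimator": est})
            with open(d / "models" / f"{sp}.pkl", "wb") as fh:
                pickle.dump(members, fh)
        pd.DataFrame(cv_rows).to_csv(d / "cv_metrics.csv", index=False)
        pd.DataFrame(sel_rows).to_csv(d / "selected_models.csv", index=False)
        pd.DataFrame(vif_rows).to_csv(d / "vif.csv", index=False)

    def stage_predict(self) -> None:
        cfg = self.cfg
        stack = self.stack()
        sets = self._occurrence_sets()
        d = self._stage_dir("predict")
        table = {sc: stack.predictor_table(sc) for sc in stack.scenarios}
        shape = stack.grid.shape
        contrib_rows, pd_rows, final_rows, weight_rows = [], [], [], []
        for sp in sorted(sets):
            with open(self.out / "fit" / "models" / f"{sp}.pkl", "rb") as fh:
                members = pickle.load(fh)
            if not members:
                log.warning("%s: no converged members; skipped", sp)
                continue
            aucs = [m["auc"] for m in members]
            ids = [f"{m['algorithm']}_r{m['run_id']}" for m in members]
            weights = None
            for scen in stack.scenarios:
                preds = [m["estimator"].predict_proba(table[scen])[:, 1]
                         .reshape(shape) for m in members]
                ens = es.ensemble_predict(preds, aucs, ids)
                write_ascii_grid(d / f"{sp}__{scen}.asc", stack.grid,
                                 ens.probability)
                weights = ens.weights
            for mid, w in zip(ids, weights):
                weight_rows.append({"species": sp, "member": mid, "weight": w})
            # final-model diagnostics on the fitting data (run 1)
            oset = sets[sp]
            run1 = oset.run(1)
            X1 = table[PRESENT].reshape(*shape, -1)[
                run1["row"].astype(int), run1["col"].astype(int), :]
            y1 = run1["label"].to_numpy()
            ests = [m["estimator"] for m in members]
            p1 = es.ensemble_predict(
                [e.predict_proba(X1)[:, 1] for e in ests], aucs).probability
            thr, _ = rf.mtp_threshold(p1[y1 == 1])
            from sklearn.metrics import roc_auc_score
            _, pres_grid = read_ascii_grid(d / f"{sp}__{PRESENT}.asc")
            final_rows.append({
                "species": sp,
                "auc": float(roc_auc_score(y1, p1)),
                "sensitivity": float((p1[y1 == 1] >= thr).mean()),
                "boyce": es.boyce_index(p1[y1 == 1], pres_grid.ravel()),
            })
            if cfg.predict_diagnostics:
                contrib = es.predictor_contribution(
                    ests, np.asarray(aucs) - 0.5, X1, y1,
                    seed=child_seed(cfg.seed, "contrib", sp))
                for pred, val in contrib.items():
                    contrib_rows.append({"species": sp, "predictor": pred,
                                         "contribution_pct": val})
                w = np.clip(np.asarray(aucs) - 0.5, 0, None)
                for pred in ("max_temperature", "min_temperature", "rugosity"):
                    vals, curve = es.partial_dependence(ests, w, X1, pred)
                    for v, c in zip(vals, curve):
                        pd_rows.append({"species": sp, "predictor": pred,
                                        "value": v, "response": c})
        pd.DataFrame(final_rows).to_csv(d / "final_metrics.csv", index=False)
        pd.DataFrame(weight_rows).to_csv(d / "ensemble_weights.csv", index=False)
        pd.DataFrame(contrib_rows).to_csv(d / "contributions.csv", index=False)
        pd.DataFrame(pd_rows).to_csv(d / "partial_dependence.csv", index=False)

    def stage_refine(self) -> None:
        cfg = self.cfg
        stack = self.stack()
        d = self._stage_dir("refine")
        thinned = pd.read_csv(self.out / "thin" / "thinned_occurrences.csv")
        depth_table = pd.read_csv(self.out / "simulate" / "depth_ranges.csv")
        report = []
        for sp, group in thinned.groupby("species", sort=True):
            pres_file = self.out / "predict" / f"{sp}__{PRESENT}.asc"
            if not pres_file.exists():
                continue
            suit = {}
            for scen in stack.scenarios:
                _, arr = read_ascii_grid(self.out / "predict" / f"{sp}__{scen}.asc")
                suit[scen] = arr
            pres_cells = np.zeros(stack.grid.shape, bool)
            pres_cells[group["row"].astype(int), group["col"].astype(int)] = True
            pres_suit = suit[PRESENT][group["row"].astype(int),
                                      group["col"].astype(int)]
            genus = group["genus"].iloc[0]
            dr = rf.resolve_depth_range(sp, genus, depth_table)
            rng_ = rf.refine_range(sp, suit, pres_cells, pres_suit, dr,
                                   stack.bathymetry, stack.grid,
                                   max_dispersal_km=cfg.max_dispersal_km,
                                   connectivity=cfg.connectivity)
            for scen, b in rng_.presence.items():
                write_ascii_grid(d / f"{sp}__{scen}.asc", stack.grid,
                                 b.astype(float), fmt="%d")
            report.append({
                "species": sp, "threshold": rng_.threshold,
                "sensitivity": rng_.sensitivity_at_threshold,
                "depth_source": dr.source,
                **{f"removed_{scen}_{step}": n
                   for scen, steps in rng_.cells_removed.items()
                   for step, n in steps.items()}})
        pd.DataFrame(report).to_csv(d / "refinement_report.csv", index=False)

    def _binary_ranges(self) -> dict[str, dict[str, np.ndarray]]:
        stack = self.stack()
        out: dict[str, dict[str, np.ndarray]] = {s: {} for s in stack.scenarios}
        for f in sorted((self.out / "refine").glob("*__*.asc")):
            sp, scen = f.stem.split("__", 1)
            _, arr = read_ascii_grid(f)
            out[scen][sp] = np.nan_to_num(arr, nan=0.0).astype(bool)
        return out

    def stage_stack(self) -> None:
        stack = self.stack()
        ranges = self._binary_ranges()
        d = self._stage_dir("stack")
        for scen, by_sp in ranges.items():
            sr = dv.stack_richness([by_sp[s] for s in sorted(by_sp)])
            write_ascii_grid(d / f"richness__{scen}.asc", stack.grid,
                             sr.astype(float), fmt="%d")

    def stage_change(self) -> None:
        stack = self.stack()
        ranges = self._binary_ranges()
        d = self._stage_dir("change")
        species = sorted(ranges[PRESENT])
        present = [ranges[PRESENT][s] for s in species]
        area = stack.cell_area_km2()
        summary = []
        for scen in [s for s in ranges if s != PRESENT]:
            future = [ranges[scen][s] for s in species]
            cm = dv.change_metrics(present, future)
            for name, arr in [("gains", cm.gains), ("losses", cm.losses),
                              ("turnover", cm.turnover), ("refugia", cm.refugia)]:
                write_ascii_grid(d / f"{name}__{scen}.asc", stack.grid,
                                 np.asarray(arr, float))
            has = cm.sr > 0
            w = area[has]
            summary.append({
                "scenario": scen,
                "mean_turnover": float(np.nansum(cm.turnover[has] * w) / w.sum()),
                "mean_refugia": float(np.nansum(cm.refugia[has] * w) / w.sum()),
                "total_gains": int(cm.gains.sum()),
                "total_losses": int(cm.losses.sum()),
            })
        pd.DataFrame(summary).to_csv(d / "change_summary.csv", index=False)

    def _prediction_matrix(self) -> "br.CellSpeciesMatrix":
        """Cell x species occurrence probabilities for community analyses.

        Each species' ensemble probability is masked to its refined
        present-day range: habitat that is climatically suitable but
        unreachable under the dispersal constraint (or outside the depth
        range) is not part of the species' predicted distribution, so it
        contributes zero. Cells left with no species (the stacked map's
        blank areas) drop out of the matrix.
        """
        preds = {}
        for f in sorted((self.out / "predict").glob(f"*__{PRESENT}.asc")):
            sp = f.stem.split("__")[0]
            _, prob = read_ascii_grid(f)
            _, rng_ = read_ascii_grid(self.out / "refine" / f"{sp}__{PRESENT}.asc")
            mask = np.nan_to_num(rng_, nan=0.0) > 0
            preds[sp] = np.clip(np.nan_to_num(prob, nan=0.0), 0.0, 1.0) * mask
        return br.build_matrix(preds)

    def stage_bioregions(self) -> None:
        cfg = self.cfg
        stack = self.stack()
        d = self._stage_dir("bioregions")
        matrix = self._prediction_matrix()
        model = br.fit_bioregions(
            matrix, k_range=range(cfg.k_min, cfg.k_max + 1),
            n_init=cfg.kmeans_n_init, selection=cfg.selection,
            seed=child_seed(cfg.seed, "bioregions"))
        write_ascii_grid(d / "bioregion_assignment.asc", stack.grid,
                         model.assignment_grid())
        model.selection_curve.to_csv(d / "selection_curve.csv", index=False)
        if model.dendrogram is not None:
            newick = br.linkage_to_newick(
                model.dendrogram, [f"region{r + 1}" for r in range(model.k)])
            (d / "centroid_dendrogram.nwk").write_text(newick + "\n")
        summaries = br.summarize_bioregions(model, self._binary_ranges(),
                                            stack.bathymetry,
                                            stack.cell_area_km2())
        rows = []
        for s in summaries:
            row = {"region": s.region, "n_cells": s.n_cells,
                   "area_km2": s.area_km2, "sr": s.sr, "endemics": s.endemics,
                   "mean_depth_m": s.mean_depth_m, "depth_q05_m": s.depth_q05_m,
                   "depth_q95_m": s.depth_q95_m}
            for scen, ch in s.change.items():
                row[f"delta_sr_{scen}"] = ch["delta_sr"]
                row[f"turnover_{scen}"] = ch["turnover"]
            rows.append(row)
        pd.DataFrame(rows).to_csv(d / "bioregion_summary.csv", index=False)
        np.save(d / "assignment.npy", model.assignment)  # runtime cache
        np.save(d / "cell_index.npy", model.cell_index)

    def stage_anosim(self) -> None:
        cfg = self.cfg
        d = self._stage_dir("anosim")
        matrix = self._prediction_matrix()
        assignment = np.load(self.out / "bioregions" / "assignment.npy")
        cell_index = np.load(self.out / "bioregions" / "cell_index.npy")
        model = br.BioregionModel(
            k=int(assignment.max()) + 1, assignment=assignment,
            centroids=np.zeros((int(assignment.max()) + 1,
                                matrix.values.shape[1])),
            wcss=0, bcss=0, tss=0, selection_curve=pd.DataFrame(),
            dendrogram=None, cell_index=cell_index,
            grid_shape=matrix.grid_shape, species_ids=matrix.species_ids)
        ens = cs.subsampled_anosim(
            matrix, model, n_runs=cfg.anosim_runs,
            subsample_size=cfg.anosim_subsample,
            n_permutations=cfg.anosim_permutations,
            seed=child_seed(cfg.seed, "anosim"))
        pd.DataFrame([{"run": i + 1, "r": r.r, "p": r.p}
                      for i, r in enumerate(ens.runs)]).to_csv(
            d / "anosim_runs.csv", index=False)
        (d / "anosim_summary.json").write_text(json.dumps({
            "mean_r": ens.mean_r, "prop_significant": ens.prop_significant,
            "n_runs": ens.n_runs, "subsample_size": ens.subsample_size,
            "n_skipped": ens.n_skipped}, indent=1))


def run_pipeline(config: RunConfig, through: str = "anosim") -> dict:
    """Convenience wrapper: build a :class:`Runner` and execute it."""
    return Runner(config).run(through)
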