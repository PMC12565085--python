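"""Configuration-driven orchestration of the full QSAR workflow.

A single YAML config drives nine stages — curate, split, featurize, select,
train, evaluate, ad, alerts, map — each writing deterministic CSV/JSON
artifacts into the output directory. A run manifest records the config, the
software versions, every seed, and a sha256 checksum per artifact, so a
re-run with the same config reproduces the deterministic artifacts
byte-identically. Validation-set chemicals never enter any training-side
stage: descriptor selection, grid search and cross-validation all operate on
training rows only, and the manifest records both id sets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admodel import (
    DcMode,
    apply_domain,
    coverage_performance_curve,
    dc_threshold,
    morgan_fingerprints,
    score_set,
)
from .alerts import lr_ad_filter, mine_alerts, predict_by_alerts
from .chemreg import (
    ChemicalRecord,
    Endpoint,
    Qualifier,
    curate,
    read_input_csv,
    write_curated,
)
from .datasets import ClassScheme, build_class_set, every_kth_split
from .errors import ConfigInvalidError
from .features import compute_descriptors, filter_descriptors, topliss_ratio
from .metrics import RegressionEval, regression_report
from .models import (
    REGRESSION,
    CVProtocol,
    TaskSpec,
    fit_model,
    grid_search,
    repeated_cv,
)
from .selection import select_descriptors
from .synthdata import GeneratorConfig, PlantedFragment, generate_dataset
from .tkmap import TKProfile, categorize_tk, concern_flag, family_summary

log = logging.getLogger("tkqsar")

STAGES = ("curate", "split", "featurize", "select", "train", "evaluate",
          "ad", "alerts", "map")


def validate_config(cfg: dict) -> dict:
    """Schema-check a config mapping; every stochastic stage needs a seed."""
    if not isinstance(cfg, dict):
        raise ConfigInvalidError("config must be a mapping")
    for key in ("seed", "output_dir", "endpoint", "input"):
        if key not in cfg:
            raise ConfigInvalidError(f"config missing required key {key!r}")
    if not isinstance(cfg["seed"], int):
        raise ConfigInvalidError("seed must be an integer")
    try:
        Endpoint[cfg["endpoint"]]
    except KeyError:
        raise ConfigInvalidError(f"unknown endpoint {cfg['endpoint']!r}")
    inp = cfg["input"]
    if not isinstance(inp, dict) or inp.get("kind") not in ("synthetic", "csv"):
        raise ConfigInvalidError("input.kind must be 'synthetic' or 'csv'")
    if inp["kind"] == "csv" and "path" not in inp:
        raise ConfigInvalidError("input.kind=csv requires input.path")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _scheme_from(cfg: dict, endpoint: Endpoint) -> ClassScheme:
    cuts = cfg.get("class_cutpoints")
    if cuts is None:
        cuts = [50.0] if endpoint is Endpoint.F_PERCENT else [1.0]
    labels = ("low", "high") if len(cuts) == 1 else ("low", "medium", "high")
    return ClassScheme(endpoint, tuple(float(c) for c in cuts), labels)


class PipelineRun:
    """Executes stages in order, accumulating artifacts and the manifest."""

    def __init__(self, cfg: dict):
        self.cfg = validate_config(cfg)
        self.endpoint = Endpoint[cfg["endpoint"]]
        self.out = Path(cfg["output_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(cfg["seed"])
        self.artifacts: dict[str, list[str]] = {}
        self.state: dict = {}

    # -- artifact helpers ---------------------------------------------------
    def _write_csv(self, stage: str, name: str, frame: pd.DataFrame) -> Path:
        path = self.out / name
        frame.to_csv(path, index=False)
        self.artifacts.setdefault(stage, []).append(name)
        return path

    def _write_json(self, stage: str, name: str, obj) -> Path:
        path = self.out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                                   default=str) + "\n")
        self.artifacts.setdefault(stage, []).append(name)
        return path

    # -- stages -------------------------------------------------------------
    def stage_curate(self):
        inp = self.cfg["input"]
        if inp["kind"] == "synthetic":
            gen_cfg = GeneratorConfig(
                n_chemicals=int(inp.get("n_chemicals", 300)),
                seed=self.seed,
                endpoint=self.endpoint,
                planted_fragments=[
                    PlantedFragment(f["smiles"], float(f["effect"]),
                                    float(f["rate"]))
                    for f in inp["fragments"]
                ] if "fragments" in inp else GeneratorConfig(
                    n_chemicals=1, seed=0).planted_fragments,
                noise_sd=float(inp.get("noise_sd", 5.0)),
                duplicate_rate=float(inp.get("duplicate_rate", 0.05)),
                qualifier_rate=float(inp.get("qualifier_rate", 0.05)),
                out_of_range_rate=float(inp.get("out_of_range_rate", 0.02)),
            )
            raw, truth = generate_dataset(gen_cfg)
            self.state["truth"] = truth
            self._write_json("curate", "truth.json", truth)
        else:
            raw = read_input_csv(inp["path"])
        ds = curate(raw)
        write_curated(ds, self.out / "curated.csv", self.out / "exclusions.csv")
        self.artifacts.setdefault("curate", []).extend(
            ["curated.csv", "exclusions.csv"])
        self.state["dataset"] = ds
        log.info("curate: %d records kept, %d excluded",
                 len(ds.records), len(ds.exclusions))

    def stage_split(self):
        ds = self.state["dataset"]
        split_cfg = self.cfg.get("split", {})
        eq_values = {
            rid: mv.value for rid, mv in ds.measurements.items()
            if mv.qualifier is Qualifier.EQ
        }
        split = every_kth_split(eq_values, k=int(split_cfg.get("k", 4)),
                                offset=int(split_cfg.get("offset", 0)))
        self.state["split"] = split
        rows = [{"id": i, "partition": "train"} for i in split.train_ids] + [
            {"id": i, "partition": "valid"} for i in split.valid_ids]
        self._write_csv("split", "split.csv",
                        pd.DataFrame(rows).sort_values("id"))
        scheme = _scheme_from(self.cfg, self.endpoint)
        self.state["scheme"] = scheme
        labels = build_class_set(ds.measurements, scheme)
        self._write_csv("split", "class_labels.csv", pd.DataFrame(
            [{"id": i, "label": l} for i, l in sorted(labels.items())]))
        self.state["labels"] = labels
        log.info("split: %d train / %d valid",
                 len(split.train_ids), len(split.valid_ids))

    def stage_featurize(self):
        ds = self.state["dataset"]
        feat_cfg = self.cfg.get("descriptors", {})
        matrix = compute_descriptors(
            sorted(ds.records, key=lambda r: r.record_id),
            backend=feat_cfg.get("backend", "rdkit2d"))
        filtered, removal_log = filter_descriptors(
            matrix, corr_cutoff=float(feat_cfg.get("corr_cutoff", 0.97)))
        self.state["descriptors"] = filtered
        self._write_csv("featurize", "descriptors.csv",
                        filtered.frame.rename_axis("id").reset_index())
        self._write_csv("featurize", "descriptor_removals.csv", removal_log)
        log.info("featurize: %d -> %d descriptors",
                 len(matrix.names), len(filtered.names))

    def _train_xy(self):
        ds, split = self.state["dataset"], self.state["split"]
        desc = self.state["descriptors"].frame
        ids = [i for i in split.train_ids if i in desc.index]
        x = desc.loc[ids]
        y = np.asarray([ds.measurements[i].value for i in ids])
        return ids, x, y

    def _valid_xy(self):
        ds, split = self.state["dataset"], self.state["split"]
        desc = self.state["descriptors"].frame
        ids = [i for i in split.valid_ids if i in desc.index]
        x = desc.loc[ids]
        y = np.asarray([ds.measurements[i].value for i in ids])
        return ids, x, y

    def stage_select(self):
        sel_cfg = self.cfg.get("selection", {})
        _, x, y = self._train_xy()
        result = select_descriptors(
            x, y, seed=self.seed,
            n_repeats=int(sel_cfg.get("n_repeats", 3)),
            n_trees=int(sel_cfg.get("n_trees", 500)),
            stepwise_trees=int(sel_cfg.get("stepwise_trees", 100)),
            patience=int(sel_cfg.get("patience", 3)))
        if not result.interpretation_set:
            # degenerate safeguard: keep the top-ranked descriptor
            result.interpretation_set = [result.ranked["name"].iloc[0]]
        self.state["selected"] = result.interpretation_set
        ratio, ok = topliss_ratio(len(x), len(result.interpretation_set))
        self._write_json("select", "selection.json", {
            "interpretation_set": result.interpretation_set,
            "threshold_set": result.threshold_set,
            "noise_floor": result.noise_floor,
            "topliss_ratio": ratio, "topliss_compliant": ok,
            "seeds": result.seeds,
        })
        log.info("select: %d descriptors (Topliss %d:1)",
                 len(result.interpretation_set), ratio)

    def _task_spec(self) -> TaskSpec:
        transform = "ln" if self.endpoint is Endpoint.VDSS_L_PER_KG else "identity"
        return TaskSpec(task=REGRESSION, endpoint=self.endpoint,
                        scheme=self.state["scheme"],
                        target_transform=transform)

    def stage_train(self):
        model_cfg = self.cfg.get("model", {})
        learner = model_cfg.get("learner", "rf")
        grid = model_cfg.get("grid", {"n_estimators": [100, 300]})
        _, x, y = self._train_xy()
        x = x[self.state["selected"]]
        spec = self._task_spec()
        best, table = grid_search(learner, grid, x, y, spec, seed=self.seed)
        fitted = fit_model(learner, x, y, spec, params=best, seed=self.seed)
        self.state["model"] = fitted
        self._write_csv("train", "grid_search.csv", table)
        fitted.save_manifest(self.out / "model_manifest.json")
        self.artifacts.setdefault("train", []).append("model_manifest.json")
        log.info("train: %s with %s", learner, best)

    def stage_evaluate(self):
        model_cfg = self.cfg.get("model", {})
        cv_cfg = model_cfg.get("cv", {})
        fitted = self.state["model"]
        _, x_tr, y_tr = self._train_xy()
        valid_ids, x_va, y_va = self._valid_xy()
        x_tr = x_tr[self.state["selected"]]
        x_va = x_va[self.state["selected"]]
        pred = fitted.predict(x_va)
        self.state["valid_pred"] = dict(zip(valid_ids, pred))
        e = RegressionEval(y_out=y_va, y_hat=pred, y_train=y_tr)
        report = regression_report(e)
        protocol = CVProtocol(
            n_iterations=int(cv_cfg.get("n_iterations", 50)),
            n_folds=int(cv_cfg.get("n_folds", 5)), seed=self.seed)
        cv = repeated_cv(fitted.learner, x_tr, y_tr, fitted.spec,
                         protocol, params=fitted.params)
        self._write_csv("evaluate", "predictions.csv", pd.DataFrame({
            "id": valid_ids, "observed": y_va, "predicted": pred,
            "predicted_class": fitted.predict_class(x_va),
        }))
        self._write_json("evaluate", "validation_metrics.json", report)
        self._write_csv("evaluate", "cv_report.csv", cv.aggregate)
        log.info("evaluate: %s", {k: round(v, 3) for k, v in report.items()})

    def stage_ad(self):
        ad_cfg = self.cfg.get("ad", {})
        ds, split = self.state["dataset"], self.state["split"]
        by_id = {r.record_id: r for r in ds.records}
        train_fp = morgan_fingerprints(
            [by_id[i] for i in split.train_ids],
            radius=int(ad_cfg.get("radius", 2)),
            n_bits=int(ad_cfg.get("n_bits", 2048)))
        valid_fp = morgan_fingerprints(
            [by_id[i] for i in split.valid_ids],
            radius=int(ad_cfg.get("radius", 2)),
            n_bits=int(ad_cfg.get("n_bits", 2048)))
        scores = score_set(valid_fp, train_fp, k=int(ad_cfg.get("k", 3)))
        dc = dc_threshold([s.mean_knn_tanimoto for s in scores],
                          z=float(ad_cfg.get("z", 0.5)),
                          mode=DcMode[ad_cfg.get("mode", "MINUS")])
        scores = apply_domain(scores, dc)
        self.state["ad_scores"] = {s.query_id: s for s in scores}
        self.state["dc"] = dc
        self._write_csv("ad", "ad_scores.csv", pd.DataFrame([{
            "id": s.query_id, "mean_knn_tanimoto": s.mean_knn_tanimoto,
            "neighbors": ";".join(n for n, _ in s.neighbors),
            "in_domain": s.in_domain} for s in scores]))
        # coverage-performance curve against the evaluation predictions
        valid_ids = [s.query_id for s in scores]
        y_obs = np.asarray([ds.measurements[i].value for i in valid_ids])
        y_hat = np.asarray([self.state["valid_pred"][i] for i in valid_ids])
        rmse_fn = lambda yt, yp: float(np.sqrt(np.mean((yt - yp) ** 2)))
        curve = coverage_performance_curve(
            scores, y_obs, y_hat, rmse_fn,
            thresholds=np.linspace(0, 1, int(ad_cfg.get("n_thresholds", 101))))
        self._write_csv("ad", "ad_curve.csv", pd.DataFrame(curve))
        self._write_json("ad", "ad_threshold.json", {
            "dc": dc, "z": float(ad_cfg.get("z", 0.5)),
            "mode": ad_cfg.get("mode", "MINUS"),
            "coverage_at_dc": float(np.mean(
                [s.mean_knn_tanimoto >= dc for s in scores]))})
        log.info("ad: Dc=%.3f", dc)

    def stage_alerts(self):
        alert_cfg = self.cfg.get("alerts", {})
        ds, split = self.state["dataset"], self.state["split"]
        labels = self.state["labels"]
        by_id = {r.record_id: r for r in ds.records}
        train_records = [by_id[i] for i in split.train_ids if i in labels]
        rules = mine_alerts(
            train_records, labels,
            min_atoms=int(alert_cfg.get("min_atoms", 2)),
            max_atoms=int(alert_cfg.get("max_atoms", 6)),
            min_support=int(alert_cfg.get("min_support", 3)),
            min_lr=float(alert_cfg.get("min_lr", 2.0)))
        self.state["rules"] = rules
        self._write_csv("alerts", "alert_rules.csv", pd.DataFrame([{
            "smarts": r.fragment, "class": r.target_class, "tp": r.tp,
            "fp": r.fp, "lr": r.lr, "capped_lr": r.capped_lr}
            for r in rules]))
        preds = [predict_by_alerts(by_id[i], rules) for i in split.valid_ids]
        inside, _ = lr_ad_filter(preds,
                                 float(alert_cfg.get("lr_threshold", 0.0)))
        in_ids = {p.query_id for p in inside}
        self.state["alert_preds"] = preds
        self._write_csv("alerts", "alert_predictions.csv", pd.DataFrame([{
            "id": p.query_id, "class": p.predicted_class,
            "lr": p.lr_of_prediction, "in_domain": p.query_id in in_ids}
            for p in preds]))
        log.info("alerts: %d rules, %d/%d valid chemicals in LR domain",
                 len(rules), len(inside), len(preds))

    def stage_map(self):
        ds = self.state["dataset"]
        truth = self.state.get("truth", {})
        ad_scores = self.state["ad_scores"]
        profiles = []
        for rid, pred in sorted(self.state["valid_pred"].items()):
            fam = (truth.get(rid, {}).get("fragment") or "none") if truth else ""
            in_ad = bool(ad_scores[rid].in_domain) if rid in ad_scores else True
            kwargs = {"f_percent": float(pred)} if \
                self.endpoint is Endpoint.F_PERCENT else {"vdss": float(pred)}
            profiles.append(TKProfile(chemical_id=rid, family=fam,
                                      in_f_ad=in_ad, in_vdss_ad=in_ad,
                                      **kwargs))
        rows = []
        for p in profiles:
            cats = categorize_tk(p)
            rows.append({"id": p.chemical_id, "family": p.family,
                         "vdss_cat": cats[0], "f_cat": cats[1],
                         "t12_cat": cats[2], "concern": concern_flag(cats)})
        self._write_csv("map", "tk_profiles.csv", pd.DataFrame(rows))
        self._write_csv("map", "family_summary.csv", family_summary(profiles))
        log.info("map: %d profiles, %d flagged", len(rows),
                 sum(r["concern"] for r in rows))

    # -- driver -------------------------------------------------------------
    def run(self, stages: tuple[str, ...] = STAGES) -> dict:
        for stage in stages:
            log.info("stage %s ...", stage)
            getattr(self, f"stage_{stage}")()
        manifest = {
            "tkqsar_version": __version__,
            "seed": self.seed,
            "config": {k: v for k, v in self.cfg.items()},
            "stages": [
                {"name": s,
                 "artifacts": [{"path": a, "sha256": _sha256(self.out / a)}
                               for a in self.artifacts.get(s, [])]}
                for s in stages
            ],
            "train_ids": list(self.state["split"].train_ids)
            if "split" in self.state else [],
            "valid_ids": list(self.state["split"].valid_ids)
            if "split" in self.state else [],
        }
        (self.out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        return manifest


def run_pipeline(cfg: dict) -> dict:
    """Validate the config and execute all nine stages; returns the manifest."""
    return PipelineRun(cfg).run()
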