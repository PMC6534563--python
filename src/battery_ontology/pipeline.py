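"""Config-driven end-to-end orchestration of ontology discovery.

Stage order mirrors the analysis workflow: DV reliability, task-survey
association (network + cross-category prediction), per-category factor
analysis, loading-space clustering with consensus robustness, outcome
target construction, and outcome prediction. Each stage writes CSV/JSON
artifacts into the output directory, and a run manifest records the
configuration hash, seeds and package versions so that two runs with
identical manifests produce identical payloads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .battery import DVMatrix, RetestPair, CovariateTable, load_dv_matrix, write_matrix
from .clustering import (
    build_tree,
    consensus_cluster,
    dynamic_tree_cut,
    fixed_height_cut,
    loading_distance,
    adjusted_mutual_information,
    silhouette,
    silhouette_sweep,
)
from .efa import bootstrap_loadings, factor_scores, fit_efa, select_dimensionality
from .network import (
    cross_category_prediction,
    fit_partial_correlation_graph,
    threshold_and_export,
)
from .prediction import derive_outcome_targets, predict_targets
from .reliability import communality_reliability_corr, reliability_table
from .synthetic import (
    GeneratorConfig,
    generate_battery,
    generate_covariates,
    generate_outcomes,
    generate_retest,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "ontology_out"
    seed: int = 0
    # input: either file paths or a synthetic generator config
    battery_path: str | None = None
    meta_path: str | None = None
    retest_path: str | None = None
    covariates_path: str | None = None
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    stages: dict = field(
        default_factory=lambda: {
            "reliability": True,
            "network": True,
            "efa": True,
            "clustering": True,
            "prediction": True,
        }
    )
    # stage parameters
    f_candidates_task: list | None = None
    f_candidates_survey: list | None = None
    n_boot: int = 200
    min_cluster_size: int = 3
    deep_split: int = 2
    n_consensus_sim: int = 500
    consensus_drop_frac: float = 0.2
    n_lambda: int = 100
    edge_threshold: float = 0.05
    prediction_model: str = "ridge"
    k_folds: int = 10
    n_perm: int = 500
    cross_prediction: bool = False  # per-DV cross-category CV is expensive

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _generator_config(cfg: PipelineConfig) -> GeneratorConfig:
    gc = GeneratorConfig(seed=cfg.seed)
    for key, val in cfg.generator.items():
        if not hasattr(gc, key):
            raise ValueError(f"unknown generator key {key!r}")
        cur = getattr(gc, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            for k2, v2 in val.items():
                setattr(cur, k2, v2)
        else:
            setattr(gc, key, val)
    return gc


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; returns in-memory results and writes artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "versions": {
            "battery_ontology": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages_run": [],
    }
    results: dict = {}

    # ---- inputs -------------------------------------------------------------
    stage = "input"
    try:
        if cfg.battery_path:
            battery = load_dv_matrix(cfg.battery_path, cfg.meta_path)
            gt = None
            pair = None
            if cfg.retest_path:
                t2 = load_dv_matrix(cfg.retest_path, cfg.meta_path)
                shared = [i for i in battery.participant_ids
                          if i in set(t2.participant_ids)]
                pair = RetestPair(
                    battery.select_participants(shared),
                    t2.select_participants(shared),
                    shared,
                )
            covariates = None
            if cfg.covariates_path:
                covariates = CovariateTable(
                    pd.read_csv(cfg.covariates_path, index_col=0)
                )
        else:
            gen_cfg = _generator_config(cfg)
            battery, gt = generate_battery(gen_cfg)
            pair = generate_retest(gen_cfg, gt, battery)
            covariates = generate_covariates(gen_cfg, battery.participant_ids)
            outcome_dvm, gt = generate_outcomes(gt, gen_cfg, covariates)
            results["outcome_battery"] = outcome_dvm
            write_matrix(battery, out / "battery.csv")
        results.update({"battery": battery, "retest": pair,
                        "covariates": covariates, "ground_truth": gt})
    except Exception as exc:
        raise StageError(stage, exc)
    manifest["stages_run"].append(stage)

    categories = [
        c for c in ("task", "survey")
        if (battery.meta["category"] == c).any()
    ]

    # ---- reliability --------------------------------------------------------
    if cfg.stages.get("reliability", True) and results["retest"] is not None:
        stage = "reliability"
        try:
            rel = reliability_table(results["retest"])
            rel.to_csv(out / "reliability.csv")
            results["reliability"] = rel
        except Exception as exc:
            raise StageError(stage, exc)
        manifest["stages_run"].append(stage)

    # ---- network (task-survey association) ----------------------------------
    if cfg.stages.get("network", True) and len(categories) == 2:
        stage = "network"
        try:
            ts = battery.select_dvs(
                [d for d in battery.dv_names
                 if battery.meta.loc[d, "category"] in ("task", "survey")]
            )
            graph = fit_partial_correlation_graph(ts, n_lambda=cfg.n_lambda)
            export = threshold_and_export(
                graph, cfg.edge_threshold,
                edge_path=out / "edges.csv",
                graphml_path=out / "graph.graphml",
            )
            graph.ebic_curve.to_csv(out / "ebic_curve.csv", index=False)
            results["network"] = {"graph": graph, "export": export}
            if cfg.cross_prediction:
                xpred = cross_category_prediction(ts, k=cfg.k_folds, seed=cfg.seed)
                xpred.to_csv(out / "cross_prediction.csv", index=False)
                results["network"]["cross_prediction"] = xpred
        except Exception as exc:
            raise StageError(stage, exc)
        manifest["stages_run"].append(stage)

    # ---- per-category EFA ---------------------------------------------------
    if cfg.stages.get("efa", True):
        stage = "efa"
        try:
            efa_out = {}
            for cat in categories:
                sub = battery.select_category(cat)
                cands = (cfg.f_candidates_task if cat == "task"
                         else cfg.f_candidates_survey)
                sweep = select_dimensionality(sub, cands, seed=cfg.seed)
                model = fit_efa(sub, sweep.best_f, seed=cfg.seed)
                scores = factor_scores(model, sub)
                sweep.to_csv(out / f"sweep_{cat}.csv")
                model.to_json(out / f"efa_{cat}.json")
                model.loadings.to_csv(out / f"loadings_{cat}.csv")
                scores.scores.to_csv(out / f"scores_{cat}.csv")
                boot = bootstrap_loadings(
                    sub, sweep.best_f, n_boot=cfg.n_boot, seed=cfg.seed,
                    base_model=model,
                )
                boot["sd"].to_csv(out / f"loading_sd_{cat}.csv")
                entry = {"sweep": sweep, "model": model,
                         "scores": scores, "bootstrap": boot}
                if "reliability" in results:
                    entry["communality_reliability"] = communality_reliability_corr(
                        model.communality, results["reliability"]
                    )
                efa_out[cat] = entry
            results["efa"] = efa_out
        except Exception as exc:
            raise StageError(stage, exc)
        manifest["stages_run"].append(stage)

    # ---- clustering ---------------------------------------------------------
    if cfg.stages.get("clustering", True) and "efa" in results:
        stage = "clustering"
        try:
            clust_out = {}
            for cat, entry in results["efa"].items():
                model = entry["model"]
                dist = loading_distance(model.loadings)
                tree = build_tree(dist)
                dyn = dynamic_tree_cut(
                    tree, dist,
                    min_cluster_size=cfg.min_cluster_size,
                    deep_split=cfg.deep_split,
                )
                fixed = fixed_height_cut(tree, dist, n_clusters=dyn.n_clusters())
                ami = adjusted_mutual_information(dyn.labels, fixed.labels)
                sil = silhouette(dist, dyn.labels) if dyn.n_clusters() > 1 else None
                cons = consensus_cluster(
                    entry["bootstrap"]["mean"], entry["bootstrap"]["sd"],
                    dyn.labels, n_sim=cfg.n_consensus_sim,
                    drop_frac=cfg.consensus_drop_frac, seed=cfg.seed,
                    min_cluster_size=cfg.min_cluster_size,
                    deep_split=cfg.deep_split,
                )
                pd.DataFrame(
                    {"dv_name": dyn.labels.index, "cluster_id": dyn.labels.values}
                ).to_csv(out / f"clusters_{cat}.csv", index=False)
                cons.cooccurrence.to_csv(out / f"cooccurrence_{cat}.csv")
                clust_out[cat] = {
                    "dynamic": dyn, "fixed": fixed,
                    "ami_dynamic_vs_fixed": ami,
                    "silhouette": sil, "consensus": cons,
                }
            results["clustering"] = clust_out
        except Exception as exc:
            raise StageError(stage, exc)
        manifest["stages_run"].append(stage)

    # ---- outcome prediction -------------------------------------------------
    if cfg.stages.get("prediction", True):
        stage = "prediction"
        try:
            outcome_dvm = results.get("outcome_battery")
            if outcome_dvm is None and "outcome" in set(battery.meta["category"]):
                outcome_dvm = battery.select_category("outcome")
            if outcome_dvm is not None and results["covariates"] is not None \
                    and "efa" in results:
                targets = derive_outcome_targets(
                    outcome_dvm, results["covariates"], seed=cfg.seed
                )
                pred_out = {"targets": targets}
                for cat, entry in results["efa"].items():
                    pred = predict_targets(
                        entry["scores"], targets["scores"],
                        model=cfg.prediction_model, k=cfg.k_folds,
                        n_perm=cfg.n_perm, seed=cfg.seed,
                    )
                    pred["summary"].to_csv(out / f"prediction_{cat}.csv")
                    pred["betas"].to_csv(out / f"fingerprints_{cat}.csv")
                    pred_out[cat] = pred
                results["prediction"] = pred_out
            else:
                logger.info("prediction stage skipped: no outcomes/covariates")
        except Exception as exc:
            raise StageError(stage, exc)
        manifest["stages_run"].append(stage)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    results["manifest"] = manifest
    return results
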