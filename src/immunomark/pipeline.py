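"""End-to-end orchestration: simulate -> qc -> features -> train -> score -> evaluate.

A single YAML-able config drives the run; every stochastic stage derives
its seed from the one top-level seed, so re-running a config reproduces
all numeric outputs bitwise.  Each stage appends its artifacts to the run
directory and the run closes with a machine-readable ``summary.json``
stamped with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, features as feat, io as fio, model as mdl, qc, scoring, synthetic

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "run",
    # either simulate a cohort ...
    "cohort": {},            # CohortSpec overrides; {} = study-like defaults
    "simulate_expression": False,
    # ... or point at files (genes x samples TSV/MTX, GMT, clinical TSV)
    "expression": None,
    "gene_sets": None,
    "clinical": None,
    "feature_table": None,
    "qc": {"thresholds": None, "staleness_fraction": 0.10},
    "replicates": {"n_biological": 6, "n_replicates": 9, "technical_sd": 0.1},
    "train": {
        "C_grid": [0.03125, 1.0, 32.0],
        "k_max": 5,
        "cv_folds": 5,
        "auc_floor": 0.76,
        "variability_ceiling": 20.0,
    },
    "score": {"B": 1000, "threshold": None},
    "evaluate": {"comparator_column": "cps", "comparator_threshold": 20},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict | None) -> dict:
    """Merge over defaults and check types/paths before any compute."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if not isinstance(cfg["seed"], int):
        raise ValueError("config.seed must be an integer (mandatory for reproducibility)")
    if cfg["score"]["B"] < 1:
        raise ValueError("config.score.B must be >= 1")
    for key in ("expression", "gene_sets", "clinical", "feature_table"):
        if cfg[key] is not None and not Path(cfg[key]).exists():
            raise ValueError(f"config.{key}: path does not exist: {cfg[key]}")
    if cfg["feature_table"] is None and cfg["expression"] is None and cfg["cohort"] is None:
        raise ValueError("config must supply a cohort spec, a feature table, or expression data")
    if cfg["expression"] is not None and cfg["clinical"] is None:
        raise ValueError("config.clinical is required with file-based expression input")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage(summary: dict, name: str, t0: float, **info):
    entry = {"stage": name, "wall_s": round(time.perf_counter() - t0, 3), **info}
    summary["stages"].append(entry)
    logger.info("stage %s: %s", name, entry)


def run_pipeline(config: dict | None = None) -> dict:
    """Run every stage in order; returns the summary dict (also written to disk).

    Stage failures abort with the stage name attached to the exception.
    """
    cfg = validate_config(config)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    summary: dict = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "stages": [],
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if cfg["feature_table"] is not None:
            fm = fio.read_table(cfg["feature_table"])
            clinical = fio.read_table(cfg["clinical"])
            stage_info = {"source": "feature_table", "n": len(fm)}
        elif cfg["expression"] is not None:
            counts = fio.read_expression(cfg["expression"])
            panel = fio.read_gmt(cfg["gene_sets"]) if cfg["gene_sets"] else feat.default_panel()
            clinical = fio.read_table(cfg["clinical"])
            norm = feat.normalize_expression(counts)
            fm, _ = feat.score_signatures(norm, panel)
            stage_info = {"source": "expression", "n": len(fm)}
        else:
            spec = synthetic.CohortSpec(**{**cfg["cohort"], "seed": cfg["cohort"].get("seed", seed)})
            fm, clinical = synthetic.generate_cohort(spec)
            weights = np.zeros(spec.n_features)
            weights[list(spec.informative_indices)] = spec.effect_sizes
            clinical["cps"] = synthetic.generate_comparator_marker(
                fm, weights, noise_sd=2.0 * float(np.linalg.norm(weights)), seed=seed + 3
            )
            if cfg["simulate_expression"]:
                expr, sets = synthetic.generate_expression_layer(fm, seed=seed + 2)
                fio.write_table(expr, outdir / "expression.tsv")
                fio.write_gmt(sets, outdir / "gene_sets.gmt")
            stage_info = {"source": "synthetic", "n": len(fm)}
        fio.write_table(fm, outdir / "features.tsv")
        fio.write_table(clinical, outdir / "clinical.tsv")
        _stage(summary, stage, t0, **stage_info)

        stage = "qc"
        t0 = time.perf_counter()
        qc_cols = set(qc.DEFAULT_THRESHOLDS)
        if qc_cols <= set(clinical.columns):
            records = clinical.reset_index().rename(columns={clinical.index.name or "index": "sample_id"})
            retained, log = qc.apply_sample_qc(records, cfg["qc"]["thresholds"])
            if "biopsy_to_treatment_months" in clinical.columns:
                kept_records = records[records["sample_id"].isin(retained)]
                retained, cutoff = qc.apply_staleness_filter(
                    kept_records, cfg["qc"]["staleness_fraction"]
                )
                summary["staleness_cutoff_months"] = cutoff
            fio.write_table(log, outdir / "qc_exclusions.tsv", index=False)
            fm, clinical = fm.loc[retained], clinical.loc[retained]
            _stage(summary, stage, t0, retained=len(retained), excluded=int(log["sample_id"].nunique()))
        else:
            _stage(summary, stage, t0, skipped="no QC metric columns present")

        stage = "assemble"
        t0 = time.perf_counter()
        joined, drop_report = feat.assemble_feature_matrix(fm, clinical)
        labels = joined["non_progressor"].to_numpy().astype(int)
        fm = joined[fm.columns]
        _stage(summary, stage, t0, n=len(joined), **{k: len(v) for k, v in drop_report.items()})

        stage = "train"
        t0 = time.perf_counter()
        tr = cfg["train"]
        candidates = mdl.build_candidates(
            fm, labels, C_grid=tr["C_grid"], k_max=tr["k_max"], seed=seed
        )
        rep_cfg = cfg["replicates"]
        rep_spec = synthetic.ReplicateSpec(
            n_biological=rep_cfg["n_biological"],
            n_replicates=rep_cfg["n_replicates"],
            technical_sd=rep_cfg["technical_sd"],
            seed=seed + 1,
        )
        replicates = synthetic.generate_replicates(fm.iloc[: rep_spec.n_biological], rep_spec)
        candidates = mdl._with_variability(candidates, replicates)
        cand_table = pd.DataFrame(
            {
                "features": ["|".join(m.features) for m in candidates],
                "C": [m.C for m in candidates],
                "cv_auc": [m.cv_auc for m in candidates],
                "variability_4std": [m.variability_4std for m in candidates],
                "feasible": [
                    m.cv_auc >= tr["auc_floor"] and m.variability_4std <= tr["variability_ceiling"]
                    for m in candidates
                ],
            }
        )
        fio.write_table(cand_table, outdir / "candidates.tsv", index=False)
        final = mdl.select_final_model(
            candidates, auc_floor=tr["auc_floor"], variability_ceiling=tr["variability_ceiling"]
        )
        fio.write_model(final, outdir / "model.yaml")
        summary["final_model"] = {
            "features": list(final.features),
            "C": final.C,
            "cv_auc": final.cv_auc,
            "variability_4std": final.variability_4std,
        }
        _stage(summary, stage, t0, n_candidates=len(candidates))

        stage = "score"
        t0 = time.perf_counter()
        sc = cfg["score"]
        score_set = scoring.bootstrap_oob_scores(
            fm, labels, final.features, final.C, B=sc["B"], seed=seed + 4
        )
        scoring.classify(score_set, threshold=sc["threshold"])
        scoring.assign_quartiles(score_set)
        fio.write_table(score_set.table.round({"score": 1}), outdir / "scores.tsv")
        summary["score"] = {
            "B": score_set.B,
            "threshold": score_set.threshold,
            "quartile_boundaries": list(score_set.quartile_boundaries),
            "redraws": score_set.redraws,
        }
        _stage(summary, stage, t0, n_scored=int(score_set.scores.notna().sum()))

        stage = "evaluate"
        t0 = time.perf_counter()
        pred = (score_set.table["predicted_class"] == "non-progressor").astype(int)
        cm = evaluation.confusion(pred, labels)
        metrics = evaluation.diagnostic_metrics(cm)
        auc, roc_curve = evaluation.roc_auc(score_set.scores.to_numpy(), labels)
        fio.write_table(roc_curve, outdir / "roc.tsv", index=False)
        fio.write_table(metrics.as_series().to_frame("value"), outdir / "metrics.tsv")
        (outdir / "metrics.json").write_text(json.dumps(metrics.as_series().to_dict(), indent=2))
        dcr = evaluation.group_rate(
            {
                "predicted_non_progressor": labels[pred.to_numpy() == 1],
                "predicted_progressor": labels[pred.to_numpy() == 0],
            }
        )
        fisher_p = evaluation.fisher_2x2([[cm.tp, cm.fp], [cm.fn, cm.tn]])
        qd = evaluation.quartile_dcr(score_set.table["quartile"].astype(int), labels)
        fio.write_table(qd, outdir / "quartile_dcr.tsv")
        surv = evaluation.km_logrank(
            joined["os_months"], joined["os_event"],
            np.where(pred == 1, "pred_non_progressor", "pred_progressor"),
        )
        for grp, curve in surv.curves.items():
            fio.write_table(curve, outdir / f"km_{grp}.tsv", index=False)
        cox = evaluation.cox_ph(
            joined["os_months"], joined["os_event"],
            pd.DataFrame({"predicted_non_progressor": pred.to_numpy()}),
        )
        fio.write_table(cox, outdir / "cox.tsv")
        summary["evaluation"] = {
            "oob_auc": auc,
            "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "dcr": {g: dcr.loc[g, "rate"] for g in dcr.index},
            "dcr_fisher_p": fisher_p,
            "km_medians": {str(k): v for k, v in surv.medians.items()},
            "logrank_p": surv.p_value,
            "cox_hr_non_progressor": float(cox["hr"].iloc[0]),
        }
        comp_col = cfg["evaluate"]["comparator_column"]
        if comp_col and comp_col in joined.columns:
            comp_pred = (joined[comp_col] >= cfg["evaluate"]["comparator_threshold"]).astype(int)
            comp = evaluation.compare_predictors(pred, comp_pred, labels)
            summary["evaluation"]["comparator"] = {
                "concordant": comp["concordant"],
                "auc": evaluation.roc_auc(joined[comp_col].to_numpy(), labels)[0],
                "sensitivity_fisher_p": comp["sensitivity_fisher_p"],
                "specificity_fisher_p": comp["specificity_fisher_p"],
            }
        _stage(summary, stage, t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def load_config(path) -> dict:
    return validate_config(yaml.safe_load(Path(path).read_text()) or {})
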