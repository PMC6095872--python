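"""End-to-end orchestration: preprocess/extract -> cluster -> associate -> classify.

A single config dict drives the whole run; every stage writes its artifacts
under one output directory and ``report.json`` indexes them together with the
seeds and settings used, so a rerun with the same config reproduces the same
numbers.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import association_report, cramers_v_test, zscore_table
from .classify import CLASSIFIER_MENU, dichotomize_outcomes, nested_cv_auc, tally_feature_importance
from .consensus import median_cluster_consensus, run_consensus, select_best_algorithm
from .features import ExtractionConfig, extract_cohort_features

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline"]

ORDERED_OUTCOMES = {
    "grade": "grade",
    "t_stage": "t_stage",
    "n_stage": "n_stage",
    "overall_stage": "overall_stage",
}
UNORDERED_OUTCOMES = {
    "subtype": "subtype",
    "recurrence_status": "recurrence_status",
    "recurrence_site": "recurrence_site",
    "histology": "histology",
}


def default_config(manifest: str, clinical: str, out_dir: str) -> dict:
    return {
        "manifest": manifest,
        "clinical": clinical,
        "out_dir": out_dir,
        "extraction": {},  # ExtractionConfig overrides
        "cluster": {
            "algorithms": ["HC_ward", "KM", "KMdist", "PAM"],
            "dissimilarities": ["euclidean", "one_minus_pearson", "one_minus_spearman"],
            "k_range": [2, 3, 4, 5, 6],
            "n_iter": 10_000,
            "subsample_frac": 0.8,
            "seed": 7,
        },
        "cv": {
            "tasks": ["rfs1", "rfs2", "rfs3", "rfs4", "rfs5", "grade"],
            "classifiers": ["ElasticNetLogReg", "L2LbfgsLogReg"],
            "reps": 1000,
            "outer_folds": 3,
            "inner_folds": 3,
            "seed": 11,
        },
    }


def _validate(config: dict) -> None:
    for key in ("manifest", "clinical"):
        if not Path(config[key]).exists():
            raise FileNotFoundError(f"config {key} file not found: {config[key]}")


def run_pipeline(config: dict) -> dict:
    """Run every stage and return the report dict (also written as JSON)."""
    _validate(config)
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config, "stages": {}}

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        return t0

    # ---- extract --------------------------------------------------------
    t0 = stage("extract")
    manifest = pd.read_csv(config["manifest"])
    clinical = pd.read_csv(config["clinical"]).set_index("tumor_id")
    extraction = ExtractionConfig(**config.get("extraction", {}))
    try:
        features = extract_cohort_features(manifest, extraction)
    except Exception as exc:
        raise RuntimeError(f"stage 'extract' failed: {exc}") from exc
    features.to_csv(out / "features.csv")
    (out / "extraction.json").write_text(
        json.dumps({**extraction.__dict__, "version": __version__}, indent=2)
    )
    report["stages"]["extract"] = {
        "n_tumors": len(features),
        "n_features": features.shape[1],
        "seconds": round(time.perf_counter() - t0, 2),
    }

    # ---- cluster --------------------------------------------------------
    t0 = stage("cluster")
    cc = config["cluster"]
    z, _ = zscore_table(features.dropna(axis=1, how="all"))
    runs, labels_per_run, summary = [], [], []
    for algorithm in cc["algorithms"]:
        for dissimilarity in cc["dissimilarities"]:
            run = run_consensus(
                z,
                algorithm,
                dissimilarity,
                k_range=cc["k_range"],
                n_iter=cc["n_iter"],
                subsample_frac=cc["subsample_frac"],
                seed=cc["seed"],
            )
            k = run.selected_k
            runs.append(run)
            labels_per_run.append(run.labels[k])
            summary.append(
                {
                    "algorithm": algorithm,
                    "dissimilarity": dissimilarity,
                    "selected_k": k,
                    "cdf_area": {str(kk): run.cdf_area[kk] for kk in run.k_range},
                    "delta_area": {str(kk): run.delta_area[kk] for kk in run.k_range},
                    "median_cluster_consensus": median_cluster_consensus(run, k),
                }
            )
    cluster_dir = out / "cluster"
    cluster_dir.mkdir(exist_ok=True)
    (cluster_dir / "consensus_report.json").write_text(json.dumps(summary, indent=2))
    labels_frame = pd.DataFrame(
        {
            f"{r.algorithm}|{r.dissimilarity}": lab
            for r, lab in zip(runs, labels_per_run)
        },
        index=features.index,
    )
    labels_frame.to_csv(cluster_dir / "labels.csv")
    for r in runs:
        np.savez_compressed(
            cluster_dir / f"consensus_{r.algorithm}_{r.dissimilarity}.npz",
            **{f"k{k}": m for k, m in r.consensus.items()},
        )
    report["stages"]["cluster"] = {
        "n_settings": len(runs),
        "seconds": round(time.perf_counter() - t0, 2),
    }

    # ---- associate ------------------------------------------------------
    t0 = stage("associate")
    clinical = clinical.loc[features.index]
    per_outcome = []
    for name, col in {**ORDERED_OUTCOMES, **UNORDERED_OUTCOMES}.items():
        if col not in clinical.columns or clinical[col].dropna().nunique() < 2:
            continue
        best, v = select_best_algorithm(runs, labels_per_run, clinical[col])
        chi2, p, dof, _ = cramers_v_test(
            labels_per_run[runs.index(best)], clinical[col]
        )
        per_outcome.append(
            {
                "outcome": name,
                "algorithm": f"{best.algorithm}|{best.dissimilarity}",
                "n": int(clinical[col].notna().sum()),
                "chi2": chi2,
                "p": p,
                "dof": dof,
                "cramers_v": v,
                "median_cc": median_cluster_consensus(best, best.selected_k),
            }
        )
    assoc_dir = out / "assoc"
    assoc_dir.mkdir(exist_ok=True)
    first_labels = labels_per_run[0]
    assoc = association_report(
        z,
        clinical,
        first_labels,
        {k: v for k, v in ORDERED_OUTCOMES.items() if v in clinical.columns},
        {k: v for k, v in UNORDERED_OUTCOMES.items() if v in clinical.columns},
    )
    assoc["spearman_rho"].to_csv(assoc_dir / "spearman_rho.csv")
    assoc["r2_mreg"].to_csv(assoc_dir / "r2_mreg.csv")
    (assoc_dir / "cluster_association.json").write_text(json.dumps(per_outcome, indent=2))
    report["stages"]["associate"] = {
        "outcomes": [r["outcome"] for r in per_outcome],
        "seconds": round(time.perf_counter() - t0, 2),
    }

    # ---- classify -------------------------------------------------------
    t0 = stage("classify")
    cv = config["cv"]
    cv_dir = out / "cv"
    cv_dir.mkdir(exist_ok=True)
    auc_grid = []
    for task in cv["tasks"]:
        y = dichotomize_outcomes(clinical, task)
        if y.nunique() < 2:
            logger.warning("task %s degenerate; skipped", task)
            continue
        for cid in cv["classifiers"]:
            spec = CLASSIFIER_MENU[cid]
            result = nested_cv_auc(
                features.loc[y.index],
                y,
                spec,
                outer_folds=cv["outer_folds"],
                inner_folds=cv["inner_folds"],
                reps=cv["reps"],
                seed=cv["seed"],
            )
            entry = {
                "task": task,
                "classifier": cid,
                "mean_auc": result.mean_auc,
                "ci95": list(result.ci95),
                "max_cv_count": result.max_cv_count,
            }
            auc_grid.append(entry)
            (cv_dir / f"{task}_{cid}.json").write_text(
                json.dumps({**entry, "aucs": result.aucs.tolist()}, indent=2)
            )
            if result.has_coefficients:
                tally_feature_importance(result, top=len(result.tallies)).to_csv(
                    cv_dir / f"{task}_{cid}_importance.csv"
                )
    report["stages"]["classify"] = {
        "auc_grid": auc_grid,
        "seconds": round(time.perf_counter() - t0, 2),
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
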