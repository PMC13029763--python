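"""End-to-end orchestration: synth → curate → dedup → split → train → screen.

One config object drives the whole run; every random draw is seeded from it,
so rerunning an identical config reproduces byte-identical CSV outputs. The
stage functions all live in their own modules — this file only wires them
together and writes artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import CurationConfig, curate
from .domain import similarity_to_reference
from .features import DEFAULT_FP_PARAMS, FingerprintParams, compute_descriptors, fingerprint_matrix, murcko_scaffold
from .modeling import (
    ModelConfig,
    aggregate_seeds,
    calibrate,
    evaluate,
    oof_predict,
    select_threshold,
    threshold_metrics,
    tune_and_fit,
)
from .screening import ad_annotate, butina_select, ensemble_score, select_top
from .splitting import assign_split, group_by_scaffold, summarize_split
from .structures import (
    audit_structures,
    deduplicate_structures,
    prepare_screening_library,
    sha256_file,
)
from .synth import SyntheticSpec, generate_activity_table, generate_screening_library

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full pipeline run depends on."""

    spec: SyntheticSpec = field(default_factory=SyntheticSpec)
    curation: CurationConfig = field(default_factory=CurationConfig)
    fp_params: FingerprintParams = DEFAULT_FP_PARAMS
    families: tuple[str, ...] = ("random_forest",)
    n_iter: int = 25
    cv_folds: int = 5
    seeds: tuple[int, ...] = (1, 2, 3)
    top_n: int = 200
    shortlist_n: int = 20
    butina_cutoff: float = 0.35


def _prepare_modeling_table(config: PipelineConfig):
    activity, truth = generate_activity_table(config.spec)
    compounds, rejections = curate(activity, config.curation)
    canonical, structure_audit = audit_structures(compounds["smiles"], keep_largest=True)
    valid = compounds.loc[canonical.index].copy()
    valid["canonical_smiles"] = canonical
    valid = valid.rename(columns={"pactivity": "pic50"})
    dedup, dedup_audit = deduplicate_structures(valid)
    dedup["scaffold"] = [murcko_scaffold(s) for s in dedup["canonical_smiles"]]
    desc = pd.DataFrame([compute_descriptors(s).to_dict() for s in dedup["canonical_smiles"]])
    dedup = pd.concat([dedup.reset_index(drop=True), desc], axis=1)
    return activity, truth, compounds, rejections, structure_audit, dedup, dedup_audit


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis; optionally write all artifacts under ``out_dir``.

    Returns a dict of in-memory results: the deduplicated modeling table,
    per-seed split frames, tuned models, the evaluation/aggregate tables,
    the annotated screening scores, top subset, clusters, and shortlist.
    """
    (
        activity,
        truth,
        compounds,
        rejections,
        structure_audit,
        dedup,
        dedup_audit,
    ) = _prepare_modeling_table(config)

    groups = group_by_scaffold(dedup)
    fps = fingerprint_matrix(dedup["canonical_smiles"], config.fp_params)
    labels = dedup["label"].to_numpy(int)

    splits = {}
    models: dict[str, dict[int, object]] = {f: {} for f in config.families}
    eval_rows = []
    predictions = []
    summaries = []
    calibrations = {}
    thresholds = {}
    for seed in config.seeds:
        split = assign_split(groups, seed=seed)
        frame = dedup.copy()
        frame["subset"] = frame["compound_id"].map(split.assignments)
        frame["seed"] = seed
        splits[seed] = frame
        summaries.append(summarize_split(split, dedup))
        trainval = frame["subset"].isin(["train", "val"]).to_numpy()
        test = (frame["subset"] == "test").to_numpy()
        for family in config.families:
            mc = ModelConfig(
                family=family, n_iter=config.n_iter, cv_folds=config.cv_folds, seed=seed
            )
            tuned = tune_and_fit(fps[trainval], labels[trainval], mc)
            models[family][seed] = tuned
            oof = oof_predict(fps[trainval], labels[trainval], tuned)
            test_probs = tuned.model.predict_proba(fps[test])[:, 1]
            oof_eval = evaluate(oof, labels[trainval])
            test_eval = evaluate(test_probs, labels[test])
            sel = select_threshold(oof, labels[trainval], criterion="mcc")
            thresholds[(family, seed)] = {
                **sel,
                "test": threshold_metrics(test_probs, labels[test], sel["threshold"]),
            }
            calibrations[(family, seed)] = {
                "oof": calibrate(oof, labels[trainval]),
                "test": calibrate(test_probs, labels[test]),
            }
            eval_rows.append(
                {
                    "model": family,
                    "seed": seed,
                    "oof_auc": oof_eval["auc"],
                    "oof_ap": oof_eval["ap"],
                    "test_auc": test_eval["auc"],
                    "test_ap": test_eval["ap"],
                    "test_mcc": test_eval["mcc"],
                    "test_balanced_accuracy": test_eval["balanced_accuracy"],
                    "best_cv_auc": tuned.best_cv_auc,
                }
            )
            pred = frame.loc[test, ["compound_id", "subset", "label"]].copy()
            pred["probability"] = test_probs
            pred["seed"] = seed
            pred["model"] = family
            predictions.append(pred)
    evaluations = pd.DataFrame(eval_rows)
    aggregate = aggregate_seeds(evaluations)
    best_family = aggregate.iloc[0]["model"]

    # --- screening against the synthetic library -------------------------
    raw_library = generate_screening_library(config.spec)
    library, lib_dropped = prepare_screening_library(raw_library, id_col="id", name_col="name")
    # screening featurization re-reads the training parameter echo and must match
    echo = FingerprintParams(**json.loads(json.dumps(config.fp_params.to_dict())))
    if echo.config_hash() != config.fp_params.config_hash():
        raise ValueError("screening fingerprint parameters diverge from training echo")
    lib_fps = fingerprint_matrix(library["canonical_smiles"], echo)
    seed_models = [models[best_family][s].model for s in config.seeds]
    scores = ensemble_score(seed_models, lib_fps, library["public_id"])
    ref_seed = config.seeds[0]
    ref_mask = splits[ref_seed]["subset"].isin(["train", "val"]).to_numpy()
    scores, ad_counts = ad_annotate(
        scores, lib_fps, fps[ref_mask], library["public_id"]
    )
    top = select_top(scores, n=config.top_n)
    candidates = top[top["in_domain"]].reset_index(drop=True)
    if candidates.empty:
        candidates = top
    id_to_row = {pid: i for i, pid in enumerate(library["public_id"])}
    cand_fps = lib_fps[[id_to_row[p] for p in candidates["public_id"]]]
    clusters, shortlist = butina_select(
        cand_fps, candidates, cutoff=config.butina_cutoff, shortlist_n=config.shortlist_n
    )

    results = {
        "activity": activity,
        "ground_truth": truth,
        "compounds": compounds,
        "rejections": rejections,
        "structure_audit": structure_audit,
        "dedup": dedup,
        "dedup_audit": dedup_audit,
        "fingerprints": fps,
        "splits": splits,
        "split_summaries": pd.concat(summaries, ignore_index=True),
        "models": models,
        "evaluations": evaluations,
        "aggregate": aggregate,
        "best_family": best_family,
        "thresholds": thresholds,
        "calibrations": calibrations,
        "predictions": pd.concat(predictions, ignore_index=True),
        "library": library,
        "library_fps": lib_fps,
        "scores": scores,
        "ad_counts": ad_counts,
        "top": top,
        "clusters": clusters,
        "shortlist": shortlist,
    }
    if out_dir is not None:
        _write_outputs(config, results, Path(out_dir))
    return results


def _write_outputs(config: PipelineConfig, results: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    csv_artifacts = {
        "activity.csv": results["activity"],
        "ground_truth.csv": results["ground_truth"],
        "compounds.csv": results["compounds"],
        "rejections.csv": results["rejections"],
        "structure_audit.csv": results["structure_audit"],
        "dedup.csv": results["dedup"],
        "split_summaries.csv": results["split_summaries"],
        "evaluations.csv": results["evaluations"],
        "aggregate.csv": results["aggregate"],
        "predictions.csv": results["predictions"],
        "library.csv": results["library"],
        "screen_scores.csv": results["scores"],
        "top.csv": results["top"],
        "shortlist.csv": results["shortlist"],
    }
    for seed, frame in results["splits"].items():
        csv_artifacts[f"split_seed{seed}.csv"] = frame.drop(columns=[], errors="ignore")
    for name, frame in csv_artifacts.items():
        frame.to_csv(out / name, index=False)
    (out / "dedup_audit.json").write_text(
        json.dumps(results["dedup_audit"], indent=2, sort_keys=True) + "\n"
    )
    clusters_payload = [
        {
            "cluster_id": c.cluster_id,
            "centroid_id": c.centroid_id,
            "member_ids": c.member_ids,
            "representative_id": c.representative_id,
        }
        for c in results["clusters"]
    ]
    (out / "clusters.json").write_text(json.dumps(clusters_payload, indent=2) + "\n")
    (out / "fingerprint_params.json").write_text(
        json.dumps(
            {**config.fp_params.to_dict(), "config_hash": config.fp_params.config_hash()},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    manifest = {name: sha256_file(out / name) for name in sorted(csv_artifacts)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
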