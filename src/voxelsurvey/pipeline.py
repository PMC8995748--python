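"""End-to-end pipeline: simulate -> prep -> bounds -> select -> compare.

Every stage writes its artifacts under one run directory, and a
``manifest.json`` records the config echo, package version, seeds and
timestamps.  Re-running with an identical config reproduces every numeric
output byte-for-byte (the manifest's timestamps aside).  A stage failure
aborts with the stage named; artifacts of completed stages are retained.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import generate_cohort, load_cohort, save_cohort
from .compare import compare_models
from .config import RunConfig
from .prep import assemble_feature_matrix, build_voxel_pairs, compute_group_matrices
from .similarity import block_similarity, feature_count_bounds
from .survey import RandomSurveySVM, split_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _float_fmt(x) -> str:
    return "" if x is None else format(float(x), ".10g")


def full_run(config: RunConfig) -> Path:
    """Execute all stages and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done = []
    started = datetime.now(timezone.utc).isoformat()

    def stage(name):
        logger.info("stage: %s", name)
        stages_done.append(name)

    try:
        # ---- simulate / load -------------------------------------------
        stage("simulate")
        if config.cohort_path is not None:
            cohort_dir = Path(config.cohort_path)
            if not cohort_dir.exists():
                raise FileNotFoundError(f"cohort path does not exist: {cohort_dir}")
            cohort = load_cohort(cohort_dir)
        else:
            cohort = generate_cohort(
                n_disease=config.n_disease,
                n_control=config.n_control,
                dims=config.dims,
                n_informative=config.n_informative,
                effect_size=config.effect_size,
                noise_sd=config.noise_sd,
                seed=config.cohort_seed,
                baseline_smoothness=config.baseline_smoothness,
                informative_layout=config.informative_layout,
            )
            save_cohort(cohort, out / "cohort")

        # ---- prep --------------------------------------------------------
        stage("prep")
        M, N = compute_group_matrices(cohort)
        pairs = build_voxel_pairs(M, N, tol=config.tol)
        if len(pairs) < 2:
            raise ValueError("fewer than 2 retained voxels after equal-voxel deletion")
        pairs.to_frame().to_csv(out / "pairs.tsv", sep="\t", index=False,
                                float_format="%.10g")
        features = assemble_feature_matrix(cohort, pairs)

        # ---- bounds ------------------------------------------------------
        stage("bounds")
        g = min(config.g, len(pairs))
        blocks = block_similarity(pairs, g=g)
        bounds = feature_count_bounds(blocks, extremum_tol=config.extremum_tol)
        (out / "bounds.json").write_text(json.dumps({
            "c_max": bounds.c_max,
            "c_min": bounds.c_min,
            "extremum_tol": bounds.extremum_tol,
            "g": g,
            "n_retained": len(pairs),
            "n_deleted": pairs.n_deleted,
            "note": "c_min/c_max count voxel rows tied at the global "
                    "similarity extrema (self-pairs excluded)",
        }, indent=2))

        # ---- select (RS-SVM) --------------------------------------------
        stage("select")
        truth_index = None
        if cohort.truth_mask is not None:
            truth_index = np.flatnonzero(cohort.truth_mask.ravel(order="C"))
        model = RandomSurveySVM(
            features, bounds=bounds, n_surveys=config.n_surveys,
            truth_mask_index=truth_index,
        )
        split = split_dataset(features.n_subjects, features.y,
                              ratios=config.ratios, seed=config.split_seed)
        results = model.fit(split=split, survey_seed=config.survey_seed)
        result_payload = {
            "R_columns": results.selected_columns.tolist(),
            "R_voxel_linear_index": results.selected_voxels.tolist(),
            "l": int(results.best.survey.l),
            "params": {
                "kernel": results.best_params.kernel,
                "C": results.best_params.C,
                "gamma": results.best_params.gamma,
            },
            "val_metrics": results.val_metrics.as_dict(),
            "test_metrics": results.test_metrics.as_dict(),
            "test_auc": results.roc().auc,
            "seeds": {"split": config.split_seed, "survey": config.survey_seed},
            "positive_class": "+1 (control)",
        }
        if truth_index is not None:
            result_payload["planted_recovery"] = results.planted_recovery()
        (out / "result.json").write_text(json.dumps(result_payload, indent=2))
        results.history_frame().to_csv(out / "history.tsv", sep="\t", index=False,
                                       float_format="%.10g")

        # ---- compare -----------------------------------------------------
        stage("evaluate")
        report = compare_models(
            features, bounds,
            model_list=config.models,
            n_repetitions=config.n_repetitions,
            seed=config.split_seed,
            columns=config.baseline_columns,
            n_surveys=config.n_surveys,
        )
        metrics_df = report.metrics_frame()
        metrics_df.to_csv(out / "metrics.tsv", sep="\t", index=False,
                          float_format="%.10g")
        report.roc_frame().to_csv(out / "roc.tsv", sep="\t", index=False,
                                  float_format="%.10g")
        report.accuracy_curves().to_csv(out / "accuracy_curves.tsv", sep="\t",
                                        float_format="%.10g")
        auc_payload = {
            model: report.auc_table().query("model == @model")["auc"].tolist()
            for model in report.models
        }
        (out / "auc.json").write_text(json.dumps(auc_payload, indent=2))
        models_payload = [
            {"model": rec.model, "repetition": rec.repetition,
             "params": {k: v for k, v in rec.params.items()},
             "n_features": rec.n_features,
             "val_accuracy": rec.val_metrics.accuracy,
             "test_accuracy": rec.test_metrics.accuracy}
            for rec in report.records
        ]
        (out / "models.json").write_text(json.dumps(models_payload, indent=2))
    except Exception as exc:
        raise StageError(
            f"pipeline failed in stage '{stages_done[-1] if stages_done else 'init'}': {exc}"
        ) from exc

    manifest = {
        "package": "voxelsurvey",
        "version": __version__,
        "config": config.to_dict(),
        "seeds": {
            "cohort": config.cohort_seed,
            "split": config.split_seed,
            "survey": config.survey_seed,
        },
        "stages": stages_done,
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
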