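"""Repeated-experiment comparison of RS-SVM against the four baselines.

Each repetition draws a fresh stratified 6:2:2 split, runs the RS-SVM
survey loop to select a feature set R, then tunes and evaluates every
requested model.  Baselines see either the selected columns R (default,
"do the selected features carry the signal?") or all retained voxels.
The report carries per-model accuracy curves across repetitions, metric
tables for the validation and test splits, test-split ROC curves, and the
max-min accuracy spread per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import BASELINE_KINDS, tune_baseline
from .metrics import MetricsReport, RocCurve, evaluate_predictions, roc_auc
from .prep import FeatureMatrix
from .similarity import FeatureBounds
from .survey import DEFAULT_N_SURVEYS, run_rs_svm, split_dataset

ALL_MODELS = ("linear", "lasso", "pls", "svm", "rs-svm")


@dataclass
class RepetitionRecord:
    """One repetition's outcome for one model."""

    repetition: int
    model: str
    val_metrics: MetricsReport
    test_metrics: MetricsReport
    roc: RocCurve
    params: dict = field(default_factory=dict)
    n_features: int = 0


@dataclass
class ComparisonReport:
    """All repetitions x models, plus seeds for provenance."""

    records: list[RepetitionRecord]
    n_repetitions: int
    models: tuple[str, ...]
    split_seeds: list[int]
    survey_seed: int
    columns_mode: str

    def metrics_frame(self) -> pd.DataFrame:
        """Tidy table (model, repetition, split, accuracy, ...)."""
        rows = []
        for rec in self.records:
            for split_name, m in (("validation", rec.val_metrics),
                                  ("test", rec.test_metrics)):
                rows.append({
                    "model": rec.model,
                    "repetition": rec.repetition,
                    "split": split_name,
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f_measure": m.f_measure,
                    "n_features": rec.n_features,
                })
        return pd.DataFrame(rows)

    def accuracy_curves(self) -> pd.DataFrame:
        """Test accuracy per (repetition, model) — the stability view."""
        df = self.metrics_frame()
        df = df[df["split"] == "test"]
        return df.pivot(index="repetition", columns="model", values="accuracy")

    def accuracy_spread(self) -> pd.Series:
        """max - min test accuracy across repetitions, per model."""
        curves = self.accuracy_curves()
        return curves.max() - curves.min()

    def roc_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for fpr, tpr in zip(rec.roc.fpr, rec.roc.tpr):
                rows.append({"model": rec.model, "repetition": rec.repetition,
                             "fpr": fpr, "tpr": tpr})
        return pd.DataFrame(rows)

    def auc_table(self) -> pd.DataFrame:
        rows = [{"model": rec.model, "repetition": rec.repetition,
                 "auc": rec.roc.auc} for rec in self.records]
        return pd.DataFrame(rows)


def compare_models(
    features: FeatureMatrix,
    bounds: FeatureBounds,
    model_list: tuple[str, ...] = ALL_MODELS,
    n_repetitions: int = 10,
    seed: int = 0,
    columns: str = "selected",
    n_surveys: int = DEFAULT_N_SURVEYS,
    grid=None,
    baseline_grids: dict | None = None,
) -> ComparisonReport:
    """Run the five-model comparison over repeated fresh splits.

    Parameters
    ----------
    columns : {"selected", "all"}
        Feature columns handed to the baselines: the RS-SVM-selected set R
        of the same repetition, or every retained voxel.
    seed : int
        Base seed; repetition i uses split seed ``seed + i`` and the survey
        loop uses seed ``seed + 10_000 + i``.
    """
    unknown = set(model_list) - set(ALL_MODELS)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    if n_repetitions < 1:
        raise ValueError(f"n_repetitions must be >= 1, got {n_repetitions}")
    if columns not in ("selected", "all"):
        raise ValueError(f"columns must be 'selected' or 'all', got {columns!r}")
    needs_selection = columns == "selected" or "rs-svm" in model_list

    records: list[RepetitionRecord] = []
    split_seeds = []
    for rep in range(n_repetitions):
        split_seed = seed + rep
        survey_seed = seed + 10_000 + rep
        split_seeds.append(split_seed)
        split = split_dataset(features.n_subjects, features.y, seed=split_seed)
        ytr = features.y[split.train_idx]
        yva = features.y[split.val_idx]
        yte = features.y[split.test_idx]

        selected = None
        if needs_selection:
            best, _ = run_rs_svm(features, bounds, split,
                                 n_surveys=n_surveys, seed=survey_seed, grid=grid)
            selected = best.survey.r
            if "rs-svm" in model_list:
                records.append(RepetitionRecord(
                    repetition=rep,
                    model="rs-svm",
                    val_metrics=best.val_metrics,
                    test_metrics=best.test_metrics,
                    roc=roc_auc(best.test_scores, yte),
                    params={"kernel": best.best_params.kernel,
                            "C": best.best_params.C,
                            "gamma": best.best_params.gamma},
                    n_features=best.survey.l,
                ))

        cols = selected if columns == "selected" else np.arange(features.n_features)
        Xtr, Xva, Xte = (features.X[idx][:, cols] for idx in
                         (split.train_idx, split.val_idx, split.test_idx))
        for kind in model_list:
            if kind == "rs-svm":
                continue
            bl_grid = (baseline_grids or {}).get(kind)
            model, params, val_report = tune_baseline(
                kind, Xtr, ytr, Xva, yva, grid=bl_grid
            )
            test_report = evaluate_predictions(yte, model.predict(Xte))
            records.append(RepetitionRecord(
                repetition=rep,
                model=kind,
                val_metrics=val_report,
                test_metrics=test_report,
                roc=roc_auc(model.decision_scores(Xte), yte),
                params=params,
                n_features=len(cols),
            ))

    return ComparisonReport(
        records=records,
        n_repetitions=n_repetitions,
        models=tuple(model_list),
        split_seeds=split_seeds,
        survey_seed=seed + 10_000,
        columns_mode=columns,
    )


# ---------------------------------------------------------------------------
# Plot helpers (matplotlib imported lazily so headless pipelines stay light)


def plot_accuracy_curves(report: ComparisonReport, ax=None):
    """Per-model test accuracy across repetitions (stability plot)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    curves = report.accuracy_curves()
    for model in curves.columns:
        ax.plot(curves.index + 1, curves[model], marker="o", label=model)
    ax.set_xlabel("repetition")
    ax.set_ylabel("test accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax


def plot_roc_curves(report: ComparisonReport, repetition: int = 0, ax=None):
    """Test-split ROC curves of one repetition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for rec in report.records:
        if rec.repetition != repetition:
            continue
        ax.plot(rec.roc.fpr, rec.roc.tpr, label=f"{rec.model} (AUC={rec.roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    return ax
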