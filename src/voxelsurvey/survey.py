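"""Random-survey SVM (RS-SVM): feature selection by repeated random surveys.

The feature space of a voxel-based morphometry study is far wider than the
cohort (tens of thousands of voxels for a few hundred subjects).  RS-SVM
selects a compact feature set by repeatedly drawing a random "survey" — a
set R of l distinct voxel columns, with l drawn uniformly from the
similarity-derived interval [C_max, C_min] — fitting a grid-search-tuned
soft-margin SVM on the training split restricted to R, and scoring it on
the validation split.  The survey with the best validation accuracy
provides the final feature set; the untouched test split measures its
generalization.

Subjects are split 6:2:2 into train/validation/test, stratified by group.
One fixed split is used for all surveys of a run.

The model-object surface follows the statsmodels convention: build a
:class:`RandomSurveySVM` from data, call :meth:`~RandomSurveySVM.fit`, and
read estimates and diagnostics off the returned
:class:`RandomSurveySVMResults` (``summary()`` prints the survey table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import GmdCohort
from .metrics import MetricsReport, RocCurve, evaluate_predictions, roc_auc
from .prep import (FeatureMatrix, assemble_feature_matrix,
                   build_voxel_pairs, compute_group_matrices, DEFAULT_TOL)
from .similarity import FeatureBounds, block_similarity, feature_count_bounds
from .svm import GridPoint, SvmModel, default_grid, grid_search

DEFAULT_N_SURVEYS = 200
DEFAULT_RATIOS = (6, 2, 2)


@dataclass(frozen=True)
class Survey:
    """One random draw of feature columns (the index set R)."""

    r: np.ndarray  # sorted distinct column positions
    seed_state: str = ""

    @property
    def l(self) -> int:  # noqa: E743 - the field's name for the survey size
        return len(self.r)


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint, exhaustive train/validation/test subject indices."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    ratios: tuple[int, int, int] = DEFAULT_RATIOS
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        parts = [set(self.train_idx), set(self.val_idx), set(self.test_idx)]
        n = sum(len(p) for p in parts)
        if len(set().union(*parts)) != n:
            raise ValueError("split parts are not disjoint")


def draw_survey(n_columns: int, bounds: FeatureBounds, rng: np.random.Generator) -> Survey:
    """Draw a survey: l ~ Uniform{c_max..c_min}, then l distinct columns."""
    if bounds.c_min > n_columns:
        raise ValueError(
            f"c_min ({bounds.c_min}) exceeds the number of columns ({n_columns})"
        )
    l = int(rng.integers(bounds.c_max, bounds.c_min + 1))
    r = np.sort(rng.choice(n_columns, size=l, replace=False))
    return Survey(r=r)


def split_dataset(
    n_subjects: int,
    y,
    ratios: tuple[int, int, int] = DEFAULT_RATIOS,
    seed: int = 0,
    stratified: bool = True,
) -> SplitSpec:
    """Seeded 6:2:2 train/validation/test split, stratified by class.

    Within each class the shuffled subjects are allocated by the floor
    proportions; remainder subjects go train-first (train, val, test, ...).
    """
    y = np.asarray(y)
    if n_subjects != len(y):
        raise ValueError("n_subjects and len(y) differ")
    if n_subjects < 5:
        raise ValueError(f"need at least 5 subjects to split 6:2:2, got {n_subjects}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to split")
    ratios = tuple(int(r) for r in ratios)
    total = sum(ratios)
    rng = np.random.default_rng(seed)

    buckets = ([], [], [])
    groups = [np.flatnonzero(y == c) for c in np.unique(y)] if stratified \
        else [np.arange(n_subjects)]
    for idx in groups:
        idx = rng.permutation(idx)
        counts = [len(idx) * r // total for r in ratios]
        rem = len(idx) - sum(counts)
        for k in range(rem):  # train-first remainder assignment
            counts[k % 3] += 1
        pos = 0
        for b, c in zip(buckets, counts):
            b.extend(idx[pos:pos + c])
            pos += c
    return SplitSpec(
        train_idx=np.sort(np.array(buckets[0], dtype=int)),
        val_idx=np.sort(np.array(buckets[1], dtype=int)),
        test_idx=np.sort(np.array(buckets[2], dtype=int)),
        ratios=ratios,
        seed=seed,
        stratified=stratified,
    )


@dataclass
class SurveyResult:
    """Outcome of one survey: the draw, tuned parameters and split metrics."""

    survey: Survey
    best_params: GridPoint
    val_metrics: MetricsReport
    test_metrics: MetricsReport
    accepted: bool = False
    model: SvmModel | None = None
    test_scores: np.ndarray | None = None


def run_rs_svm(
    features: FeatureMatrix,
    bounds: FeatureBounds,
    split: SplitSpec,
    n_surveys: int = DEFAULT_N_SURVEYS,
    seed: int = 0,
    grid: list[GridPoint] | None = None,
) -> tuple[SurveyResult, list[SurveyResult]]:
    """The RS-SVM loop: draw surveys, tune, validate, keep the best.

    "Best" is the survey with the highest validation accuracy; ties are
    broken toward the smaller survey, then the earlier draw.  The tuned
    model of every survey is also evaluated once on the test split so the
    history carries an unbiased generalization estimate per survey.
    """
    if n_surveys < 1:
        raise ValueError(f"n_surveys must be >= 1, got {n_surveys}")
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    Xtr, ytr = features.X[split.train_idx], features.y[split.train_idx]
    Xva, yva = features.X[split.val_idx], features.y[split.val_idx]
    Xte, yte = features.X[split.test_idx], features.y[split.test_idx]

    history: list[SurveyResult] = []
    best: SurveyResult | None = None
    for k in range(n_surveys):
        survey = draw_survey(features.n_features, bounds, rng)
        cols = survey.r
        params, val_report, model = grid_search(
            Xtr[:, cols], ytr, Xva[:, cols], yva, grid=grid
        )
        test_scores = model.decision_scores(Xte[:, cols])
        test_report = evaluate_predictions(yte, model.predict(Xte[:, cols]))
        result = SurveyResult(
            survey=survey,
            best_params=params,
            val_metrics=val_report,
            test_metrics=test_report,
            model=model,
            test_scores=test_scores,
        )
        history.append(result)
        if (
            best is None
            or result.val_metrics.accuracy > best.val_metrics.accuracy
            or (
                result.val_metrics.accuracy == best.val_metrics.accuracy
                and result.survey.l < best.survey.l
            )
        ):
            best = result
    best.accepted = True
    # history entries other than the winner drop their fitted models to keep
    # a 200-survey run lightweight
    for res in history:
        if res is not best:
            res.model = None
    return best, history


# ---------------------------------------------------------------------------
# Model/Results surface


class RandomSurveySVM:
    """Random-survey SVM model over a subjects x voxels feature matrix.

    Parameters
    ----------
    features : FeatureMatrix
        Subject densities at retained voxels, labels in {-1, +1}.
    bounds : FeatureBounds, optional
        Survey-size interval; computed from the voxel similarities
        (``g`` blocks) when omitted.
    n_surveys : int
        Number of random surveys per fit.
    grid : list of GridPoint, optional
        Hyperparameter grid; the package default when omitted.
    g : int
        Block count for the similarity partition when bounds are computed
        here.
    truth_mask_index : ndarray, optional
        Linear indices of planted informative voxels (synthetic cohorts),
        enabling recovery diagnostics on the results object.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        bounds: FeatureBounds | None = None,
        n_surveys: int = DEFAULT_N_SURVEYS,
        grid: list[GridPoint] | None = None,
        g: int = 10,
        truth_mask_index: np.ndarray | None = None,
    ):
        self.features = features
        self.n_surveys = n_surveys
        self.grid = grid
        self.g = g
        self.truth_mask_index = truth_mask_index
        self._pairs = None
        if bounds is None:
            raise ValueError(
                "bounds is required when constructing from a FeatureMatrix; "
                "use from_cohort() to derive bounds from the data"
            )
        self.bounds = bounds

    @classmethod
    def from_cohort(
        cls,
        cohort: GmdCohort,
        tol: float = DEFAULT_TOL,
        g: int = 10,
        n_surveys: int = DEFAULT_N_SURVEYS,
        grid: list[GridPoint] | None = None,
        weights: np.ndarray | None = None,
    ) -> "RandomSurveySVM":
        """Build the model from a cohort: group summaries, equal-voxel
        deletion, feature assembly and similarity-derived bounds."""
        M, N = compute_group_matrices(cohort, weights=weights)
        pairs = build_voxel_pairs(M, N, tol=tol)
        if len(pairs) < 2:
            raise ValueError("fewer than 2 retained voxels; nothing to survey")
        features = assemble_feature_matrix(cohort, pairs)
        blocks = block_similarity(pairs, g=min(g, len(pairs)))
        bounds = feature_count_bounds(blocks)
        truth_index = None
        if cohort.truth_mask is not None:
            truth_index = np.flatnonzero(cohort.truth_mask.ravel(order="C"))
        model = cls(
            features,
            bounds=bounds,
            n_surveys=n_surveys,
            grid=grid,
            g=g,
            truth_mask_index=truth_index,
        )
        model._pairs = pairs
        return model

    def fit(self, split_seed: int = 0, survey_seed: int = 0,
            split: SplitSpec | None = None) -> "RandomSurveySVMResults":
        """Run the survey loop and return the results object."""
        if split is None:
            split = split_dataset(
                self.features.n_subjects, self.features.y, seed=split_seed
            )
        best, history = run_rs_svm(
            self.features,
            self.bounds,
            split,
            n_surveys=self.n_surveys,
            seed=survey_seed,
            grid=self.grid,
        )
        return RandomSurveySVMResults(self, split, best, history, survey_seed)


class RandomSurveySVMResults:
    """Fitted RS-SVM: selected features, tuned model, metrics, diagnostics."""

    def __init__(self, model: RandomSurveySVM, split: SplitSpec,
                 best: SurveyResult, history: list[SurveyResult], survey_seed: int):
        self.model = model
        self.split = split
        self.best = best
        self.history = history
        self.survey_seed = survey_seed

    # -- estimates -----------------------------------------------------

    @property
    def selected_columns(self) -> np.ndarray:
        """Column positions of the selected feature set R."""
        return self.best.survey.r

    @property
    def selected_voxels(self) -> np.ndarray:
        """Linear voxel indices (in the source volume) of R."""
        return self.model.features.column_index[self.best.survey.r]

    @property
    def best_params(self) -> GridPoint:
        return self.best.best_params

    @property
    def val_metrics(self) -> MetricsReport:
        return self.best.val_metrics

    @property
    def test_metrics(self) -> MetricsReport:
        return self.best.test_metrics

    # -- diagnostics ---------------------------------------------------

    def roc(self) -> RocCurve:
        """Test-split ROC of the selected model."""
        yte = self.model.features.y[self.split.test_idx]
        return roc_auc(self.best.test_scores, yte)

    def planted_recovery(self) -> float:
        """Fraction of selected columns that are planted informative voxels.

        Only available when the model was built from a synthetic cohort
        with a ground-truth mask.
        """
        if self.model.truth_mask_index is None:
            raise ValueError("no ground-truth mask available")
        planted = np.isin(self.selected_voxels, self.model.truth_mask_index)
        return float(planted.mean())

    def history_frame(self) -> pd.DataFrame:
        """Per-survey table: size, parameters, validation/test accuracy."""
        rows = [
            {
                "survey_id": k,
                "l": res.survey.l,
                "kernel": res.best_params.kernel,
                "C": res.best_params.C,
                "gamma": res.best_params.gamma,
                "val_accuracy": res.val_metrics.accuracy,
                "test_accuracy": res.test_metrics.accuracy,
                "accepted": res.accepted,
            }
            for k, res in enumerate(self.history)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        b = self.best
        lines = [
            "Random-Survey SVM Results",
            "=" * 60,
            f"Subjects:              {self.model.features.n_subjects} "
            f"(train {len(self.split.train_idx)} / val {len(self.split.val_idx)}"
            f" / test {len(self.split.test_idx)})",
            f"Feature columns:       {self.model.features.n_features}",
            f"Survey-size interval:  [{self.model.bounds.c_max}, "
            f"{self.model.bounds.c_min}]",
            f"Surveys run:           {len(self.history)}",
            "-" * 60,
            f"Selected |R|:          {b.survey.l}",
            f"Selected voxels:       {[int(v) for v in self.selected_voxels]}",
            f"Kernel / C / gamma:    {b.best_params.kernel} / {b.best_params.C}"
            f" / {b.best_params.gamma}",
            f"Validation accuracy:   {b.val_metrics.accuracy:.4f}",
            f"Test accuracy:         {b.test_metrics.accuracy:.4f}",
            f"Test precision:        {_fmt(b.test_metrics.precision)}",
            f"Test recall:           {_fmt(b.test_metrics.recall)}",
            f"Test F-measure:        {_fmt(b.test_metrics.f_measure)}",
            f"Test AUC:              {self.roc().auc:.4f}",
        ]
        if self.model.truth_mask_index is not None:
            lines.append(f"Planted recovery:      {self.planted_recovery():.4f}")
        lines.append("=" * 60)
        return "\n".join(lines)


def _fmt(v) -> str:
    return "undefined" if v is None else f"{v:.4f}"
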