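"""Random surveys, stratified splitting and the RS-SVM selection loop."""

import numpy as np
import pytest

from voxelsurvey import (FeatureBounds, RandomSurveySVM, draw_survey,
                         run_rs_svm, split_dataset)


class TestDrawSurvey:
    def test_size_within_bounds_and_distinct(self, rng):
        bounds = FeatureBounds(c_max=21, c_min=132)
        for _ in range(20):
            s = draw_survey(64_411, bounds, rng)
            assert 21 <= s.l <= 132
            assert len(set(s.r)) == s.l
            assert np.all(np.diff(s.r) > 0)

    def test_degenerate_interval(self, rng):
        s = draw_survey(10, FeatureBounds(c_max=5, c_min=5), rng)
        assert s.l == 5

    def test_seed_determinism(self):
        bounds = FeatureBounds(c_max=3, c_min=8)
        a = draw_survey(100, bounds, np.random.default_rng(42))
        b = draw_survey(100, bounds, np.random.default_rng(42))
        assert np.array_equal(a.r, b.r)

    def test_bounds_wider_than_columns_rejected(self, rng):
        with pytest.raises(ValueError, match="c_min"):
            draw_survey(5, FeatureBounds(c_max=2, c_min=10), rng)


class TestSplitDataset:
    def test_ten_subjects_split_622(self):
        y = np.array([-1] * 5 + [1] * 5)
        s = split_dataset(10, y, seed=0)
        assert (len(s.train_idx), len(s.val_idx), len(s.test_idx)) == (6, 2, 2)

    def test_partition_and_stratification(self):
        y = np.array([-1] * 30 + [1] * 20)
        s = split_dataset(50, y, seed=3)
        parts = [s.train_idx, s.val_idx, s.test_idx]
        union = np.concatenate(parts)
        assert sorted(union) == list(range(50))
        for part, frac in zip(parts, (0.6, 0.2, 0.2)):
            for cls, n_cls in ((-1, 30), (1, 20)):
                got = int(np.sum(y[part] == cls))
                assert abs(got - frac * n_cls) <= 1

    def test_seed_determinism(self):
        y = np.array([-1] * 10 + [1] * 10)
        a, b = (split_dataset(20, y, seed=5) for _ in range(2))
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.test_idx, b.test_idx)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            split_dataset(6, np.ones(6), seed=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            split_dataset(4, np.array([-1, -1, 1, 1]), seed=0)


class TestRunRsSvm:
    def test_single_survey_is_the_best(self, small_model):
        split = split_dataset(small_model.features.n_subjects,
                              small_model.features.y, seed=1)
        best, history = run_rs_svm(small_model.features, small_model.bounds,
                                   split, n_surveys=1, seed=2)
        assert len(history) == 1
        assert best is history[0]
        assert best.accepted

    def test_reproducible_for_fixed_seeds(self, small_model):
        split = split_dataset(small_model.features.n_subjects,
                              small_model.features.y, seed=1)
        runs = [run_rs_svm(small_model.features, small_model.bounds, split,
                           n_surveys=8, seed=9) for _ in range(2)]
        (best_a, hist_a), (best_b, hist_b) = runs
        assert np.array_equal(best_a.survey.r, best_b.survey.r)
        assert best_a.test_metrics == best_b.test_metrics
        for ra, rb in zip(hist_a, hist_b):
            assert np.array_equal(ra.survey.r, rb.survey.r)
            assert ra.val_metrics.accuracy == rb.val_metrics.accuracy

    def test_best_validation_accuracy_has_prefix_property(self, small_model):
        """With a fixed seed the survey stream is a prefix: more surveys can
        only improve the best validation accuracy."""
        split = split_dataset(small_model.features.n_subjects,
                              small_model.features.y, seed=1)
        accs = []
        for n in (2, 6, 12):
            best, _ = run_rs_svm(small_model.features, small_model.bounds,
                                 split, n_surveys=n, seed=4)
            accs.append(best.val_metrics.accuracy)
        assert accs == sorted(accs)

    def test_best_maximizes_validation_accuracy(self, small_model):
        split = split_dataset(small_model.features.n_subjects,
                              small_model.features.y, seed=1)
        best, history = run_rs_svm(small_model.features, small_model.bounds,
                                   split, n_surveys=10, seed=3)
        assert best.val_metrics.accuracy == max(
            r.val_metrics.accuracy for r in history)


class TestModelResults:
    def test_from_cohort_builds_valid_bounds(self, small_model):
        b = small_model.bounds
        assert 1 <= b.c_max <= b.c_min <= small_model.features.n_features

    def test_results_surface(self, small_model):
        res = small_model.fit(split_seed=1, survey_seed=2)
        r = res.selected_columns
        assert len(r) == res.best.survey.l
        assert np.all(res.selected_voxels ==
                      small_model.features.column_index[r])
        assert 0.0 <= res.planted_recovery() <= 1.0
        assert 0.0 <= res.roc().auc <= 1.0
        hist = res.history_frame()
        assert len(hist) == 20 and hist["accepted"].sum() == 1

    def test_summary_mentions_key_quantities(self, small_model):
        text = small_model.fit(split_seed=1, survey_seed=2).summary()
        for token in ("Selected |R|", "Test accuracy", "Survey-size interval",
                      "Planted recovery"):
            assert token in text

    def test_feature_matrix_constructor_requires_bounds(self, small_model):
        with pytest.raises(ValueError, match="bounds"):
            RandomSurveySVM(small_model.features)
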