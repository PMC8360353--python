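"""Stratified folds, out-of-fold pooling, confusion metrics and the
analytic coin-toss benchmark."""

import numpy as np
import pytest

from vocrisk.evaluation import (
    confusion_metrics,
    cross_validate_level,
    random_model_f1,
    run_trials,
    stratified_folds,
    trial_seeds,
)


def study_labels():
    return np.array([1] * 36 + [0] * 176)


class TestStratifiedFolds:
    @pytest.mark.parametrize("seed", [0, 1, 17, 123456])
    def test_study_imbalance_gives_9_high_44_low_per_fold(self, seed):
        y = study_labels()
        folds = stratified_folds(y, k=4, seed=seed)
        for i in range(4):
            in_fold = folds.fold_ids == i
            assert in_fold.sum() == 53
            assert y[in_fold].sum() == 9

    def test_same_seed_identical_assignment(self):
        y = study_labels()
        f1 = stratified_folds(y, k=4, seed=3)
        f2 = stratified_folds(y, k=4, seed=3)
        np.testing.assert_array_equal(f1.fold_ids, f2.fold_ids)

    def test_k_of_one_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(study_labels(), k=1, seed=0)

    def test_class_smaller_than_k_rejected(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            stratified_folds(y, k=4, seed=0)

    def test_fold_sizes_differ_by_at_most_one(self):
        y = np.array([1] * 10 + [0] * 33)
        folds = stratified_folds(y, k=4, seed=5)
        sizes = folds.fold_sizes()
        assert sizes.max() - sizes.min() <= 1


class TestCrossValidateLevel:
    def test_constant_high_trainer_has_full_recall_zero_specificity(self):
        y = study_labels()
        folds = stratified_folds(y, k=4, seed=0)
        preds = cross_validate_level(lambda tr, te, i: np.ones(len(te)), None, folds)
        m = confusion_metrics(preds.astype(int), y)
        assert m.recall == 1.0 and m.specificity == 0.0

    def test_every_subject_predicted_exactly_once(self):
        y = study_labels()
        folds = stratified_folds(y, k=4, seed=1)
        seen = []

        def trainer(tr, te, i):
            seen.extend(te)
            return np.zeros(len(te))

        cross_validate_level(trainer, None, folds)
        assert sorted(seen) == list(range(len(y)))

    def test_test_fold_never_in_training_indices(self):
        y = study_labels()
        folds = stratified_folds(y, k=4, seed=2)

        def trainer(tr, te, i):
            assert len(np.intersect1d(tr, te)) == 0
            return np.zeros(len(te))

        cross_validate_level(trainer, None, folds)

    def test_trainer_failure_reports_fold_id(self):
        folds = stratified_folds(study_labels(), k=4, seed=0)

        def trainer(tr, te, i):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="fold 0"):
            cross_validate_level(trainer, None, folds)


class TestConfusionMetrics:
    def test_harmonic_mean_of_equal_precision_recall(self):
        # 1 TP, 1 FP, 1 FN, rest TN -> precision = recall = 0.5 -> F1 = 0.5
        preds = np.array([1, 1, 0, 0, 0])
        labels = np.array([1, 0, 1, 0, 0])
        m = confusion_metrics(preds, labels)
        assert m.precision == m.recall == 0.5
        assert m.f1 == pytest.approx(0.5)

    def test_all_positive_prediction_matches_coin_limit(self):
        """Predicting high for everyone: TP=36, FP=176 -> F1 = 0.2903."""
        y = study_labels()
        m = confusion_metrics(np.ones(len(y), int), y)
        assert (m.tp, m.fn, m.fp, m.tn) == (36, 0, 176, 0)
        assert round(m.f1, 4) == 0.2903

    def test_zero_predicted_positives_gives_zero_f1(self):
        y = study_labels()
        m = confusion_metrics(np.zeros(len(y), int), y)
        assert m.precision == 0.0 and m.f1 == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array([1]), np.array([1, 0]))


class TestRandomModel:
    def test_fair_coin_f1(self):
        assert round(random_model_f1(0.5).f1, 4) == 0.2535

    def test_always_high_coin_f1(self):
        assert round(random_model_f1(1.0).f1, 4) == 0.2903

    def test_expected_confusion_counts_at_half(self):
        b = random_model_f1(0.5)
        assert (b.tp, b.fn, b.fp, b.tn) == (18.0, 18.0, 88.0, 88.0)

    def test_monotone_in_p_and_maximal_at_one(self):
        grid = np.linspace(0.01, 1.0, 100)
        f1s = [random_model_f1(float(p)).f1 for p in grid]
        assert all(b >= a - 1e-12 for a, b in zip(f1s, f1s[1:]))
        assert f1s[-1] == max(f1s)

    def test_p_out_of_range_errors(self):
        with pytest.raises(ValueError):
            random_model_f1(1.2)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_agrees_with_monte_carlo_coin_toss(self, p):
        """Closed form within 3 SE of a simulated coin over 1e5 tosses."""
        rng = np.random.default_rng(42)
        reps = 20
        n = 100_000
        n_pos = int(n * 36 / 212)
        y = np.zeros(n, dtype=int)
        y[:n_pos] = 1
        f1s = []
        for _ in range(reps):
            preds = (rng.random(n) < p).astype(int)
            f1s.append(confusion_metrics(preds, y).f1)
        f1s = np.array(f1s)
        se = f1s.std(ddof=1) / np.sqrt(reps)
        analytic = random_model_f1(p, n_pos, n - n_pos).f1
        assert abs(f1s.mean() - analytic) < 3 * se + 1e-4


class TestTrials:
    def test_seed_pairs_derived_from_master(self):
        assert trial_seeds(5, 3) == [(5, 6), (7, 8), (9, 10)]

    def test_at_least_two_trials_required(self):
        with pytest.raises(ValueError):
            run_trials(None, n_trials=1)

    def _toy_dataset(self, rng, n=48):
        from vocrisk.pipeline import StackingDataset

        y = (np.arange(n) % 4 == 0).astype(int)
        X = rng.normal(0, 0.2, (n, 20))
        X[:, 0] += y * 5.0
        return StackingDataset(
            ids=[f"S{i}" for i in range(n)], X=X, y_post=y, y_pre=y,
            segments=[np.empty((0, 2, 360))] * n,
        )

    def test_mean_is_average_of_per_trial_f1_within_ci(self, rng):
        ds = self._toy_dataset(rng)
        summary = run_trials(ds, n_trials=4, variant="C", master_seed=0)
        f1s = summary.per_trial_f1()
        assert summary.mean_f1 == pytest.approx(f1s.mean())
        assert summary.ci_low <= summary.mean_f1 <= summary.ci_high
        assert f1s.min() - 1e-12 <= summary.mean_f1 <= f1s.max() + 1e-12
        # the planted separating feature dominates chance comfortably
        assert summary.mean_f1 > 0.7

    def test_same_master_seed_reproduces_all_trials(self, rng):
        ds = self._toy_dataset(rng)
        s1 = run_trials(ds, n_trials=2, variant="C", master_seed=5)
        s2 = run_trials(ds, n_trials=2, variant="C", master_seed=5)
        np.testing.assert_array_equal(s1.per_trial_f1(), s2.per_trial_f1())
        for t1, t2 in zip(s1.trials, s2.trials):
            np.testing.assert_array_equal(t1.predictions, t2.predictions)
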