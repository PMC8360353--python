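"""Cross-validation, trial aggregation and the random-model benchmark.

The stacking classifier is evaluated with stratified 4-fold
cross-validation under two seeds: seed alpha controls the fold shuffle for
all level-1 base models, seed beta the (independent) fold shuffle for the
level-2 meta model. Out-of-fold predictions are pooled over all folds so
that every subject is predicted exactly once per trial, and the whole
procedure is repeated over 20 trials with different seed pairs; the mean
F1-score over trials is the reported performance.

The analytic benchmark is a biased coin predicting "high pain" with
probability p: its expected confusion matrix is TP = n_pos*p,
FN = n_pos*(1-p), FP = n_neg*p, TN = n_neg*(1-p), giving precision
n_pos/(n_pos+n_neg), recall p, and a closed-form F1(p) that is
non-decreasing in p and maximal at p = 1. With the study imbalance of
36:176 this maximum is F1 = 0.2903 — the floor any useful model must beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stacking_model import (
    STACK_BASE_IDS,
    BaseModelSpec,
    CNNConfig,
    _pool_segments,
    assemble_meta_inputs,
    train_base,
    train_cnn,
    train_meta,
)

__all__ = [
    "FoldAssignment",
    "ConfusionMetrics",
    "TrialResult",
    "RandomBenchmark",
    "stratified_folds",
    "cross_validate_level",
    "run_stacking_trial",
    "run_trials",
    "confusion_metrics",
    "random_model_f1",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Seed-controlled stratified fold map; fold ids are 0..k-1."""

    k: int
    fold_ids: np.ndarray
    seed: int

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_ids, minlength=self.k)


def stratified_folds(labels: np.ndarray, k: int = 4, seed: int = 0) -> FoldAssignment:
    """Shuffle subjects within each class and deal them round-robin.

    Preserves class proportions: for a 212-subject roster with 36
    positives and k = 4, every fold receives exactly 9 high-pain and 44
    low-pain subjects. Fold sizes differ by at most one per class.
    Deterministic given ``seed``.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    fold_ids = np.full(len(y), -1, dtype=int)
    start = 0  # rotate the remainder across classes so fold sizes differ by <= 1
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
        idx = idx[rng.permutation(len(idx))]
        fold_ids[idx] = (np.arange(len(idx)) + start) % k
        start = (start + len(idx)) % k
    return FoldAssignment(k=k, fold_ids=fold_ids, seed=seed)


def cross_validate_level(trainer, dataset, folds: FoldAssignment) -> np.ndarray:
    """Generic out-of-fold prediction loop for one stacking level.

    ``trainer(train_idx, test_idx, fold_i) -> predictions for test_idx``
    must fit all fold-internal preprocessing on the training folds only.
    Predictions are returned re-ordered to the original subject order;
    every subject is predicted exactly once.
    """
    n = len(folds.fold_ids)
    out = np.full(n, -1, dtype=float)
    for i in range(folds.k):
        te = np.flatnonzero(folds.fold_ids == i)
        tr = np.flatnonzero(folds.fold_ids != i)
        try:
            preds = trainer(tr, te, i)
        except Exception as exc:  # noqa: BLE001 - annotate with the fold id
            raise RuntimeError(f"trainer failed on fold {i}: {exc}") from exc
        out[te] = preds
    assert not np.any(out < 0), "some subjects were never predicted"
    return out


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fn: int
    fp: int
    tn: int
    precision: float
    recall: float
    specificity: float
    accuracy: float
    f1: float


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def confusion_metrics(predictions: np.ndarray, labels: np.ndarray) -> ConfusionMetrics:
    """Confusion counts and derived metrics for binary calls (1 = high).

    Zero-denominator conventions: precision = 0 when no positives are
    predicted; recall = 0 when there are no true positives.
    """
    p = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if len(p) != len(y):
        raise ValueError("predictions and labels differ in length")
    if len(p) == 0:
        raise ValueError("empty inputs")
    tp = int(((p == 1) & (y == 1)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (fp + tn) if fp + tn else 0.0
    accuracy = (tp + tn) / len(p)
    return ConfusionMetrics(tp, fn, fp, tn, precision, recall, specificity,
                            accuracy, _f1(precision, recall))


@dataclass(frozen=True)
class TrialResult:
    """One dual-seed cross-validated trial: pooled predictions + metrics."""

    seed_alpha: int
    seed_beta: int
    variant: str
    predictions: np.ndarray
    labels: np.ndarray
    metrics: ConfusionMetrics


def _base_oof_predictions(
    X: np.ndarray,
    y: np.ndarray,
    segments_per_subject,
    folds: FoldAssignment,
    seed_alpha: int,
    cnn_config: CNNConfig | None,
) -> np.ndarray:
    """Out-of-fold hard calls for the 7 retained base models (columns)."""
    n = len(y)
    oof = np.zeros((n, len(STACK_BASE_IDS)))
    for j, mid in enumerate(STACK_BASE_IDS):
        if mid == "cnn":
            def trainer(tr, te, i):
                tr_segs, tr_labels = _pool_segments(segments_per_subject, y, tr)
                cnn = train_cnn(tr_segs, tr_labels, seed=seed_alpha + 31 * i + 7,
                                config=cnn_config)
                return [cnn.predict_subject(segments_per_subject[t]) for t in te]
        else:
            def trainer(tr, te, i, _mid=mid, _j=j):
                fm = train_base(BaseModelSpec(_mid), X[tr], y[tr],
                                seed=seed_alpha + 31 * i + _j)
                return fm.predict(X[te])
        oof[:, j] = cross_validate_level(trainer, None, folds)
    return oof


def run_stacking_trial(
    dataset,
    seed_alpha: int,
    seed_beta: int,
    variant: str = "A",
    cnn_config: CNNConfig | None = None,
) -> TrialResult:
    """One full dual-seed trial of the two-level stacking model.

    Level 1: base models cross-validated under folds shuffled by
    ``seed_alpha`` (shared by all base models), producing out-of-fold
    predictions for every subject, re-ordered to the original roster
    order. Level 2: the meta model cross-validated under folds shuffled by
    ``seed_beta`` on the variant's input slice. Variant C bypasses level 1
    entirely; variant E uses the pre-study pain category as the label.

    ``dataset`` needs attributes ``X`` (n x 20 feature matrix, NaNs
    allowed), ``y_post``, ``y_pre`` (0/1 arrays) and ``segments``
    (per-subject list of (n_i, 2, 360) arrays).
    """
    X = np.asarray(dataset.X, dtype=float)
    y = np.asarray(dataset.y_pre if variant == "E" else dataset.y_post, dtype=int)
    segs = dataset.segments

    feat_cols = [c for c in range(X.shape[1])]
    if variant == "D":
        from .features import FEATURE_NAMES

        feat_cols.remove(FEATURE_NAMES.index("median_M_vasoc"))
    Xv = X[:, feat_cols]

    base_oof = None
    if variant != "C":
        folds_a = stratified_folds(y, k=4, seed=seed_alpha)
        base_oof = _base_oof_predictions(Xv, y, segs, folds_a, seed_alpha, cnn_config)

    meta_X = assemble_meta_inputs(variant, X, base_oof)
    folds_b = stratified_folds(y, k=4, seed=seed_beta)

    def meta_trainer(tr, te, i):
        fitted = train_meta(meta_X[tr], y[tr], variant=variant,
                            seed=seed_beta + 101 * i)
        return fitted.predict(meta_X[te])

    preds = cross_validate_level(meta_trainer, None, folds_b).astype(int)
    return TrialResult(
        seed_alpha=seed_alpha,
        seed_beta=seed_beta,
        variant=variant,
        predictions=preds,
        labels=y,
        metrics=confusion_metrics(preds, y),
    )


@dataclass(frozen=True)
class TrialSummary:
    """Aggregate over trials: mean F1 with a 95% t-interval."""

    mean_f1: float
    ci_low: float
    ci_high: float
    trials: list[TrialResult] = field(repr=False, default_factory=list)

    def per_trial_f1(self) -> np.ndarray:
        return np.array([t.metrics.f1 for t in self.trials])

    def metrics_table(self) -> pd.DataFrame:
        rows = [
            {
                "seed_alpha": t.seed_alpha,
                "seed_beta": t.seed_beta,
                "variant": t.variant,
                "tp": t.metrics.tp,
                "fn": t.metrics.fn,
                "fp": t.metrics.fp,
                "tn": t.metrics.tn,
                "precision": t.metrics.precision,
                "recall": t.metrics.recall,
                "specificity": t.metrics.specificity,
                "accuracy": t.metrics.accuracy,
                "f1": t.metrics.f1,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def trial_seeds(master_seed: int, n_trials: int) -> list[tuple[int, int]]:
    """Reproducible (alpha_i, beta_i) = (master + 2i, master + 2i + 1)."""
    return [(master_seed + 2 * i, master_seed + 2 * i + 1) for i in range(n_trials)]


def run_trials(
    dataset,
    n_trials: int = 20,
    variant: str = "A",
    master_seed: int = 0,
    cnn_config: CNNConfig | None = None,
) -> TrialSummary:
    """Repeat the dual-seed trial ``n_trials`` times and aggregate.

    The reported performance is the mean F1 over trials; the 95%
    confidence interval is a t-distribution interval on the trial means.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    trials = [
        run_stacking_trial(dataset, a, b, variant=variant, cnn_config=cnn_config)
        for a, b in trial_seeds(master_seed, n_trials)
    ]
    f1s = np.array([t.metrics.f1 for t in trials])
    mean = float(f1s.mean())
    sd = float(f1s.std(ddof=1))
    half = sps.t.ppf(0.975, n_trials - 1) * sd / np.sqrt(n_trials) if sd > 0 else 0.0
    return TrialSummary(mean_f1=mean, ci_low=mean - half, ci_high=mean + half,
                        trials=trials)


@dataclass(frozen=True)
class RandomBenchmark:
    """Expected performance of a biased coin calling high pain w.p. p."""

    p: float
    n_pos: int
    n_neg: int
    tp: float
    fn: float
    fp: float
    tn: float
    precision: float
    recall: float
    f1: float


def random_model_f1(p: float, n_pos: int = 36, n_neg: int = 176) -> RandomBenchmark:
    """Analytic coin-toss baseline from the expected confusion matrix.

    TP = n_pos*p, FN = n_pos*(1-p), FP = n_neg*p, TN = n_neg*(1-p); hence
    precision = n_pos/(n_pos+n_neg) for p > 0, recall = p, and F1 follows
    in closed form. F1(p) is non-decreasing and maximal at p = 1, where it
    equals 2*n_pos/(n_pos + n_pos + n_neg) — 0.2903 for 36:176.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    tp = n_pos * p
    fn = n_pos * (1.0 - p)
    fp = n_neg * p
    tn = n_neg * (1.0 - p)
    precision = n_pos / (n_pos + n_neg) if p > 0 else 0.0
    recall = p
    return RandomBenchmark(
        p=p, n_pos=n_pos, n_neg=n_neg, tp=tp, fn=fn, fp=fp, tn=tn,
        precision=precision, recall=recall, f1=_f1(precision, recall),
    )
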