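"""Two-level stacking classifier.

Level 1 holds seven base learners — logistic regression, linear/RBF SVM,
random forest, extremely randomized trees, AdaBoost, and a 1-D CNN that
reads the raw 180-s two-channel segments around each vasoconstriction
event. Level 2 is an MLP meta model that receives the base models' category
calls together with (depending on the variant) the 20 per-subject features
and makes the final prediction.

Variants (meta-model input slices):

- A: 20 features + 7 base outputs (27 inputs) — the full model
- B: 7 base outputs only
- C: 20 features only (no level 1; equals the stand-alone MLP)
- D: 19 features (median M_vasoc excluded everywhere) + 7 base outputs
- E: same wiring as A, but trained/labeled on the pre-study pain category

Class imbalance is handled by inverse-frequency class weights on the
positive (high-pain) class in every learner. All sigmoid outputs are
thresholded at 0.5, ties going to high pain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ._nn import (
    Conv1d,
    Dense,
    Dropout,
    GlobalAvgPool1d,
    MaxPool1d,
    Network,
    ReLU,
    Trainer,
)
from .features import FEATURE_NAMES

__all__ = [
    "ALL_BASE_IDS",
    "STACK_BASE_IDS",
    "VARIANTS",
    "BaseModelSpec",
    "FeaturePreprocessor",
    "train_base",
    "train_cnn",
    "aggregate_cnn",
    "train_meta",
    "predict_stack",
    "fit_stack",
    "FittedStack",
    "meta_input_width",
    "inverse_frequency_weights",
]

#: All eleven candidate base algorithms.
ALL_BASE_IDS: tuple[str, ...] = (
    "logistic_regression",
    "svm_linear",
    "svm_rbf",
    "svm_polynomial",
    "random_forest",
    "extra_trees",
    "adaboost",
    "gradient_boosting",
    "xgboost",
    "cnn",
    "mlp",
)

#: The seven base learners retained in the stacking ensemble, fixed order.
STACK_BASE_IDS: tuple[str, ...] = (
    "logistic_regression",
    "svm_linear",
    "svm_rbf",
    "random_forest",
    "extra_trees",
    "adaboost",
    "cnn",
)

VARIANTS = ("A", "B", "C", "D", "E")

#: Models that receive standardized features; tree ensembles take raw values.
_SCALED_MODELS = {"logistic_regression", "svm_linear", "svm_rbf", "svm_polynomial", "mlp"}

#: Decision threshold on sigmoid outputs; ties at exactly 0.5 go to high pain.
DECISION_THRESHOLD = 0.5


def inverse_frequency_weights(y: np.ndarray) -> dict[int, float]:
    """Positive-class weighting: {low: 1, high: n_low / n_high}."""
    y = np.asarray(y, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training data must contain both classes")
    return {0: 1.0, 1: n_neg / n_pos}


@dataclass(frozen=True)
class BaseModelSpec:
    """One base learner: algorithm id, hyperparameter overrides, weighting."""

    model_id: str
    hyperparameters: dict = field(default_factory=dict)
    class_weights: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.model_id not in ALL_BASE_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")


class FeaturePreprocessor:
    """Fold-internal imputation and standardization.

    Fitted on training-fold subjects only: missing values (event-free
    subjects' vasoconstriction medians) are replaced by the training-fold
    median of the feature; standardization uses training-fold mean/SD.
    """

    def fit(self, X: np.ndarray) -> "FeaturePreprocessor":
        X = np.asarray(X, dtype=float)
        self.medians_ = np.nanmedian(X, axis=0)
        self.medians_ = np.where(np.isnan(self.medians_), 0.0, self.medians_)
        filled = np.where(np.isnan(X), self.medians_, X)
        self.mean_ = filled.mean(axis=0)
        sd = filled.std(axis=0)
        self.sd_ = np.where(sd == 0, 1.0, sd)
        return self

    def transform(self, X: np.ndarray, standardize: bool) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        filled = np.where(np.isnan(X), self.medians_, X)
        if standardize:
            return (filled - self.mean_) / self.sd_
        return filled


# --- feature-based base learners -------------------------------------------


class _NumpyMLP:
    """Stand-alone MLP on the feature vector (also the meta architecture)."""

    # fixed-epoch training: at this cohort scale a held-out validation split
    # would be too small to steer early stopping reliably, so regularization
    # comes from dropout and the epoch budget instead
    def __init__(self, n_in: int, seed: int, hidden: int = 32, dropout: float = 0.2,
                 lr: float = 1e-2, max_epochs: int = 150, patience: int = 0):
        rng = np.random.default_rng(seed)
        self.net = Network([
            Dense(n_in, hidden, rng),
            ReLU(),
            Dropout(dropout, rng),
            Dense(hidden, 1, rng),
        ])
        self.trainer = Trainer(
            self.net, lr=lr, batch_size=32, max_epochs=max_epochs,
            patience=patience, seed=seed + 1,
        )

    def fit(self, X, y, class_weight):
        self.trainer.fit(np.asarray(X, dtype=float), y, class_weight)
        return self

    def predict_proba_pos(self, X) -> np.ndarray:
        return self.net.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba_pos(X) >= DECISION_THRESHOLD).astype(int)


class FittedFeatureModel:
    """A fitted feature-based base learner plus its preprocessing state."""

    def __init__(self, model_id: str, estimator, prep: FeaturePreprocessor,
                 standardize: bool):
        self.model_id = model_id
        self.estimator = estimator
        self.prep = prep
        self.standardize = standardize

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xt = self.prep.transform(X, self.standardize)
        return np.asarray(self.estimator.predict(Xt), dtype=int)

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        Xt = self.prep.transform(X, self.standardize)
        est = self.estimator
        if isinstance(est, _NumpyMLP):
            return est.predict_proba_pos(Xt)
        if hasattr(est, "predict_proba"):
            return est.predict_proba(Xt)[:, 1]
        if hasattr(est, "decision_function"):
            d = est.decision_function(Xt)
            return 1.0 / (1.0 + np.exp(-d))
        return est.predict(Xt).astype(float)


def _make_estimator(spec: BaseModelSpec, cw: dict[int, float], seed: int, n_features: int):
    hp = dict(spec.hyperparameters)
    mid = spec.model_id
    if mid == "logistic_regression":
        return LogisticRegression(max_iter=2000, class_weight=cw, **hp)
    if mid == "svm_linear":
        return SVC(kernel="linear", class_weight=cw, random_state=seed, **hp)
    if mid == "svm_rbf":
        return SVC(kernel="rbf", class_weight=cw, random_state=seed, **hp)
    if mid == "svm_polynomial":
        return SVC(kernel="poly", class_weight=cw, random_state=seed, **hp)
    if mid == "random_forest":
        hp.setdefault("n_estimators", 200)
        return RandomForestClassifier(class_weight=cw, random_state=seed, **hp)
    if mid == "extra_trees":
        hp.setdefault("n_estimators", 200)
        return ExtraTreesClassifier(class_weight=cw, random_state=seed, **hp)
    if mid == "adaboost":
        hp.setdefault("n_estimators", 100)
        return AdaBoostClassifier(random_state=seed, **hp)
    if mid == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if mid == "xgboost":
        hp.setdefault("n_estimators", 200)
        return XGBClassifier(
            scale_pos_weight=cw[1] / cw[0], random_state=seed,
            eval_metric="logloss", **hp,
        )
    if mid == "mlp":
        return _NumpyMLP(n_in=n_features, seed=seed, **hp)
    raise ValueError(f"{mid!r} is not a feature-based model")


def train_base(
    spec: BaseModelSpec, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> FittedFeatureModel:
    """Fit one feature-based base learner on a training fold.

    Positive-class weighting is applied to every algorithm (class weights
    where supported, sample weights for the boosting learners, positive
    scale for XGBoost). Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold contains a single class")
    cw = spec.class_weights or inverse_frequency_weights(y)
    prep = FeaturePreprocessor().fit(X)
    standardize = spec.model_id in _SCALED_MODELS
    Xt = prep.transform(X, standardize)
    est = _make_estimator(spec, cw, seed, X.shape[1])
    if spec.model_id in ("adaboost", "gradient_boosting"):
        sw = np.where(y == 1, cw[1], cw[0])
        est.fit(Xt, y, sample_weight=sw)
    elif isinstance(est, _NumpyMLP):
        est.fit(Xt, y, cw)
    else:
        est.fit(Xt, y)
    return FittedFeatureModel(spec.model_id, est, prep, standardize)


# --- CNN base model ---------------------------------------------------------


@dataclass(frozen=True)
class CNNConfig:
    """1-D CNN over the (2, 360) segment tensor.

    Two convolution blocks (kernel 7, stride 1, ReLU, max-pool 4) feeding a
    global average pool, a dense layer and a sigmoid output. The filter
    counts are kept small for the size of dataset this pipeline targets.
    """

    filters: tuple[int, int] = (8, 16)
    kernel: int = 7
    pool: int = 4
    dense: int = 16
    lr: float = 5e-3
    batch_size: int = 128
    max_epochs: int = 15
    patience: int = 3
    min_epochs: int = 6
    max_train_segments: int = 1000


class FittedCNN:
    """Segment-level CNN with per-channel standardization state."""

    def __init__(self, net: Network, chan_mean, chan_sd, majority: int,
                 history: list[float]):
        self.net = net
        self.chan_mean = chan_mean
        self.chan_sd = chan_sd
        self.majority = majority
        self.history = history

    def _standardize(self, segs: np.ndarray) -> np.ndarray:
        return (segs - self.chan_mean) / self.chan_sd

    def segment_scores(self, segments: np.ndarray) -> np.ndarray:
        """Positive-class score per segment; input shape (n, 2, 360)."""
        if len(segments) == 0:
            return np.empty(0)
        return self.net.predict_proba(self._standardize(np.asarray(segments, float)))

    def predict_subject(self, segments: np.ndarray) -> int:
        return aggregate_cnn(self.segment_scores(segments), self.majority)


def train_cnn(
    segments: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    config: CNNConfig | None = None,
) -> FittedCNN:
    """Train the segment-level CNN.

    ``segments`` has shape (n_segments, 2, 360) — channel 0 PPGa, channel 1
    RRI; every segment carries the pain category of its subject.
    Class-weighted loss, Adam, early stopping on a 20% stratified split.
    Large training sets are subsampled (seeded) to bound the cost.
    """
    cfg = config or CNNConfig()
    segments = np.asarray(segments, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if segments.ndim != 3 or segments.shape[1] != 2:
        raise ValueError("segments must have shape (n, 2, 360)")
    if len(segments) == 0:
        raise ValueError("no segments to train on")
    rng = np.random.default_rng(seed)
    if len(segments) > cfg.max_train_segments:
        keep = rng.choice(len(segments), cfg.max_train_segments, replace=False)
        keep.sort()
        segments, labels = segments[keep], labels[keep]

    chan_mean = segments.mean(axis=(0, 2), keepdims=True)
    chan_sd = segments.std(axis=(0, 2), keepdims=True)
    chan_sd = np.where(chan_sd == 0, 1.0, chan_sd)
    x = (segments - chan_mean) / chan_sd

    f1, f2 = cfg.filters
    net_rng = np.random.default_rng(seed + 1)
    net = Network([
        Conv1d(2, f1, cfg.kernel, net_rng),
        ReLU(),
        MaxPool1d(cfg.pool),
        Conv1d(f1, f2, cfg.kernel, net_rng),
        ReLU(),
        MaxPool1d(cfg.pool),
        GlobalAvgPool1d(),
        Dense(f2, cfg.dense, net_rng),
        ReLU(),
        Dense(cfg.dense, 1, net_rng),
    ])
    if len(np.unique(labels)) < 2:
        cw = {0: 1.0, 1: 1.0}
    else:
        cw = inverse_frequency_weights(labels)
    trainer = Trainer(
        net, lr=cfg.lr, batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
        patience=cfg.patience, min_epochs=cfg.min_epochs, seed=seed + 2,
    )
    trainer.fit(x, labels, cw)
    majority = int(labels.mean() >= 0.5)
    return FittedCNN(net, chan_mean, chan_sd, majority, trainer.history)


def aggregate_cnn(scores: np.ndarray, majority: int = 0) -> int:
    """Subject-level call from per-segment scores.

    The subject score is the mean segment score; the category is high iff
    it reaches 0.5. Subjects with no usable segments receive the training
    fold's majority category.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) == 0:
        return majority
    return int(scores.mean() >= DECISION_THRESHOLD)


# --- meta model -------------------------------------------------------------

_N_FEATURES = len(FEATURE_NAMES)
_N_BASES = len(STACK_BASE_IDS)


def meta_input_width(variant: str) -> int:
    """Meta-model input width for each variant."""
    widths = {
        "A": _N_FEATURES + _N_BASES,       # 27
        "B": _N_BASES,                     # 7
        "C": _N_FEATURES,                  # 20
        "D": _N_FEATURES - 1 + _N_BASES,   # 26
        "E": _N_FEATURES + _N_BASES,       # 27
    }
    if variant not in widths:
        raise ValueError(f"unknown variant {variant!r}")
    return widths[variant]


class FittedMeta:
    """Fitted MLP meta model with its preprocessing state."""

    def __init__(self, mlp: _NumpyMLP, prep: FeaturePreprocessor, variant: str):
        self.mlp = mlp
        self.prep = prep
        self.variant = variant

    def predict(self, meta_X: np.ndarray) -> np.ndarray:
        Xt = self.prep.transform(meta_X, standardize=True)
        return self.mlp.predict(Xt)


def train_meta(
    meta_X: np.ndarray, y: np.ndarray, variant: str = "A", seed: int = 0,
    hyperparameters: dict | None = None,
) -> FittedMeta:
    """Train the MLP meta model on features + out-of-fold base outputs.

    ``meta_X`` columns must match the variant's input slice (base outputs
    must be out-of-fold predictions, never in-fold). One hidden layer of
    32 ReLU units with dropout 0.2 and a class-weighted sigmoid output.
    """
    meta_X = np.asarray(meta_X, dtype=float)
    y = np.asarray(y, dtype=int)
    expected = meta_input_width(variant)
    if meta_X.shape[1] != expected:
        raise ValueError(
            f"variant {variant} expects {expected} meta inputs, got {meta_X.shape[1]}"
        )
    cw = inverse_frequency_weights(y)
    prep = FeaturePreprocessor().fit(meta_X)
    Xt = prep.transform(meta_X, standardize=True)
    mlp = _NumpyMLP(n_in=expected, seed=seed, **(hyperparameters or {}))
    mlp.fit(Xt, y, cw)
    return FittedMeta(mlp, prep, variant)


# --- whole-stack convenience ------------------------------------------------


@dataclass
class FittedStack:
    """All fitted pieces of one stack: 6 feature bases, the CNN, the meta.

    Nothing inside derives from subjects outside the training data it was
    fitted on; the meta model was trained on internally cross-validated
    (out-of-fold) base outputs.
    """

    feature_bases: dict[str, FittedFeatureModel]
    cnn: FittedCNN | None
    meta: FittedMeta
    variant: str
    feature_columns: list[int]

    def predict(self, X: np.ndarray, segments_per_subject: list[np.ndarray] | None) -> np.ndarray:
        return predict_stack(self, X, segments_per_subject)


def _variant_feature_slice(variant: str) -> list[int]:
    cols = list(range(_N_FEATURES))
    if variant == "D":
        cols.remove(FEATURE_NAMES.index("median_M_vasoc"))
    return cols


def base_outputs_matrix(
    feature_bases: dict[str, FittedFeatureModel],
    cnn: FittedCNN | None,
    X: np.ndarray,
    segments_per_subject: list[np.ndarray] | None,
) -> np.ndarray:
    """Hard 0/1 base-model calls for each subject, one column per base."""
    n = len(X)
    out = np.zeros((n, _N_BASES))
    for j, mid in enumerate(STACK_BASE_IDS):
        if mid == "cnn":
            if cnn is None:
                raise ValueError("stack was fitted without a CNN")
            preds = [
                cnn.predict_subject(segs if segs is not None else np.empty((0, 2, 360)))
                for segs in (segments_per_subject or [None] * n)
            ]
            out[:, j] = preds
        else:
            out[:, j] = feature_bases[mid].predict(X)
    return out


def assemble_meta_inputs(
    variant: str, X: np.ndarray, base_out: np.ndarray | None
) -> np.ndarray:
    """Slice features/base outputs into the variant's meta-input matrix."""
    cols = _variant_feature_slice(variant)
    if variant == "B":
        assert base_out is not None
        return np.asarray(base_out, dtype=float)
    if variant == "C":
        return np.asarray(X, dtype=float)[:, cols]
    if base_out is None:
        raise ValueError(f"variant {variant} requires base outputs")
    return np.hstack([np.asarray(X, dtype=float)[:, cols], base_out])


def fit_stack(
    X: np.ndarray,
    y: np.ndarray,
    segments_per_subject: list[np.ndarray] | None,
    variant: str = "A",
    seed: int = 0,
    cnn_config: CNNConfig | None = None,
    n_inner_folds: int = 4,
) -> FittedStack:
    """Fit a complete stack on one training set.

    Base models are fitted on the full training data; the meta model is
    trained on *out-of-fold* base outputs produced by an internal
    stratified split of the training set, so no base output fed to the
    meta model was predicted in-fold.
    """
    from .evaluation import stratified_folds  # local import to avoid a cycle

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cols = _variant_feature_slice(variant)
    Xv = X[:, cols]
    segs = segments_per_subject

    feature_bases: dict[str, FittedFeatureModel] = {}
    cnn = None
    oof = None
    if variant not in ("C",):
        # out-of-fold base outputs for meta training
        folds = stratified_folds(y, k=n_inner_folds, seed=seed)
        oof = np.zeros((len(y), _N_BASES))
        for i in range(n_inner_folds):
            tr = folds.fold_ids != i
            te = ~tr
            for j, mid in enumerate(STACK_BASE_IDS):
                if mid == "cnn":
                    tr_segs, tr_labels = _pool_segments(segs, y, np.where(tr)[0])
                    fold_cnn = train_cnn(tr_segs, tr_labels, seed=seed + 31 * i, config=cnn_config)
                    oof[te, j] = [fold_cnn.predict_subject(segs[t]) for t in np.where(te)[0]]
                else:
                    fm = train_base(BaseModelSpec(mid), Xv[tr], y[tr], seed=seed + 31 * i + j)
                    oof[te, j] = fm.predict(Xv[te])
        # final base models on the full training data
        for j, mid in enumerate(STACK_BASE_IDS):
            if mid == "cnn":
                all_segs, all_labels = _pool_segments(segs, y, np.arange(len(y)))
                cnn = train_cnn(all_segs, all_labels, seed=seed + 997, config=cnn_config)
            else:
                feature_bases[mid] = train_base(BaseModelSpec(mid), Xv, y, seed=seed + j)

    meta_X = assemble_meta_inputs(variant, X, oof)
    meta = train_meta(meta_X, y, variant=variant, seed=seed + 1009)
    return FittedStack(feature_bases, cnn, meta, variant, cols)


def _pool_segments(segs_per_subject, y, idx):
    """Stack the segments of the selected subjects with their labels."""
    chunks, labels = [], []
    for i in idx:
        s = segs_per_subject[i] if segs_per_subject is not None else None
        if s is not None and len(s):
            chunks.append(np.asarray(s, dtype=float))
            labels.append(np.full(len(s), y[i], dtype=int))
    if not chunks:
        raise ValueError("no segments available in the training fold")
    return np.concatenate(chunks), np.concatenate(labels)


def predict_stack(
    fitted: FittedStack,
    X: np.ndarray,
    segments_per_subject: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Final category (1 = high pain) for each subject, deterministically.

    Each subject's prediction depends only on its own features and
    segments and the fitted state, so permuting subject order permutes
    predictions identically.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != _N_FEATURES:
        raise ValueError(f"expected {_N_FEATURES} features, got {X.shape[1]}")
    Xv = X[:, fitted.feature_columns]
    base_out = None
    if fitted.variant != "C":
        base_out = base_outputs_matrix(
            fitted.feature_bases, fitted.cnn, Xv, segments_per_subject
        )
    meta_X = assemble_meta_inputs(fitted.variant, X, base_out)
    return fitted.meta.predict(meta_X)
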