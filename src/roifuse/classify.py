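"""Per-modality SVM classification and repeated balanced-split evaluation.

Every model standardizes its selected features to zero mean and unit
variance using training subjects only (``x' = (x - mean) / sd``), fits an
RBF-kernel support vector machine (C = 0.1, gamma = 1 / (n_features x
mean training-feature variance)), and maps decision values to
probabilities with a Platt-style logistic sigmoid fitted on the training
decision values.  Performance is estimated by many class-stratified
80/20 train/test cycles; per-cycle accuracy, sensitivity, specificity,
balanced accuracy, ROC and AUC are aggregated into means, standard
deviations and a vertically averaged ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn import metrics as skm
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .errors import ConfigError, DataError
from .tables import AD, CN, FeatureTable

__all__ = [
    "StandardizationParams",
    "SvmConfig",
    "EvalConfig",
    "ModalityModel",
    "CycleMetrics",
    "AggregateMetrics",
    "standardize_fit",
    "standardize_apply",
    "train_modality_model",
    "predict_probability",
    "predict_label",
    "confusion_metrics",
    "roc_and_auc",
    "mean_roc",
    "repeated_holdout_evaluation",
]

DEFAULT_FPR_GRID = tuple(np.round(np.linspace(0.0, 1.0, 101), 2))


# ---------------------------------------------------------------- scaling
@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature training mean and sample standard deviation (ddof=1)."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray


def standardize_fit(train_table: FeatureTable) -> StandardizationParams:
    if train_table.n_subjects < 2:
        raise DataError("standardization needs >= 2 training subjects")
    mean = train_table.values.mean(axis=0)
    std = train_table.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(std == 0)
    if zero.size:
        raise DataError(
            f"constant training feature {train_table.feature_names[zero[0]]!r}; "
            "standard deviation is zero")
    return StandardizationParams(train_table.feature_names, mean, std)


def standardize_apply(params: StandardizationParams, table: FeatureTable) -> FeatureTable:
    """Apply training-derived scaling; never refits on the given table."""
    if tuple(table.feature_names) != tuple(params.feature_names):
        raise DataError("feature names do not match the standardization parameters")
    return FeatureTable(
        table.subject_ids, table.labels, table.feature_names,
        (table.values - params.mean) / params.std,
        require_both_classes=table.require_both_classes)


# ---------------------------------------------------------------- configs
@dataclass(frozen=True)
class SvmConfig:
    """SVM hyperparameters; the shipped defaults are the study settings."""

    kernel: str = "rbf"
    C: float = 0.1
    gamma_mode: str = "scale"  # 1 / (n_features * mean training-feature variance)
    seed: int = 0

    def __post_init__(self):
        if self.kernel not in ("rbf", "linear"):
            raise ConfigError("SvmConfig.kernel must be 'rbf' or 'linear'")
        if self.C <= 0:
            raise ConfigError("SvmConfig.C must be positive")
        if self.gamma_mode != "scale":
            raise ConfigError("SvmConfig.gamma_mode must be 'scale'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EvalConfig:
    """Repeated-holdout settings: 2,000 stratified 80/20 cycles by default."""

    n_cycles: int = 2000
    train_fraction: float = 0.8
    seed: int = 0
    fpr_grid: tuple[float, ...] = DEFAULT_FPR_GRID

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ConfigError("EvalConfig.n_cycles must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("EvalConfig.train_fraction must lie in (0, 1)")
        grid = np.asarray(self.fpr_grid, dtype=float)
        if grid.size < 2 or (np.diff(grid) <= 0).any() or grid[0] < 0 or grid[-1] > 1:
            raise ConfigError("EvalConfig.fpr_grid must be ascending within [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fpr_grid"] = list(self.fpr_grid)
        return d


# ---------------------------------------------------------------- model
@dataclass(frozen=True)
class ModalityModel:
    """A trained single-modality classifier.

    Bundles the selected feature names, the training-derived
    standardization, the fitted SVM and the sigmoid calibration
    ``P(AD | f) = 1 / (1 + exp(-(a f + b)))`` on decision values ``f``.
    """

    feature_names: tuple[str, ...]
    standardization: StandardizationParams
    svm: SVC = field(repr=False)
    calibration_a: float
    calibration_b: float
    config: SvmConfig

    def metadata(self) -> dict:
        return {
            "features": list(self.feature_names),
            "svm": self.config.to_dict(),
            "gamma": float(self.svm._gamma) if hasattr(self.svm, "_gamma")
                     else float(self.svm.gamma),
            "calibration": {"kind": "platt_sigmoid_on_training_decision_values",
                            "a": self.calibration_a, "b": self.calibration_b},
        }


def _scale_gamma(X: np.ndarray) -> float:
    # explicit definition: 1 / (n_features * mean per-feature variance)
    return 1.0 / (X.shape[1] * X.var(axis=0).mean())


def train_modality_model(train_table: FeatureTable, selected,
                         svm: SvmConfig = SvmConfig()) -> ModalityModel:
    """Standardize on training data, fit the SVM and the Platt calibration.

    All parameters (scaling, SVM, sigmoid) derive from the training
    subjects only.  Deterministic for a fixed config.
    """
    sub = train_table.select_features(selected)
    if len(np.unique(sub.labels)) < 2:
        raise DataError("training data must contain both classes")
    params = standardize_fit(sub)
    std = standardize_apply(params, sub)
    gamma = _scale_gamma(std.values) if svm.kernel == "rbf" else "auto"
    clf = SVC(kernel=svm.kernel, C=svm.C, gamma=gamma, random_state=svm.seed)
    clf.fit(std.values, std.labels)
    f = clf.decision_function(std.values).reshape(-1, 1)
    # Platt-style sigmoid; the modest L2 penalty keeps the fit finite on
    # separable training sets while preserving monotonicity
    lr = LogisticRegression(C=1.0, solver="lbfgs")
    lr.fit(f, std.labels)
    return ModalityModel(tuple(sub.feature_names), params, clf,
                         float(lr.coef_[0, 0]), float(lr.intercept_[0]), svm)


def predict_probability(model: ModalityModel, table: FeatureTable) -> np.ndarray:
    """Per-subject probability of AD, each in [0, 1]."""
    sub = table.select_features(model.feature_names)
    std = standardize_apply(model.standardization, sub)
    f = model.svm.decision_function(std.values)
    return 1.0 / (1.0 + np.exp(-(model.calibration_a * f + model.calibration_b)))


def predict_label(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard diagnosis: AD when probability >= threshold (ties go to AD)."""
    return (np.asarray(probabilities) >= threshold).astype(np.int64)


# ---------------------------------------------------------------- metrics
def confusion_metrics(true_labels, predicted_labels) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, balanced accuracy (AD positive)."""
    y = np.asarray(true_labels, dtype=np.int64)
    yhat = np.asarray(predicted_labels, dtype=np.int64)
    if y.shape != yhat.shape:
        raise DataError("label vectors differ in length")
    n_ad = int((y == AD).sum())
    n_cn = int((y == CN).sum())
    if n_ad == 0 or n_cn == 0:
        raise DataError("both classes must be present in the true labels")
    tp = int(((y == AD) & (yhat == AD)).sum())
    tn = int(((y == CN) & (yhat == CN)).sum())
    sens = tp / n_ad
    spec = tn / n_cn
    return {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": 0.5 * (sens + spec),
    }


def roc_and_auc(true_labels, scores):
    """ROC by threshold sweep and trapezoidal AUC.

    Equivalent to the Mann-Whitney rank statistic U/(n1*n0) (ties count
    one half); that equivalence is asserted in the test suite.

    Returns ``(fpr, tpr, auc)`` with fpr/tpr anchored at (0,0) and (1,1).
    """
    y = np.asarray(true_labels, dtype=np.int64)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise DataError("labels and scores differ in length")
    if len(np.unique(y)) < 2:
        raise DataError("ROC requires both classes in the true labels")
    fpr, tpr, _ = skm.roc_curve(y, s, pos_label=AD)
    return fpr, tpr, float(skm.auc(fpr, tpr))


def _step_interp(fpr: np.ndarray, tpr: np.ndarray, grid: np.ndarray) -> np.ndarray:
    # right-continuous step through the curve knots: at grid value g the
    # highest TPR attained at FPR <= g
    idx = np.searchsorted(fpr, grid, side="right") - 1
    idx = np.clip(idx, 0, len(fpr) - 1)
    return tpr[idx]


def mean_roc(curves, fpr_grid=DEFAULT_FPR_GRID):
    """Vertical ROC averaging on a common FPR grid.

    Each curve is step-interpolated to the grid and TPRs are averaged
    pointwise.  Returns ``(grid, mean_tpr, std_tpr)``.
    """
    curves = list(curves)
    if not curves:
        raise DataError("mean_roc needs at least one curve")
    grid = np.asarray(fpr_grid, dtype=float)
    tprs = np.empty((len(curves), grid.size))
    for i, (fpr, tpr) in enumerate(curves):
        fpr = np.asarray(fpr, dtype=float)
        tpr = np.asarray(tpr, dtype=float)
        if fpr[0] > 0 or fpr[-1] < 1:
            raise DataError("each ROC curve must span FPR 0 to 1")
        tprs[i] = _step_interp(fpr, tpr, grid)
    return grid, tprs.mean(axis=0), tprs.std(axis=0)


# ------------------------------------------------------- repeated holdout
@dataclass(frozen=True)
class CycleMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)


_SCALARS = ("accuracy", "sensitivity", "specificity", "balanced_accuracy", "auc")


@dataclass(frozen=True)
class AggregateMetrics:
    """Mean +/- sd of each per-cycle scalar plus the mean ROC on a grid."""

    mean: dict[str, float]
    std: dict[str, float]
    n_cycles: int
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    std_tpr: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_cycles": self.n_cycles,
            "mean": {k: float(v) for k, v in self.mean.items()},
            "std": {k: float(v) for k, v in self.std.items()},
        }


def aggregate_cycles(cycles: list[CycleMetrics], fpr_grid=DEFAULT_FPR_GRID) -> AggregateMetrics:
    if not cycles:
        raise DataError("no cycles to aggregate")
    arr = {k: np.array([getattr(c, k) for c in cycles]) for k in _SCALARS}
    grid, mean_tpr, std_tpr = mean_roc([(c.fpr, c.tpr) for c in cycles], fpr_grid)
    return AggregateMetrics(
        mean={k: float(v.mean()) for k, v in arr.items()},
        std={k: float(v.std(ddof=0)) for k, v in arr.items()},
        n_cycles=len(cycles),
        fpr_grid=grid, mean_tpr=mean_tpr, std_tpr=std_tpr)


def _stratified_split(labels: np.ndarray, train_fraction: float,
                      rng: np.random.Generator):
    train, test = [], []
    for cls in (CN, AD):
        idx = np.flatnonzero(labels == cls)
        n_test = max(1, int(round(len(idx) * (1.0 - train_fraction))))
        if n_test >= len(idx):
            raise DataError(
                f"class {cls} has too few subjects for train fraction {train_fraction}")
        perm = rng.permutation(idx)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def repeated_holdout_evaluation(table: FeatureTable, selected,
                                svm: SvmConfig = SvmConfig(),
                                eval_config: EvalConfig = EvalConfig()):
    """Many stratified train/test cycles with a fresh model per cycle.

    Every cycle re-draws a class-stratified split (per-class test counts
    rounded to nearest, at least one test subject per class), refits
    standardization + SVM + calibration on the training portion only,
    scores the test portion and stores the cycle's metrics.  Per-cycle
    randomness derives deterministically from ``eval_config.seed``.

    Returns ``(AggregateMetrics, list[CycleMetrics])``.
    """
    sub = table.select_features(selected)
    rng = np.random.default_rng(np.random.SeedSequence(eval_config.seed))
    cycles: list[CycleMetrics] = []
    for _ in range(eval_config.n_cycles):
        train_idx, test_idx = _stratified_split(sub.labels,
                                                eval_config.train_fraction, rng)
        model = train_modality_model(sub.take_subjects(train_idx),
                                     sub.feature_names, svm)
        test = sub.take_subjects(test_idx)
        prob = predict_probability(model, test)
        cm = confusion_metrics(test.labels, predict_label(prob))
        fpr, tpr, auc = roc_and_auc(test.labels, prob)
        cycles.append(CycleMetrics(cm["accuracy"], cm["sensitivity"],
                                   cm["specificity"], cm["balanced_accuracy"],
                                   auc, fpr, tpr))
    return aggregate_cycles(cycles, eval_config.fpr_grid), cycles
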