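"""Responder labelling and the cost-sensitive KNN fatigue classifier.

A trial is a *muscle fatigue responder* for a given muscle when its MNF
regression has a negative slope with p < 0.05, and a *knee wobble responder*
when the stepwise regression of its wobble measures retains at least one term
with p < 0.05.  Wobble responders are then scored as predictors of "one or
more fatigued muscles" (PPV/NPV), and a K-nearest-neighbors classifier
(k = 27, Chebyshev distance, Kruskal-Wallis feature selection, asymmetric
misclassification costs 1:4, stratified five-fold cross-validation) predicts
any-muscle fatigue from the acceleration features alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .recordings import MUSCLES
from .stats import RegressionResult, StepwiseResult

__all__ = [
    "ResponderLabels",
    "KnnConfig",
    "PredictiveReport",
    "KnnReport",
    "label_muscle_responders",
    "label_wobble_responder",
    "predictive_values",
    "kruskal_feature_select",
    "knn_predict_fatigue",
]


@dataclass
class ResponderLabels:
    """Per-trial boolean fatigue flags (one per muscle) and the wobble flag.

    A ``None`` flag marks a missing upstream regression; such trials are
    excluded downstream with a logged count.
    """

    trial_id: str
    gmd_fatigue: Optional[bool]
    gmx_fatigue: Optional[bool]
    rf_fatigue: Optional[bool]
    wobble: Optional[bool]

    @property
    def muscle_flags(self) -> tuple[Optional[bool], ...]:
        return (self.gmd_fatigue, self.gmx_fatigue, self.rf_fatigue)

    @property
    def any_fatigue(self) -> Optional[bool]:
        flags = [f for f in self.muscle_flags if f is not None]
        if not flags:
            return None
        return any(flags)

    @property
    def n_fatigued(self) -> int:
        return sum(bool(f) for f in self.muscle_flags if f is not None)


@dataclass(frozen=True)
class KnnConfig:
    """Hyperparameters of the fatigue-from-acceleration KNN classifier."""

    k: int = 27
    metric: str = "chebyshev"
    n_features_selected: int = 10
    cost_false_negative: float = 1.0
    cost_false_positive: float = 4.0
    n_folds: int = 5
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.cost_false_negative <= 0 or self.cost_false_positive <= 0:
            raise ValueError("misclassification costs must be positive")

    @property
    def positive_threshold(self) -> float:
        """Predict positive iff the k-neighbor positive vote fraction exceeds this.

        Minimizing expected cost c_fn*P(pos) (predict negative) versus
        c_fp*(1-P(pos)) (predict positive) gives the threshold
        c_fp / (c_fp + c_fn); ties go to negative.
        """
        return self.cost_false_positive / (
            self.cost_false_positive + self.cost_false_negative
        )


def label_muscle_responders(
    regressions: Mapping[str, Optional[RegressionResult]], alpha: float = 0.05
) -> dict[str, Optional[bool]]:
    """Fatigue flag per muscle: negative slope AND slope p-value < alpha."""
    flags: dict[str, Optional[bool]] = {}
    for muscle in MUSCLES:
        reg = regressions.get(muscle)
        if reg is None or not np.isfinite(reg.slope) or not np.isfinite(reg.p_slope):
            flags[muscle] = None
        else:
            flags[muscle] = bool(reg.slope < 0 and reg.p_slope < alpha)
    return flags


def label_wobble_responder(
    stepwise: Optional[StepwiseResult], alpha: float = 0.05
) -> Optional[bool]:
    """Wobble flag: at least one retained stepwise term with p < alpha."""
    if stepwise is None:
        return None
    return any(p < alpha for p in stepwise.term_pvalues.values())


@dataclass(frozen=True)
class PredictiveReport:
    """Confusion counts with positive/negative predictive values in percent."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def ppv(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def npv(self) -> float:
        denom = self.tn + self.fn
        return 100.0 * self.tn / denom if denom else float("nan")

    def to_dict(self, ndigits: int | None = None) -> dict:
        ppv, npv = self.ppv, self.npv
        if ndigits is not None:
            ppv = round(ppv, ndigits) if np.isfinite(ppv) else ppv
            npv = round(npv, ndigits) if np.isfinite(npv) else npv
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "ppv": ppv, "npv": npv}


def predictive_values(predicted, truth) -> PredictiveReport:
    """Confusion counts, PPV and NPV of a boolean prediction vs truth."""
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.size == 0:
        raise ValueError("empty label vectors")
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have the same length")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    tn = int(np.sum(~pred & ~true))
    fn = int(np.sum(~pred & true))
    return PredictiveReport(tp=tp, fp=fp, tn=tn, fn=fn)


def kruskal_feature_select(features: np.ndarray, labels, n_keep: int) -> np.ndarray:
    """Rank features by between-class Kruskal-Wallis H; keep the n_keep smallest p.

    Features identical across all samples get H = 0, p = 1 (no information).
    Returns column indices ordered by ascending p (ties broken by descending H,
    then column index).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("feature selection needs >= 2 classes")
    n_feat = X.shape[1]
    H = np.zeros(n_feat)
    p = np.ones(n_feat)
    for j in range(n_feat):
        samples = [X[y == c, j] for c in classes]
        try:
            with np.errstate(invalid="ignore"):
                H[j], p[j] = sps.kruskal(*samples)
        except ValueError:  # all values identical
            H[j], p[j] = 0.0, 1.0
        if not (np.isfinite(H[j]) and np.isfinite(p[j])):  # all-tied degenerate
            H[j], p[j] = 0.0, 1.0
    order = np.lexsort((np.arange(n_feat), -H, p))
    return order[: min(n_keep, n_feat)]


@dataclass
class KnnReport:
    predictions: np.ndarray
    pooled: PredictiveReport
    per_fold: list[PredictiveReport] = field(default_factory=list)
    selected_features: list[np.ndarray] = field(default_factory=list)


def _prepare_fold(Xtr: np.ndarray, Xte: np.ndarray, standardize: bool):
    """Median-impute NaNs and (optionally) z-score using training statistics."""
    med = np.nanmedian(Xtr, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    Xtr = np.where(np.isfinite(Xtr), Xtr, med)
    Xte = np.where(np.isfinite(Xte), Xte, med)
    if standardize:
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    return Xtr, Xte


def knn_predict_fatigue(
    feature_matrix: np.ndarray, labels, config: KnnConfig = KnnConfig()
) -> KnnReport:
    """Cost-sensitive Chebyshev KNN under stratified cross-validation.

    Per fold: impute/standardize on the training split, select features by
    Kruskal-Wallis, take the k-neighbor positive vote fraction, and predict
    positive iff it strictly exceeds the cost threshold (ties -> negative).
    Deterministic given ``config.seed`` (fold shuffling is the only
    stochastic element).
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if X.shape[0] != y.size:
        raise ValueError("feature rows and labels differ in length")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < config.n_folds:
        raise ValueError(
            f"stratification error: smallest class has {counts.min()} trials, "
            f"need >= n_folds = {config.n_folds}"
        )

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    predictions = np.zeros(y.size, dtype=bool)
    per_fold: list[PredictiveReport] = []
    selected: list[np.ndarray] = []
    threshold = config.positive_threshold

    for train_idx, test_idx in skf.split(X, y):
        if config.k >= train_idx.size:
            raise ValueError(
                f"k = {config.k} must be smaller than the fold training size "
                f"{train_idx.size}"
            )
        Xtr, Xte = _prepare_fold(X[train_idx], X[test_idx], config.standardize)
        cols = kruskal_feature_select(Xtr, y[train_idx], config.n_features_selected)
        selected.append(cols)
        if np.ptp(Xtr[:, cols], axis=0).max() == 0:
            # zero-information fold: every neighbor set is an arbitrary tie, so
            # the vote fraction is the training-class prior
            p_pos = np.full(len(test_idx), y[train_idx].mean())
        else:
            knn = KNeighborsClassifier(n_neighbors=config.k, metric=config.metric)
            knn.fit(Xtr[:, cols], y[train_idx])
            proba = knn.predict_proba(Xte[:, cols])
            pos_col = int(np.nonzero(knn.classes_)[0][0])
            p_pos = proba[:, pos_col]
        fold_pred = p_pos > threshold
        predictions[test_idx] = fold_pred
        per_fold.append(predictive_values(fold_pred, y[test_idx]))

    pooled = predictive_values(predictions, y)
    return KnnReport(
        predictions=predictions, pooled=pooled, per_fold=per_fold, selected_features=selected
    )
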