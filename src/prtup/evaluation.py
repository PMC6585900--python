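"""Performance evaluation: confusion metrics, ROC/AUC, k-fold CV,
the (lambda, w) tuning grid and the label-shuffle permutation test.

Headline cross-validation numbers are pooled over the concatenated
held-out predictions of all folds; per-fold metrics are retained for
reporting mean +/- SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoding import EncodingConfig, PropertyTable, encode_dataset
from .model import SVMConfig
from .peptides import LabeledDataset


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts plus sensitivity, specificity, accuracy and MCC.

    Sn = TP/(TP+FN), Sp = TN/(FP+TN), Acc = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    MCC is defined as 0 when any denominator factor vanishes.
    """

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def sn(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else float("nan")

    @property
    def sp(self) -> float:
        return self.TN / (self.FP + self.TN) if (self.FP + self.TN) else float("nan")

    @property
    def acc(self) -> float:
        return (self.TP + self.TN) / (self.TP + self.TN + self.FP + self.FN)

    @property
    def mcc(self) -> float:
        d = (
            (self.TP + self.FP)
            * (self.TP + self.FN)
            * (self.TN + self.FP)
            * (self.TN + self.FN)
        )
        if d == 0:
            return 0.0
        return (self.TP * self.TN - self.FP * self.FN) / math.sqrt(d)

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "Sn": self.sn, "Sp": self.sp, "Acc": self.acc, "MCC": self.mcc,
        }


def confusion_metrics(predictions: np.ndarray, truth: np.ndarray) -> ConfusionMetrics:
    """Confusion counts and derived measures from binary label vectors."""
    pred = np.asarray(predictions).astype(int)
    y = np.asarray(truth).astype(int)
    if len(pred) == 0:
        raise EvaluationError("empty input")
    if len(pred) != len(y):
        raise EvaluationError("predictions and truth differ in length")
    return ConfusionMetrics(
        TP=int(np.sum((pred == 1) & (y == 1))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over unique-score thresholds and trapezoidal AUC.

    Equivalent to the normalized Mann-Whitney U statistic (ties count 1/2).
    """
    y = np.asarray(truth).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise EvaluationError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass
class CVResult:
    fold_metrics: list[ConfusionMetrics]
    pooled_metrics: ConfusionMetrics
    roc_points: np.ndarray
    auc: float
    seed: int
    fold_indices: list[np.ndarray] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return self.pooled_metrics.acc


def k_fold_cv(
    matrix: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    svm_config: SVMConfig = SVMConfig(),
    seed: int = 0,
) -> CVResult:
    """Seeded stratified k-fold cross-validation of the RBF SVM.

    Pooled metrics are computed over the union of held-out predictions;
    the ROC/AUC uses pooled calibrated probabilities. Labels are assigned
    by thresholding the probability at ``svm_config.tp`` (ties positive).
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels).astype(int)
    if k < 2:
        raise EvaluationError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise EvaluationError(
            f"k = {k} exceeds smallest class size {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    all_prob = np.empty(len(y))
    all_pred = np.empty(len(y), dtype=int)
    fold_metrics = []
    fold_indices = []
    for tr, te in skf.split(X, y):
        clf = SVC(
            C=svm_config.C,
            gamma=svm_config.gamma,
            kernel="rbf",
            probability=True,
            random_state=seed,
        )
        clf.fit(X[tr], y[tr])
        pos_col = int(np.where(clf.classes_ == 1)[0][0])
        prob = clf.predict_proba(X[te])[:, pos_col]
        pred = (prob >= svm_config.tp).astype(int)
        all_prob[te] = prob
        all_pred[te] = pred
        fold_metrics.append(confusion_metrics(pred, y[te]))
        fold_indices.append(te)
    pooled = confusion_metrics(all_pred, y)
    points, auc = roc_auc(all_prob, y)
    return CVResult(
        fold_metrics=fold_metrics,
        pooled_metrics=pooled,
        roc_points=points,
        auc=auc,
        seed=seed,
        fold_indices=fold_indices,
    )


def default_lambda_w_grid() -> list[tuple[int, float]]:
    """The canonical tuning grid: lambda 1..6 step 1, w 0.05..0.70 step 0.05
    (6 x 14 = 84 combinations)."""
    lambdas = range(1, 7)
    ws = [round(0.05 * i, 2) for i in range(1, 15)]
    return [(lam, w) for lam in lambdas for w in ws]


def tune_lambda_w(
    dataset: LabeledDataset,
    grid: list[tuple[int, float]] | None = None,
    cv_folds: int = 10,
    svm_config: SVMConfig = SVMConfig(),
    seed: int = 0,
    table: PropertyTable | None = None,
) -> tuple[tuple[int, float], pd.DataFrame]:
    """Encode the dataset afresh at each (lambda, w) grid point and CV it.

    Uses the full feature set (no feature selection) as the tuning stage
    does. Returns the accuracy-maximal pair (first maximum wins) and the
    whole surface.
    """
    if grid is None:
        grid = default_lambda_w_grid()
    if not grid:
        raise EvaluationError("empty (lambda, w) grid")
    if table is None:
        table = PropertyTable.default()
    rows = []
    best = (-1.0, None)
    for lam, w in grid:
        cfg = EncodingConfig(lam=lam, w=w)
        X = encode_dataset(dataset.peptides, cfg, table)
        res = k_fold_cv(X, dataset.labels, k=cv_folds, svm_config=svm_config, seed=seed)
        rows.append({"lambda": lam, "w": w, "cv_accuracy": res.accuracy})
        if res.accuracy > best[0]:
            best = (res.accuracy, (lam, w))
    return best[1], pd.DataFrame(rows)


@dataclass
class PermutationResult:
    observed_acc: float
    permuted_accs: np.ndarray
    exceed_count: int
    n_shuffles: int

    @property
    def p_value(self) -> float:
        return self.exceed_count / self.n_shuffles

    @property
    def p_display(self) -> str:
        if self.exceed_count == 0:
            return f"p < {1 / self.n_shuffles:g}"
        return f"p = {self.p_value:g}"


def permutation_test(
    matrix: np.ndarray,
    labels: np.ndarray,
    svm_config: SVMConfig = SVMConfig(),
    n_shuffles: int = 1000,
    cv_folds: int = 10,
    seed: int = 0,
) -> PermutationResult:
    """Label-shuffle significance test of the cross-validated accuracy.

    The observed accuracy comes from CV on the true labels; each shuffle
    permutes the labels uniformly at random and repeats the CV. The
    p-value is the fraction of shuffles whose accuracy exceeds the
    observed one, displayed as "< 1/N" when no shuffle does.
    """
    if n_shuffles < 1:
        raise EvaluationError("n_shuffles must be >= 1")
    y = np.asarray(labels).astype(int)
    observed = k_fold_cv(matrix, y, k=cv_folds, svm_config=svm_config, seed=seed).accuracy
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_shuffles)
    for i in range(n_shuffles):
        y_perm = rng.permutation(y)
        permuted[i] = k_fold_cv(
            matrix, y_perm, k=cv_folds, svm_config=svm_config, seed=seed
        ).accuracy
    exceed = int(np.sum(permuted > observed))
    return PermutationResult(
        observed_acc=observed,
        permuted_accs=permuted,
        exceed_count=exceed,
        n_shuffles=n_shuffles,
    )
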