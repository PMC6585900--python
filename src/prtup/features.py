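"""F-score feature ranking and incremental feature selection (IFS).

Each feature gets a univariate F-score — the ratio of between-class to
within-class variability:

    F = [(mean_pos - mean)^2 + (mean_neg - mean)^2]
        / [var_pos_unbiased + var_neg_unbiased]

(the definition computed by the widely used LIBSVM `fselect.py` tool).
Features are ranked by descending F-score; IFS then grows nested subsets
along the ranking and cross-validates an SVM on each, keeping the subset
with maximal accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


class FeatureSelectionError(ValueError):
    pass


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if pos.sum() == 0 or neg.sum() == 0:
        raise FeatureSelectionError("both classes must be non-empty")
    if pos.sum() < 2 or neg.sum() < 2:
        raise FeatureSelectionError("each class needs >= 2 samples")
    return pos, neg


def f_score(values: np.ndarray, labels: np.ndarray) -> float:
    """F-score of a single feature column.

    Returns ``inf`` when the classes are perfectly and constantly separated
    (positive numerator, zero within-class variance) and 0.0 when the class
    means both equal the overall mean.
    """
    values = np.asarray(values, dtype=float)
    pos, neg = _check_classes(labels)
    return float(f_scores(values[:, None], labels)[0])


def f_scores(matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised column-wise F-scores for an encoded dataset."""
    X = np.asarray(matrix, dtype=float)
    pos, neg = _check_classes(labels)
    xp, xn = X[pos], X[neg]
    mean_all = X.mean(axis=0)
    mean_p = xp.mean(axis=0)
    mean_n = xn.mean(axis=0)
    num = (mean_p - mean_all) ** 2 + (mean_n - mean_all) ** 2
    den = ((xp - mean_p) ** 2).sum(axis=0) / (len(xp) - 1) + (
        (xn - mean_n) ** 2
    ).sum(axis=0) / (len(xn) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[num == 0] = 0.0
    out[(num > 0) & (den == 0)] = np.inf
    return out


@dataclass(frozen=True)
class FScoreRanking:
    """Per-feature F-scores and the permutation sorting them descending.

    Ties are broken by ascending feature index (stable sort), so the
    ranking is deterministic.
    """

    scores: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.order):
            raise FeatureSelectionError("scores/order length mismatch")

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def rank_features(matrix: np.ndarray, labels: np.ndarray) -> FScoreRanking:
    scores = f_scores(matrix, labels)
    # argsort is ascending; negate finite comparison via descending stable sort
    order = np.argsort(-scores, kind="stable")
    return FScoreRanking(scores=scores, order=order)


@dataclass(frozen=True)
class IFSResult:
    subset_sizes: np.ndarray
    accuracies: np.ndarray
    optimal_size: int
    optimal_indices: np.ndarray

    @property
    def optimal_accuracy(self) -> float:
        i = int(np.where(self.subset_sizes == self.optimal_size)[0][0])
        return float(self.accuracies[i])


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, folds, C: float, gamma: float
) -> float:
    correct = 0
    for train_idx, test_idx in folds:
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(X[train_idx], y[train_idx])
        correct += int((clf.predict(X[test_idx]) == y[test_idx]).sum())
    return correct / len(y)


def incremental_feature_selection(
    matrix: np.ndarray,
    labels: np.ndarray,
    ranking: FScoreRanking,
    cv_folds: int = 10,
    stride: int = 1,
    C: float = 1.0,
    gamma: float = 0.125,
    seed: int = 0,
) -> IFSResult:
    """Grow nested feature subsets along the ranking; keep the best.

    Subset sizes are 1, 1+stride, 1+2*stride, ... plus always the full set.
    The same seeded stratified folds are reused at every size (paired
    comparison). Ties in the accuracy curve resolve to the smaller subset.
    The method's canonical protocol is stride 1 over all features; larger
    strides give a coarse curve for desk-scale runs.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if len(ranking.order) != X.shape[1]:
        raise FeatureSelectionError(
            f"ranking covers {len(ranking.order)} features, matrix has {X.shape[1]}"
        )
    if stride < 1:
        raise FeatureSelectionError("stride must be >= 1")
    n_features = X.shape[1]
    sizes = list(range(1, n_features + 1, stride))
    if sizes[-1] != n_features:
        sizes.append(n_features)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    accs = np.empty(len(sizes))
    for i, k in enumerate(sizes):
        cols = ranking.order[:k]
        accs[i] = _cv_accuracy(X[:, cols], y, folds, C, gamma)
    best = int(np.argmax(accs))  # first maximum -> smallest subset under ties
    optimal_size = sizes[best]
    return IFSResult(
        subset_sizes=np.asarray(sizes),
        accuracies=accs,
        optimal_size=optimal_size,
        optimal_indices=ranking.order[:optimal_size].copy(),
    )
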