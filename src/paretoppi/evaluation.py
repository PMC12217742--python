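"""Classification/regression metrics, stratified CV, best-model selection
and the Pareto-front ensemble prediction rules.

Classification metrics are computed in closed form from (possibly
fractional) confusion counts, so that printed sensitivity/specificity
rates and class sizes can be turned back into full metric rows for
external baselines. Ensembles combine Pareto-front members that pass a
quality filter (CV accuracy > 0.80 for classifiers, CV Spearman
correlation > 0.2 for regressors); per sample, a member only votes when
fewer than half of its selected features are missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    """Fractional counts are allowed (rate-derived reconstructions)."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float | None
    specificity: float | None
    sensitivity: float | None
    precision: float | None
    f1: float | None
    f2: float | None
    roc_auc: float | None = None


@dataclass(frozen=True)
class RegressionMetrics:
    rmse: float
    rae: float | None
    rrse: float | None
    spearman_rho: float | None
    spearman_p: float | None


def f_beta(precision: float | None, recall: float | None, beta: float) -> float | None:
    if precision is None or recall is None or precision + recall == 0:
        return None
    b2 = beta * beta
    denom = b2 * precision + recall
    return None if denom == 0 else (1 + b2) * precision * recall / denom


def metrics_from_counts(c: ConfusionCounts) -> ClassificationMetrics:
    """Closed-form metrics; undefined ratios are reported missing, not 0."""

    def ratio(num: float, den: float) -> float | None:
        return None if den == 0 else num / den

    accuracy = ratio(c.tp + c.tn, c.n)
    sensitivity = ratio(c.tp, c.tp + c.fn)
    specificity = ratio(c.tn, c.tn + c.fp)
    precision = ratio(c.tp, c.tp + c.fp)
    return ClassificationMetrics(
        accuracy=accuracy,
        specificity=specificity,
        sensitivity=sensitivity,
        precision=precision,
        f1=f_beta(precision, sensitivity, 1.0),
        f2=f_beta(precision, sensitivity, 2.0),
    )


def metrics_from_rates(sensitivity: float, specificity: float,
                       n_pos: float, n_neg: float) -> ClassificationMetrics:
    """Reconstruct a full metric row from printed rates and class counts."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class counts must be positive")
    return metrics_from_counts(ConfusionCounts(
        tp=sensitivity * n_pos,
        fn=(1 - sensitivity) * n_pos,
        tn=specificity * n_neg,
        fp=(1 - specificity) * n_neg,
    ))


def regression_metrics(actual, predicted) -> RegressionMetrics:
    """RMSE, relative absolute error, root relative squared error and
    Spearman correlation (with two-sided p) of a prediction set."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    resid = a - p
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    dev = a - a.mean()
    sum_abs_dev = np.abs(dev).sum()
    sum_sq_dev = (dev ** 2).sum()
    rae = None if sum_abs_dev == 0 else float(np.abs(resid).sum() / sum_abs_dev)
    rrse = None if sum_sq_dev == 0 else float(np.sqrt((resid ** 2).sum() / sum_sq_dev))
    rho = pval = None
    if a.size >= 3 and np.ptp(a) > 0 and np.ptp(p) > 0:
        res = spearmanr(a, p)
        if not math.isnan(res.statistic):
            rho, pval = float(res.statistic), float(res.pvalue)
    return RegressionMetrics(rmse=rmse, rae=rae, rrse=rrse,
                             spearman_rho=rho, spearman_p=pval)


def stratified_kfold(labels, k: int, seed: int) -> list[np.ndarray]:
    """Shuffled stratified fold assignment; returns per-fold test indices."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(y)), y)]


# ---------------------------------------------------------------------------
# Front-member selection and ensemble prediction.
#
# Members are duck-typed: they need .weighted_fitness, .feature_indices,
# .genes, plus predict_proba(X) (classifiers, positive-class probability)
# or predict(X) (regressors) and cv_accuracy / cv_correlation attributes.
# ---------------------------------------------------------------------------


def select_best_model(front_members: list):
    """Highest weighted fitness; ties broken by fewer selected features,
    then lexicographically smaller genome."""
    if not front_members:
        raise ValueError("empty front")
    return min(
        front_members,
        key=lambda m: (-m.weighted_fitness, len(m.feature_indices), tuple(m.genes)),
    )


def _votes_mask(member, missing_mask: np.ndarray, missing_rule: float) -> np.ndarray:
    """Per sample: True when the member may vote (< missing_rule fraction of
    its selected features are missing)."""
    sel = np.asarray(member.feature_indices, dtype=int)
    frac_missing = missing_mask[:, sel].mean(axis=1)
    return frac_missing < missing_rule


def ensemble_classify(
    front_members: list,
    X: np.ndarray,
    missing_mask: np.ndarray | None = None,
    accuracy_threshold: float = 0.80,
    missing_rule: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Majority-vote ensemble over quality-filtered front members.

    Returns (labels, mean positive-class probabilities, unpredictable flag).
    Even-vote ties are decided by mean probability >= 0.5. Samples with no
    eligible voter are flagged unpredictable (label -1, probability NaN).
    """
    if not front_members:
        raise ValueError("empty front")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if missing_mask is None:
        missing_mask = np.isnan(X)
    eligible = [m for m in front_members if m.cv_accuracy > accuracy_threshold]
    probs = np.full((len(eligible), n), np.nan)
    votes = np.zeros((len(eligible), n), dtype=bool)
    for j, member in enumerate(eligible):
        votes[j] = _votes_mask(member, missing_mask, missing_rule)
        if votes[j].any():
            probs[j, votes[j]] = member.predict_proba(X[votes[j]])
    n_voters = votes.sum(axis=0)
    unpredictable = n_voters == 0
    mean_prob = np.full(n, np.nan)
    labels = np.full(n, -1, dtype=int)
    ok = ~unpredictable
    if ok.any():
        totals = np.where(votes, np.nan_to_num(probs), 0.0).sum(axis=0)
        mean_prob[ok] = totals[ok] / n_voters[ok]
        pos_votes = np.where(votes, probs >= 0.5, False).sum(axis=0)
        maj = np.zeros(n, dtype=int)
        maj[pos_votes * 2 > n_voters] = 1
        tie = (pos_votes * 2 == n_voters) & ok
        maj[tie] = (mean_prob[tie] >= 0.5).astype(int)
        labels[ok] = maj[ok]
    return labels, mean_prob, unpredictable


def ensemble_regress(
    front_members: list,
    X: np.ndarray,
    missing_mask: np.ndarray | None = None,
    correlation_threshold: float = 0.2,
    missing_rule: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean prediction over members with CV correlation above threshold,
    subject to the per-sample missingness rule. Returns (predictions,
    unpredictable flag)."""
    if not front_members:
        raise ValueError("empty front")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if missing_mask is None:
        missing_mask = np.isnan(X)
    eligible = [
        m for m in front_members
        if m.cv_correlation is not None and m.cv_correlation > correlation_threshold
    ]
    preds = np.full((len(eligible), n), np.nan)
    for j, member in enumerate(eligible):
        can_vote = _votes_mask(member, missing_mask, missing_rule)
        if can_vote.any():
            preds[j, can_vote] = member.predict(X[can_vote])
    counts = (~np.isnan(preds)).sum(axis=0)
    totals = np.nan_to_num(preds).sum(axis=0)
    mean_pred = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    unpredictable = counts == 0
    return mean_pred, unpredictable
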