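"""ROC/AUC machinery, optimal operating points, feature-group ablation, and
case/control score comparison.

AUC is computed as the Mann–Whitney concordance probability
P(score_pos > score_neg) + 0.5 * P(equal) via average ranks, which handles
ties exactly and agrees with trapezoidal integration of the ROC curve. The
optimal threshold is the point on the ROC curve farthest from the diagonal,
i.e. the threshold maximizing Youden's J = TPR - FPR.

Feature-group ablation measures the contribution of a group of (typically
highly correlated) features as the AUC drop from retraining without the
group, replicated over independent negative subsamples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class RocCurve:
    """Thresholds with their (FPR, TPR) operating points, plus AUC.

    Thresholds are in decreasing order (calls are score >= threshold), so FPR
    and TPR are nondecreasing along the curve. The first entry is an +inf
    sentinel where nothing is called pathogenic.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> RocCurve:
    """ROC curve and tie-aware AUC. Both classes must be present."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    # Mann-Whitney concordance: mean rank of positives
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def optimal_threshold(roc: RocCurve) -> float:
    """Threshold whose ROC point lies farthest from the diagonal.

    Maximizes TPR - FPR (Youden's J; equivalent to the largest perpendicular
    distance to the chance line). Ties resolve to the lowest such threshold.
    """
    j = roc.tpr - roc.fpr
    best = j.max()
    candidates = roc.thresholds[np.isclose(j, best)]
    finite = candidates[np.isfinite(candidates)]
    pick = finite if finite.size else candidates
    return float(pick.min())


@dataclass
class AblationResult:
    """Replicate AUC drops from excluding one feature group."""

    group: str
    delta_aucs: np.ndarray
    median: float
    iqr: tuple[float, float]

    @classmethod
    def from_deltas(cls, group: str, deltas: np.ndarray) -> "AblationResult":
        q1, q3 = np.percentile(deltas, [25, 75])
        return cls(
            group=group,
            delta_aucs=np.asarray(deltas, float),
            median=float(np.median(deltas)),
            iqr=(float(q1), float(q3)),
        )


TrainFn = Callable[[pd.DataFrame, np.ndarray, int], Callable[[pd.DataFrame], np.ndarray]]


def ablate_group(
    train_fn: TrainFn,
    X: pd.DataFrame,
    y: Sequence[int],
    group: Sequence[str],
    *,
    n_reps: int = 15,
    neg_per_pos: float = 10.0,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> AblationResult:
    """AUC contribution of a feature group by cross-one-group-out retraining.

    For each replicate: subsample negatives to ``neg_per_pos`` per positive
    (matching the roughly 1:10 positive:negative benchmark ratio), split
    train/test, fit the model with and without the group via ``train_fn``,
    and record delta AUC = AUC(full) - AUC(without group) on the test split.

    ``train_fn(X_train, y_train, seed)`` must return a scoring callable.
    """
    y = np.asarray(y, dtype=int)
    group = list(group)
    if not group:
        raise ValueError("feature group is empty")
    missing = [g for g in group if g not in X.columns]
    if missing:
        raise KeyError(f"group feature(s) absent from X: {missing}")
    kept = [c for c in X.columns if c not in group]
    if not kept:
        raise ValueError("feature group covers every feature; nothing to ablate against")

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    n_neg_take = min(len(neg_idx), int(round(neg_per_pos * len(pos_idx))))

    deltas = np.empty(n_reps)
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_rng = np.random.default_rng(rep_seed)
        neg_take = rep_rng.choice(neg_idx, size=n_neg_take, replace=False)
        idx = np.concatenate([pos_idx, neg_take])
        idx = rep_rng.permutation(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test, tr = idx[:n_test], idx[n_test:]
        Xtr, ytr, Xte, yte = X.iloc[tr], y[tr], X.iloc[test], y[test]

        full = train_fn(Xtr, ytr, rep_seed)
        reduced = train_fn(Xtr[kept], ytr, rep_seed)
        auc_full = roc_auc(yte, full(Xte)).auc
        auc_red = roc_auc(yte, reduced(Xte[kept])).auc
        deltas[rep] = auc_full - auc_red
    return AblationResult.from_deltas("+".join(group), deltas)


def compare_case_control(
    scores_cases: Sequence[float], scores_controls: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test between case and control score sets."""
    a = np.asarray(scores_cases, dtype=float)
    b = np.asarray(scores_controls, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
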