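"""ROC/AUC statistics: Mann-Whitney AUC, bootstrap CIs, and the DeLong test.

The AUC is computed as the Mann-Whitney probability estimate (ties counted as
one half), which makes it invariant to strictly increasing transforms of the
scores.  Confidence intervals are percentile bootstrap intervals with
class-stratified resampling, so every replicate contains both classes.  Two
correlated ROC curves evaluated on the same subjects are compared with the
DeLong structural-components estimator of the variance of the AUC difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ScoredSet:
    """Model scores paired with binary outcome labels on one evaluation set."""

    scores: np.ndarray
    labels: np.ndarray
    origin: str = ""

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be 1-d arrays of equal length")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(int))


@dataclass(frozen=True)
class RocComparison:
    """Paired AUCs with bootstrap CIs and the DeLong statistic."""

    auc_a: float
    auc_b: float
    ci_a: tuple
    ci_b: tuple
    delta: float            # auc_b - auc_a
    z: float
    p: float
    n_boot: int
    degenerate: bool = False
    label_a: str = ""
    label_b: str = ""


def _split_scores(labels, scores):
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-d arrays of equal length")
    if not ((labels == 0) | (labels == 1)).all():
        raise ValueError("labels must be binary 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC requires both outcome classes to be present")
    return pos, neg


def auc(labels, scores) -> float:
    """Mann-Whitney AUC with mid-rank tie handling.

    Equals the probability that a random positive outscores a random negative,
    counting ties as 1/2.
    """
    pos, neg = _split_scores(labels, scores)
    n1, n0 = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def bootstrap_ci(labels, scores, n_boot: int = 2000, level: float = 0.95,
                 seed: int = 0) -> tuple:
    """Percentile bootstrap interval for the AUC, resampling within classes.

    Stratified (class-wise) resampling guarantees both classes in every
    replicate.  Returns ``(lower, upper)``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is small for a percentile interval", stacklevel=2
        )
    pos, neg = _split_scores(labels, scores)
    rng = np.random.default_rng(seed)
    n1, n0 = len(pos), len(neg)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = pos[rng.integers(0, n1, n1)]
        n = neg[rng.integers(0, n0, n0)]
        ranks = stats.rankdata(np.concatenate([p, n]))
        aucs[b] = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _placements(pos, neg):
    """DeLong structural components (placement values) for one score vector.

    ``v10[i]`` is the fraction of negatives a positive ``i`` outscores (ties
    1/2); ``v01[j]`` the fraction of positives a negative ``j`` is outscored
    by.  Mid-ranks give the tie convention.
    """
    n1, n0 = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks[:n1] - ranks_pos) / n0
    v01 = 1.0 - (ranks[n1:] - ranks_neg) / n1
    return v10, v01


def delong_variance(labels, scores) -> float:
    """DeLong variance estimate of a single AUC."""
    pos, neg = _split_scores(labels, scores)
    v10, v01 = _placements(pos, neg)
    return float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))


def delong_test(set_a: ScoredSet, set_b: ScoredSet, n_boot: int = 2000,
                level: float = 0.95, seed: int = 0) -> RocComparison:
    """Compare two correlated ROC curves scored on the same subjects.

    Both score vectors must refer to the same records in the same order
    (paired design).  The variance of ``auc_b - auc_a`` is estimated from the
    structural components; the two-sided p-value is normal.  If that variance
    is zero (e.g. identical scores), the comparison is flagged degenerate and
    ``p = 1``.
    """
    if not np.array_equal(set_a.labels, set_b.labels):
        raise ValueError("paired DeLong test requires identical labels in order")
    labels = set_a.labels
    pos_mask = labels == 1
    a_pos, a_neg = set_a.scores[pos_mask], set_a.scores[~pos_mask]
    b_pos, b_neg = set_b.scores[pos_mask], set_b.scores[~pos_mask]
    v10_a, v01_a = _placements(a_pos, a_neg)
    v10_b, v01_b = _placements(b_pos, b_neg)
    n1, n0 = len(a_pos), len(a_neg)

    auc_a = float(np.mean(v10_a))
    auc_b = float(np.mean(v10_b))
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / n1 + s01 / n0
    var_delta = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = auc_b - auc_a

    degenerate = var_delta <= 0
    if degenerate:
        z, p = 0.0, 1.0
    else:
        z = delta / np.sqrt(var_delta)
        p = float(2.0 * stats.norm.sf(abs(z)))

    if n_boot == 0:   # test only, no interval requested (e.g. simulation loops)
        ci_a = ci_b = (float("nan"), float("nan"))
    else:
        ci_a = bootstrap_ci(labels, set_a.scores, n_boot=n_boot, level=level,
                            seed=seed)
        ci_b = bootstrap_ci(labels, set_b.scores, n_boot=n_boot, level=level,
                            seed=seed + 1)
    return RocComparison(
        auc_a=auc_a, auc_b=auc_b, ci_a=ci_a, ci_b=ci_b, delta=delta,
        z=float(z), p=float(p), n_boot=n_boot, degenerate=degenerate,
        label_a=set_a.origin, label_b=set_b.origin,
    )
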