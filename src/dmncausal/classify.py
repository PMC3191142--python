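"""Group statistics on the hub index and ROC cohort discrimination.

The hub index D_outer/D_all drops in the AD-like group, so the patient
class scores *lower*: the ROC convention here is ``positive_when="low"``
(a subject is called positive — diseased — when its score falls below the
threshold).  The optimal cutoff maximizes Youden's J = sensitivity +
specificity - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocPoint:
    """One threshold of the ROC sweep with its true-positive rate
    (sensitivity) and true-negative rate (specificity)."""

    threshold: float
    sensitivity: float
    specificity: float


def one_tailed_two_sample_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    direction: Literal["a_greater", "b_greater"] = "a_greater",
) -> float:
    """One-tailed Welch two-sample t-test p-value.

    Welch's unequal-variance form is used; ``direction`` states the
    alternative (e.g. ``a_greater`` tests mean(a) > mean(b)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        raise ValueError("zero variance in both groups")
    alternative = "greater" if direction == "a_greater" else "less"
    res = scipy.stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def anova_oneway(groups: Sequence[Sequence[float]]) -> float:
    """One-way ANOVA F-test p-value across two or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.var(a) == 0.0 for a in arrays):
        raise ValueError("degenerate (zero) variance in every group")
    return float(scipy.stats.f_oneway(*arrays).pvalue)


def roc_curve(
    scores_negatives: Sequence[float],
    scores_positives: Sequence[float],
    positive_when: Literal["low", "high"] = "low",
) -> list[RocPoint]:
    """ROC sweep over candidate thresholds.

    Candidate thresholds are the midpoints between adjacent pooled unique
    scores plus -inf and +inf endpoints.  With ``positive_when="low"`` a
    subject is called positive when its score is strictly below the
    threshold (the patient group scores lower); with ``"high"``, strictly
    above.
    """
    neg = np.asarray(scores_negatives, dtype=float)
    pos = np.asarray(scores_positives, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both score lists must be nonempty")
    pooled = np.unique(np.concatenate([neg, pos]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.array([])
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    points = []
    for thr in thresholds:
        points.append(evaluate_threshold(neg, pos, thr, positive_when))
    return points


def evaluate_threshold(
    scores_negatives: Sequence[float],
    scores_positives: Sequence[float],
    threshold: float,
    positive_when: Literal["low", "high"] = "low",
) -> RocPoint:
    """Sensitivity/specificity of one threshold."""
    neg = np.asarray(scores_negatives, dtype=float)
    pos = np.asarray(scores_positives, dtype=float)
    if positive_when == "low":
        called_pos = pos < threshold
        called_neg = neg >= threshold
    elif positive_when == "high":
        called_pos = pos > threshold
        called_neg = neg <= threshold
    else:
        raise ValueError(f"unknown positive_when {positive_when!r}")
    return RocPoint(
        threshold=float(threshold),
        sensitivity=float(np.mean(called_pos)),
        specificity=float(np.mean(called_neg)),
    )


def optimal_cutoff(roc: Sequence[RocPoint]) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken by higher specificity, then by lower threshold
    (logged when invoked).
    """
    if not roc:
        raise ValueError("empty ROC curve")
    best = None
    tie = False
    for pt in roc:
        j = pt.sensitivity + pt.specificity - 1.0
        key = (j, pt.specificity, -pt.threshold)
        if best is None or key > best[0]:
            best = (key, pt)
            tie = False
        elif key[0] == best[0][0]:
            tie = True
    if tie:
        logger.info("optimal_cutoff: tie on Youden's J broken by specificity/threshold")
    pt = best[1]
    return pt.threshold, pt.sensitivity, pt.specificity
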