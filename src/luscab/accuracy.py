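"""Diagnostic test accuracy: 2x2 tables, Se/Sp/PPV/NPV, ROC/AUC with DeLong CI.

Test-positivity is score >= cutoff throughout (the 3.5-point cutoff is
attainable exactly because scores move in half-point steps); "below the
cutoff" is the rule-out side.  The AUC is the Mann-Whitney probability of
correct pairwise ranking with ties counted 1/2, its 95% confidence interval
the DeLong (1988) nonparametric variance with a normal approximation,
truncated to [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .scoring import ValidationError

__all__ = [
    "ConfusionMatrix",
    "DiagnosticStats",
    "ROCResult",
    "confusion_at_cutoff",
    "diagnostic_stats",
    "reconstruct_confusion",
    "roc_auc",
    "auc_mann_whitney",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts at one score cutoff for one binary outcome."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValidationError("confusion matrix must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class DiagnosticStats:
    """Se/Sp/PPV/NPV as proportions; a zero-denominator ratio is None, never 0."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve and AUC with a DeLong 95% confidence interval.

    ``thresholds`` run from +inf down to -inf, placed midway between
    consecutive distinct observed scores, so (fpr, tpr) climbs from (0, 0)
    to (1, 1).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float


def confusion_at_cutoff(scores, outcomes, cutoff: float) -> ConfusionMatrix:
    """Cross-tabulate score >= cutoff against a binary outcome."""
    s = np.asarray(scores, dtype=float)
    o = np.asarray(outcomes, dtype=bool)
    if s.ndim != 1 or o.ndim != 1 or s.size != o.size:
        raise ValidationError(
            f"scores and outcomes must be 1-d of equal length, got {s.shape} and {o.shape}"
        )
    if s.size == 0:
        raise ValidationError("empty input")
    pos = s >= cutoff
    return ConfusionMatrix(
        tp=int(np.sum(pos & o)),
        fp=int(np.sum(pos & ~o)),
        tn=int(np.sum(~pos & ~o)),
        fn=int(np.sum(~pos & o)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def diagnostic_stats(cm: ConfusionMatrix) -> DiagnosticStats:
    """Se, Sp, PPV and NPV of a 2x2 table; undefined ratios are None."""
    return DiagnosticStats(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_confusion(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Rebuild the integer 2x2 table behind printed Se/Sp and group sizes.

    tp = round(Se * n_pos), tn = round(Sp * n_neg), rounding half away from
    zero.  If a printed proportion is inconsistent with every integer table
    (the rounded count is more than half a unit from the exact product) a
    warning is emitted; the value is never adjusted silently.
    """
    if not 0 <= sensitivity <= 1 or not 0 <= specificity <= 1:
        raise ValidationError("sensitivity and specificity must be in [0, 1]")
    if n_pos < 0 or n_neg < 0:
        raise ValidationError("group sizes must be non-negative")
    tp = _round_half_away(sensitivity * n_pos)
    tn = _round_half_away(specificity * n_neg)
    # A printed proportion is consistent when some integer count reproduces
    # it to the printed resolution (one decimal of a percent = 0.005 as a
    # proportion, half a unit in the last printed place).
    for label, count, printed, denom in (
        ("sensitivity", tp, sensitivity, n_pos),
        ("specificity", tn, specificity, n_neg),
    ):
        if denom > 0 and abs(count / denom - printed) > 0.005:
            warnings.warn(
                f"printed {label} {printed} is inconsistent with any integer count"
                f" out of {denom} (closest: {count}/{denom} = {count / denom:.4f})",
                stacklevel=2,
            )
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)


def _split_scores(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    o = np.asarray(outcomes, dtype=bool)
    if s.ndim != 1 or o.ndim != 1 or s.size != o.size:
        raise ValidationError(
            f"scores and outcomes must be 1-d of equal length, got {s.shape} and {o.shape}"
        )
    pos, neg = s[o], s[~o]
    if pos.size == 0:
        raise ValidationError("no positive outcomes: AUC is undefined")
    if neg.size == 0:
        raise ValidationError("no negative outcomes: AUC is undefined")
    return pos, neg


def auc_mann_whitney(scores, outcomes) -> float:
    """AUC as the pairwise probability P(score_pos > score_neg) + P(tie)/2."""
    pos, neg = _split_scores(scores, outcomes)
    # Midranks over the pooled sample give the U statistic without the
    # quadratic pairwise loop.
    pooled = np.concatenate([pos, neg])
    ranks = sps.rankdata(pooled)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong (1988) variance of the empirical AUC via placement values."""
    m, n = pos.size, neg.size
    # placement of each positive among negatives and vice versa
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, x in enumerate(pos):
        v10[i] = (np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n
    for j, y in enumerate(neg):
        v01[j] = (np.sum(pos > y) + 0.5 * np.sum(pos == y)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_auc(scores, outcomes, ci_level: float = 0.95) -> ROCResult:
    """Empirical ROC curve with Mann-Whitney AUC and DeLong 95% CI.

    Thresholds are placed midway between consecutive distinct observed
    scores, with +/-inf endpoints, and the curve is enumerated at each.
    """
    pos, neg = _split_scores(scores, outcomes)
    s = np.concatenate([pos, neg])
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    tpr = np.array([np.mean(pos >= t) for t in thresholds])
    fpr = np.array([np.mean(neg >= t) for t in thresholds])
    auc = auc_mann_whitney(scores, outcomes)
    var = _delong_variance(pos, neg)
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    half = z * math.sqrt(var)
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        auc_ci_low=max(0.0, auc - half),
        auc_ci_high=min(1.0, auc + half),
    )
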