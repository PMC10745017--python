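"""Descriptive and univariate comparison statistics for cohort tables.

Quantitative variables are summarised as median and interquartile range
(percentiles by linear interpolation between order statistics) or mean and
standard deviation, and compared across groups with the Kruskal-Wallis
rank test.  Categorical variables are compared with Pearson's chi-square
(no continuity correction) when every expected cell count is at least 5,
otherwise with Fisher's exact test; the two-sided Fisher p-value sums the
probabilities of all tables no more probable than the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .scoring import ValidationError

__all__ = [
    "Summary",
    "GroupComparison",
    "summarize",
    "compare_groups",
    "compare_categorical",
    "spearman_correlation",
]


@dataclass(frozen=True)
class Summary:
    """Location/spread summary of one quantitative variable."""

    n: int
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    mean: float | None = None
    sd: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    variable_name: str
    groups: list[str]
    summaries: dict = field(default_factory=dict)  # group label -> Summary or counts
    test_name: str = ""
    statistic: float | None = None
    p_value: float | None = None


def summarize(values: Sequence[float], kind: str = "median_iqr") -> Summary:
    """Median + IQR (default) or mean + SD of a non-empty sample.

    Quartiles use linear interpolation between order statistics (numpy's
    default, "type 7"), the convention the synthetic-cohort calibration
    targets also use.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    if kind == "median_iqr":
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return Summary(n=x.size, median=float(med), q1=float(q1), q3=float(q3))
    if kind == "mean_sd":
        return Summary(
            n=x.size,
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        )
    raise ValidationError(f"kind must be 'median_iqr' or 'mean_sd', got {kind!r}")


def compare_groups(
    values_by_group: dict[str, Sequence[float]], variable_name: str = ""
) -> GroupComparison:
    """Kruskal-Wallis comparison of a quantitative variable across groups."""
    if len(values_by_group) < 2:
        raise ValidationError("at least two groups are required")
    arrays = {}
    for label, vals in values_by_group.items():
        a = np.asarray(vals, dtype=float)
        if a.size == 0:
            raise ValidationError(f"group {label!r} is empty")
        arrays[label] = a
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        # all observations identical: H = 0 by convention, p = 1
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*arrays.values())
    return GroupComparison(
        variable_name=variable_name,
        groups=list(arrays),
        summaries={g: summarize(a) for g, a in arrays.items()},
        test_name="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
    )


def compare_categorical(counts, variable_name: str = "", group_labels=None) -> GroupComparison:
    """Chi-square or Fisher's exact comparison of a contingency table.

    Pearson chi-square without continuity correction when all expected
    counts are >= 5; otherwise Fisher's exact test for 2x2 tables, or
    chi-square with a warning for larger sparse tables.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValidationError(f"contingency table must be at least 2x2, got shape {table.shape}")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ValidationError("contingency table must hold non-negative integers")
    if table.sum() == 0:
        raise ValidationError("contingency table is all zeros")
    table = table.astype(int)
    expected = sps.contingency.expected_freq(table)
    labels = list(group_labels) if group_labels is not None else [
        f"group_{j}" for j in range(table.shape[1])
    ]
    if np.all(expected >= 5):
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        test = "chi_square"
    elif table.shape == (2, 2):
        stat, p = sps.fisher_exact(table)
        test = "fisher_exact"
    else:
        warnings.warn(
            "expected count < 5 in a table larger than 2x2; falling back to chi-square",
            stacklevel=2,
        )
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        test = "chi_square"
    return GroupComparison(
        variable_name=variable_name,
        groups=labels,
        summaries={lab: table[:, j].tolist() for j, lab in enumerate(labels)},
        test_name=test,
        statistic=float(stat),
        p_value=float(p),
    )


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float | None, float | None]:
    """Spearman rank correlation with average ranks for ties; p by t-approximation.

    A constant input vector makes the correlation undefined: returns
    (None, None) with a warning rather than a spurious number.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or xa.size != ya.size:
        raise ValidationError("x and y must be 1-d of equal length")
    if xa.size < 3:
        raise ValidationError("at least three pairs are required")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        warnings.warn("constant input: Spearman correlation is undefined", stacklevel=2)
        return None, None
    rho, p = sps.spearmanr(xa, ya)
    return float(rho), float(p)
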