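"""Confusion-count benchmarking against a full-depth truth set.

In the downsampling experiment the full dataset's gene (or variant) set is
taken as the truth set T; a subsample's set A is scored with

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = TP / (TP + 1/2 (FP + FN))

where TP = |A ∩ T|, FP = |A \\ T|, FN = |T \\ A|.  The F form above equals the
harmonic mean 2PR/(P+R) wherever both P and R are defined.  Degenerate
denominators (empty subsample or empty truth) are reported as missing (NaN)
rather than 0 to distinguish "no calls" from "all calls wrong".

Welch's unequal-variance t-test is included for comparing per-sample metric
values between two groups (e.g. two library-preparation kits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy import stats

from ._errors import DesignError

__all__ = [
    "ConfusionCounts",
    "MetricResult",
    "confusion",
    "precision_recall_f",
    "welch_t",
    "significance_stars",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricResult:
    """Precision/recall/F triple; NaN marks an undefined (0/0) metric."""

    precision: float
    recall: float
    f_score: float

    def defined(self) -> bool:
        return not any(
            math.isnan(v) for v in (self.precision, self.recall, self.f_score)
        )


def confusion(
    subsample_set: set[Hashable], truth_set: set[Hashable]
) -> ConfusionCounts:
    """TP/FP/FN of a subsample's set against the full-data truth set."""
    subsample_set = set(subsample_set)
    truth_set = set(truth_set)
    tp = len(subsample_set & truth_set)
    return ConfusionCounts(
        tp=tp, fp=len(subsample_set) - tp, fn=len(truth_set) - tp
    )


def precision_recall_f(counts: ConfusionCounts) -> MetricResult:
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    denom = tp + 0.5 * (fp + fn)
    f_score = tp / denom if denom > 0 else math.nan
    return MetricResult(precision=precision, recall=recall, f_score=f_score)


def welch_t(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Welch two-sample t-test; returns ``(t, df, two_sided_p)``.

    Requires at least two observations per group and nonzero variance in at
    least one group (Welch–Satterthwaite df is undefined otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DesignError("welch_t requires >= 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            # identical constant groups: no evidence of difference
            return 0.0, float(x.size + y.size - 2), 1.0
        raise DesignError("welch_t undefined: both groups have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Conventional significance stars (**** at p <= 1e-4)."""
    if math.isnan(p):
        return ""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p <= threshold:
            return stars
    return "ns"
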