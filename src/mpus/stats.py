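"""Evaluation statistics for the MPUS pipeline.

Confusion-matrix metrics, ROC analysis with the Youden-index operating
cutoff, normality-gated two-group comparison, two-proportion testing, and
ordinary least squares for the lesion~parenchyma AREA relation.

Orientation convention for AREA scores: a more *negative* AREA means stronger
washout and is the malignancy-suggestive direction, so ROC utilities default
to "smaller score = positive class" and expose a flag to flip it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceReport:
    """Derived metrics; ratios with a zero denominator are None, not 0."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    f1: Optional[float]


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_metrics(counts: ConfusionCounts) -> PerformanceReport:
    """Standard confusion-matrix metrics (Se, Sp, PPV, NPV, accuracy, F1)."""
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    return PerformanceReport(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        f1=_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
    )


def counts_from_predictions(
    predicted: Sequence[bool], truth: Sequence[bool]
) -> ConfusionCounts:
    p = np.asarray(predicted, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("predicted and truth must have the same length")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def auroc(
    scores: Sequence[float], labels: Sequence[bool], larger_is_positive: bool = False
) -> float:
    """Pairwise-concordance (Mann-Whitney) AUROC estimate, ties counted 1/2.

    The probability that a random positive scores on the positive side of a
    random negative.  Default orientation: smaller (more negative) score =
    positive class, matching the AREA/washout convention.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if s.shape != lab.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if not larger_is_positive:
        s = -s
    ranks = sps.rankdata(s)
    return float((ranks[lab].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray  # dB, ascending
    se: np.ndarray  # sensitivity at "score <= threshold" (default orientation)
    sp: np.ndarray
    auroc: float
    larger_is_positive: bool


def roc_curve(
    scores: Sequence[float], labels: Sequence[bool], larger_is_positive: bool = False
) -> ROCResult:
    """Empirical ROC over all observed thresholds.

    With the default orientation a lesion is called positive when its score is
    at or below the threshold; sensitivity is therefore non-decreasing in the
    threshold and tightening the threshold (moving it down) can only lower it.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    thresholds = np.unique(s)
    pos = s[lab]
    neg = s[~lab]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    if larger_is_positive:
        se = np.array([(pos >= t).mean() for t in thresholds])
        sp = np.array([(neg < t).mean() for t in thresholds])
    else:
        se = np.array([(pos <= t).mean() for t in thresholds])
        sp = np.array([(neg > t).mean() for t in thresholds])
    return ROCResult(
        thresholds=thresholds,
        se=se,
        sp=sp,
        auroc=auroc(s, lab, larger_is_positive=larger_is_positive),
        larger_is_positive=larger_is_positive,
    )


def youden_cutoff(roc: ROCResult) -> float:
    """Threshold maximising Youden's J = Se + Sp - 1, ties broken toward higher Se."""
    j = roc.se + roc.sp - 1.0
    best = j.max()
    candidates = np.flatnonzero(np.isclose(j, best, rtol=0.0, atol=1e-12))
    best_se = roc.se[candidates].max()
    candidates = candidates[np.isclose(roc.se[candidates], best_se, rtol=0.0, atol=1e-12)]
    # among remaining ties prefer the least aggressive threshold
    idx = candidates[-1] if not roc.larger_is_positive else candidates[0]
    return float(roc.thresholds[idx])


# ---------------------------------------------------------------------------
# group comparison / proportions / regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    pvalue: float
    test: str  # "t" | "mannwhitney"
    statistic: float


def _looks_normal(x: np.ndarray, alpha: float) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    p = sps.shapiro(x).pvalue
    return bool(np.isfinite(p) and p > alpha)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "auto",
    alpha_normality: float = 0.05,
) -> GroupComparison:
    """Two-sided two-sample comparison with a Shapiro-Wilk normality gate.

    ``method="auto"`` uses Student's t-test when both groups pass the
    normality check at ``alpha_normality``, otherwise the Mann-Whitney U test
    (exact for small tie-free samples); ``"t"`` and ``"mannwhitney"`` force a
    branch.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if method == "auto":
        method = (
            "t"
            if _looks_normal(a, alpha_normality) and _looks_normal(b, alpha_normality)
            else "mannwhitney"
        )
    if method == "t":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError("t-test branch undefined for two constant groups")
        res = sps.ttest_ind(a, b)
        return GroupComparison(pvalue=float(res.pvalue), test="t", statistic=float(res.statistic))
    if method == "mannwhitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(
            pvalue=float(res.pvalue), test="mannwhitney", statistic=float(res.statistic)
        )
    raise ValueError(f"unknown method {method!r}")


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, method: str = "z"
) -> float:
    """Two-sided comparison of two binomial proportions.

    ``method="z"``: pooled-variance z test (equivalently the chi-square test
    without continuity correction).  ``method="fisher"``: Fisher's exact test.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if method == "fisher":
        return float(sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])[1])
    if method != "z":
        raise ValueError(f"unknown method {method!r}")
    if k1 * n2 == k2 * n1:  # identical proportions, z = 0
        return 1.0
    _, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(p)


@dataclass(frozen=True)
class RegressionResult:
    intercept: float
    slope: float
    p_slope: float
    intercept_se: float
    slope_se: float


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need paired samples, at least 2")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        intercept=float(res.intercept),
        slope=float(res.slope),
        p_slope=float(res.pvalue),
        intercept_se=float(res.intercept_stderr),
        slope_se=float(res.stderr),
    )


@dataclass(frozen=True)
class DetectionRate:
    """Among lesions whose malignancy call was correct, the fraction also typed correctly."""

    n_type_correct: int
    n_malignancy_correct: int

    def __post_init__(self) -> None:
        if self.n_malignancy_correct <= 0:
            raise ValueError("no correctly classified lesions")
        if not 0 <= self.n_type_correct <= self.n_malignancy_correct:
            raise ValueError("type-correct count must be within [0, malignancy-correct count]")

    @property
    def fraction(self) -> float:
        return self.n_type_correct / self.n_malignancy_correct

    @property
    def percent(self) -> int:
        return round(100.0 * self.fraction)


def detection_rate(n_type_correct: int, n_malignancy_correct: int) -> DetectionRate:
    return DetectionRate(n_type_correct, n_malignancy_correct)
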