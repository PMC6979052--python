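"""Statistical layer: location tests, correlation, and ROC analysis.

The ROC machinery is the diagnostic core: an empirical ROC curve over
thresholds placed between distinct score values, trapezoidal AUC (equal
to the Mann–Whitney concordance with half credit for ties), the
Hanley–McNeil standard error, a normal-approximation 95% CI clipped to
[0, 1], and the Youden-optimal cutoff (J = sensitivity + specificity - 1)
with ties broken toward higher sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from empredict.errors import InsufficientDataError, InvalidInputError


@dataclass(frozen=True)
class TestResult:
    """Outcome of a t test; ``degenerate`` flags zero-variance inputs."""

    statistic: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with its two-sided p value."""

    r: float
    p_value: float
    n: int


@dataclass
class RocResult:
    """Empirical ROC curve with AUC, SE, clipped CI and Youden cutoff.

    ``orientation`` records which direction of the score indicates the
    positive class; for membrane potentials, ``lower-score-positive``
    means more-negative (hyperpolarized) Em predicts success.
    ``cutoff`` is on the original score scale: with lower-score-positive
    orientation a sample is called positive when score <= cutoff.
    """

    points: list[tuple[float, float]]  # (fpr, tpr), (0,0) .. (1,1)
    auc: float
    se: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float  # % at the cutoff
    specificity: float  # % at the cutoff
    orientation: str = "lower-score-positive"
    n_positive: int = 0
    n_negative: int = 0
    thresholds: list[float] = field(default_factory=list)


def paired_t(x, y) -> TestResult:
    """Two-sided paired Student's t test.

    Degenerate cases are flagged rather than erroring: all differences
    zero returns (t=0, p=1); a constant non-zero difference returns the
    p -> 0 limit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise InsufficientDataError("paired t test needs n >= 2")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult(statistic=0.0, p_value=1.0, n=n, degenerate=True)
        sign = np.sign(d[0])
        return TestResult(statistic=float(sign * np.inf), p_value=0.0, n=n,
                          degenerate=True)
    t, p = sps.ttest_rel(x, y)
    return TestResult(statistic=float(t), p_value=float(p), n=n)


def unpaired_t(x, y) -> TestResult:
    """Two-sided unpaired (independent-samples, equal-variance) t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("unpaired t test needs n >= 2 per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        same = x[0] == y[0]
        return TestResult(statistic=0.0 if same else float(np.sign(x[0] - y[0]) * np.inf),
                          p_value=1.0 if same else 0.0,
                          n=x.size + y.size, degenerate=True)
    t, p = sps.ttest_ind(x, y)
    return TestResult(statistic=float(t), p_value=float(p), n=x.size + y.size)


def pearson(x, y) -> CorrelationResult:
    """Pearson r with the two-sided p value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue),
                             n=x.size)


def anova_oneway(*groups) -> TestResult:
    """One-way ANOVA across two or more groups (thin standard wrapper)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError("one-way ANOVA needs >= 2 groups of n >= 2")
    f, p = sps.f_oneway(*groups)
    return TestResult(statistic=float(f), p_value=float(p),
                      n=sum(len(g) for g in groups))


def hanley_mcneil_se(auc: float, n_positive: int, n_negative: int) -> float:
    """Standard error of an empirical AUC by the Hanley–McNeil formula.

    Uses the exponential approximations Q1 = A/(2-A), Q2 = 2A^2/(1+A).
    """
    if n_positive < 1 or n_negative < 1:
        raise InvalidInputError("both classes must be non-empty")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_positive - 1) * (q1 - a * a)
        + (n_negative - 1) * (q2 - a * a)
    ) / (n_positive * n_negative)
    return float(np.sqrt(max(var, 0.0)))


def ci_from_auc(auc: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for an AUC, clipped to [0, 1]."""
    if se < 0:
        raise InvalidInputError("se must be >= 0")
    if not 0 < level < 1:
        raise InvalidInputError("level must lie in (0,1)")
    z = sps.norm.ppf(0.5 + level / 2.0)
    lower = max(0.0, auc - z * se)
    upper = min(1.0, auc + z * se)
    return (float(lower), float(upper))


def roc_analysis(
    scores,
    labels,
    orientation: str = "lower-score-positive",
    level: float = 0.95,
) -> RocResult:
    """Empirical ROC of a continuous score against binary outcomes.

    Thresholds are placed at the midpoints between consecutive distinct
    score values (plus sentinels beyond both ends), so every achievable
    confusion table appears exactly once.  With
    ``lower-score-positive`` orientation a sample is predicted positive
    when its score is <= the threshold.  AUC is the trapezoidal area of
    the resulting polyline, which equals Mann–Whitney concordance with
    half credit for tied scores.  The reported cutoff maximizes Youden's
    J = sensitivity + specificity - 1, breaking ties toward higher
    sensitivity (and, among those, the more inclusive threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InvalidInputError("scores and labels must be 1-D and equal length")
    if not np.all(np.isfinite(scores)):
        raise InvalidInputError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("both outcome classes must be present")
    if orientation not in ("lower-score-positive", "higher-score-positive"):
        raise InvalidInputError(f"unknown orientation {orientation!r}")

    # Work on an internal scale where larger means more positive-like
    s = -scores if orientation == "lower-score-positive" else scores

    # ROC points by cumulative counting over distinct values (descending):
    # point k predicts positive when s >= k-th largest distinct value.
    # Counting (not threshold comparison) keeps the polyline exact even when
    # adjacent distinct scores have no representable midpoint between them.
    uniq = np.unique(s)  # ascending
    pos_hist = np.bincount(np.searchsorted(uniq, s[labels]), minlength=uniq.size)
    neg_hist = np.bincount(np.searchsorted(uniq, s[~labels]), minlength=uniq.size)
    tpr = np.concatenate(([0.0], np.cumsum(pos_hist[::-1]) / n_pos))
    fpr = np.concatenate(([0.0], np.cumsum(neg_hist[::-1]) / n_neg))
    # representative thresholds (reporting only): between distinct values,
    # with sentinels beyond both ends
    desc = uniq[::-1]
    internal_thresholds = np.concatenate(
        ([desc[0] + 1.0], (desc[:-1] + desc[1:]) / 2.0, [desc[-1] - 1.0])
    )

    auc = float(np.trapezoid(tpr, fpr))
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    ci = ci_from_auc(auc, se, level)

    j = tpr - fpr
    best = int(np.lexsort((fpr, -tpr, -j))[0])  # max J, then max tpr, then min fpr
    t_internal = internal_thresholds[best]
    cutoff = -t_internal if orientation == "lower-score-positive" else t_internal

    return RocResult(
        points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        se=se,
        ci95=ci,
        cutoff=float(cutoff),
        sensitivity=100.0 * float(tpr[best]),
        specificity=100.0 * float(1.0 - fpr[best]),
        orientation=orientation,
        n_positive=n_pos,
        n_negative=n_neg,
        thresholds=[
            (-t if orientation == "lower-score-positive" else t)
            for t in internal_thresholds.tolist()
        ],
    )


def auc_concordance(scores, labels, orientation: str = "lower-score-positive") -> float:
    """Brute-force all-pairs Mann–Whitney concordance (ties = 1/2).

    Independent O(n_pos * n_neg) cross-check of the trapezoidal AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    s = -scores if orientation == "lower-score-positive" else scores
    pos = s[labels]
    neg = s[~labels]
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both outcome classes must be present")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)
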