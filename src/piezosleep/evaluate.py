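"""Statistical evaluation of REI/Fcv against reference AHI.

Covers the evaluation machinery used to judge the screening method:
Pearson correlations, the incremental value of Fcv on top of REI in an
ordinary least-squares model, ROC/AUC with a DeLong confidence interval,
cutoff selection balancing sensitivity and specificity, and binary /
four-level severity confusion metrics.

Conventions: predicted-positive means score >= cutoff throughout, matching
the clinical phrasing "REI >= 14"; percentages are kept at full precision
internally and rounded half-up to one decimal only for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
import statsmodels.api as sm

from .errors import DomainError, SingularityError, UndefinedCorrelationError
from .io import SeverityClass

#: REI (events/h of TRT) boundaries of the four-level severity bands
#: (normal < 9, mild 9-14, moderate 14-24, severe >= 24); boundary values
#: go to the higher class ("REI >= 14", "REI >= 24").
REI_SEVERITY_BOUNDS = (9.0, 14.0, 24.0)


def round_display(value: float, ndigits: int = 1) -> float:
    """Half-up rounding used for displayed percentages (84.55 -> 84.6)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# --- correlation and regression --------------------------------------------


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient.

    Raises :class:`UndefinedCorrelationError` when either input is constant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("pearson_r needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation of a constant vector is undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class IncrementalRegressionResult:
    """Incremental value of Fcv after REI in an OLS model of AHI."""

    multiple_r_base: float  # AHI ~ REI
    multiple_r_full: float  # AHI ~ REI + Fcv
    partial_f: float
    p_value: float
    n: int


def incremental_regression(
    ahi: Sequence[float], rei: Sequence[float], fcv: Sequence[float]
) -> IncrementalRegressionResult:
    """Does Fcv improve the fit of AHI once REI is in the model?

    Fits AHI ~ REI and AHI ~ REI + Fcv by ordinary least squares and tests
    the increment with the partial F statistic
    ``((RSS1 - RSS2) / 1) / (RSS2 / (n - 3))`` on F(1, n - 3).
    """
    ahi = np.asarray(ahi, dtype=np.float64)
    rei = np.asarray(rei, dtype=np.float64)
    fcv = np.asarray(fcv, dtype=np.float64)
    n = ahi.size
    if not (rei.size == fcv.size == n) or n < 5:
        raise DomainError("incremental_regression needs equal-length vectors, n >= 5")

    x_full = sm.add_constant(np.column_stack([rei, fcv]))
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise SingularityError("REI and Fcv are collinear")

    base = sm.OLS(ahi, sm.add_constant(rei)).fit()
    full = sm.OLS(ahi, x_full).fit()
    rss1 = float(base.ssr)
    rss2 = float(full.ssr)
    df2 = n - 3
    if rss2 <= 0:
        partial_f = math.inf
        p_value = 0.0
    else:
        partial_f = max(0.0, (rss1 - rss2)) / (rss2 / df2)
        p_value = float(stats.f.sf(partial_f, 1, df2))
    return IncrementalRegressionResult(
        multiple_r_base=math.sqrt(max(0.0, base.rsquared)),
        multiple_r_full=math.sqrt(max(0.0, full.rsquared)),
        partial_f=partial_f,
        p_value=p_value,
        n=n,
    )


# --- ROC / AUC ---------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    ci95: Tuple[float, float]
    curve: np.ndarray  # ordered (fpr, tpr) points
    n_pos: int
    n_neg: int


def _placements(pos: np.ndarray, neg: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components via midranks."""
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    rank_all = stats.rankdata(combined)  # midranks
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    auc = v10.mean()
    return v10, v01, float(auc)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2).

    The 95% CI uses the DeLong variance with a logit transform, clipped to
    [0, 1]; a degenerate variance (perfect separation) collapses the CI to
    the point estimate.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise DomainError("roc_auc needs both classes present")

    v10, v01, auc = _placements(pos, neg)
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(v01, ddof=1) / neg.size
    se = math.sqrt(var)

    if se == 0 or auc in (0.0, 1.0):
        ci = (auc, auc)
    else:
        logit = math.log(auc / (1 - auc))
        se_logit = se / (auc * (1 - auc))
        lo = logit - 1.959963984540054 * se_logit
        hi = logit + 1.959963984540054 * se_logit
        ci = (1 / (1 + math.exp(-lo)), 1 / (1 + math.exp(-hi)))
    ci = (min(max(ci[0], 0.0), 1.0), min(max(ci[1], 0.0), 1.0))

    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    curve = np.column_stack([fpr, tpr])
    return RocResult(auc=auc, ci95=ci, curve=curve, n_pos=int(pos.size), n_neg=int(neg.size))


def optimal_cutoff(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Cutoff balancing sensitivity and specificity.

    Candidates are midpoints between adjacent distinct scores (with
    predicted-positive meaning score >= cutoff).  The candidate maximising
    ``min(sensitivity, specificity)`` wins; ties are broken by the larger
    Youden index, then by the lower cutoff.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise DomainError("optimal_cutoff needs both classes present")

    distinct = np.unique(scores)
    if distinct.size < 2:
        raise DomainError("optimal_cutoff needs at least two distinct scores")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    best = None
    best_key = None
    for c in candidates:
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        key = (-min(sens, spec), -(sens + spec - 1.0), c)
        if best_key is None or key < best_key:
            best_key = key
            best = float(c)
    return best


# --- confusion tables --------------------------------------------------------


@dataclass(frozen=True)
class BinaryConfusion:
    """2x2 table; positive = reference AHI at/above the severity cutoff."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class BinaryMetrics:
    """Percent agreement metrics; a metric with a zero denominator is None."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    ppa: Optional[float]
    npa: Optional[float]


def _ratio_percent(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den > 0 else None


def binary_metrics(c: BinaryConfusion) -> BinaryMetrics:
    """Sensitivity, specificity, accuracy, PPA and NPA in percent."""
    if c.total == 0:
        raise DomainError("all-zero confusion table")
    return BinaryMetrics(
        sensitivity=_ratio_percent(c.tp, c.tp + c.fn),
        specificity=_ratio_percent(c.tn, c.tn + c.fp),
        accuracy=_ratio_percent(c.tp + c.tn, c.total),
        ppa=_ratio_percent(c.tp, c.tp + c.fp),
        npa=_ratio_percent(c.tn, c.tn + c.fn),
    )


def binary_confusion(
    rei: Sequence[float],
    ahi: Sequence[float],
    rei_cutoff: float,
    ahi_cutoff: float,
) -> BinaryConfusion:
    """Cross-tabulate REI >= rei_cutoff against reference AHI >= ahi_cutoff."""
    rei = np.asarray(rei, dtype=np.float64)
    ahi = np.asarray(ahi, dtype=np.float64)
    pred = rei >= rei_cutoff
    ref = ahi >= ahi_cutoff
    return BinaryConfusion(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
        tn=int(np.sum(~pred & ~ref)),
    )


def classify_severity_by_rei(rei: float) -> SeverityClass:
    """Four-level severity from REI: <9 / 9-14 / 14-24 / >=24.

    Boundary values go to the higher class.
    """
    if not math.isfinite(rei) or rei < 0:
        raise DomainError(f"REI must be a finite non-negative rate, got {rei!r}")
    idx = int(np.searchsorted(REI_SEVERITY_BOUNDS, rei, side="right"))
    return SeverityClass(idx)


@dataclass(frozen=True)
class MultiLevelConfusion:
    """4x4 table: rows = class predicted from REI, columns = reference class."""

    matrix: Tuple[Tuple[int, ...], ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (4, 4) or (m < 0).any():
            raise DomainError("matrix must be 4x4 with non-negative counts")
        object.__setattr__(
            self, "matrix", tuple(tuple(int(v) for v in row) for row in m)
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.array.sum())


def multilevel_confusion(
    rei: Sequence[float], ahi_tst: Sequence[float]
) -> MultiLevelConfusion:
    from .io import severity_class

    m = np.zeros((4, 4), dtype=np.int64)
    for r, a in zip(rei, ahi_tst):
        m[int(classify_severity_by_rei(r)), int(severity_class(a))] += 1
    return MultiLevelConfusion(tuple(tuple(int(v) for v in row) for row in m))


@dataclass
class MultiLevelMetrics:
    accuracy: float  # percent correctly classified
    off_by_shares: Tuple[float, float, float]  # percent of misclassifications off by 1, 2, 3
    per_class_sensitivity: Tuple[Optional[float], ...]
    per_class_specificity: Tuple[Optional[float], ...]


def multilevel_metrics(m: MultiLevelConfusion) -> MultiLevelMetrics:
    """Accuracy, off-by-k misclassification shares and per-class agreement.

    ``off_by_shares[k-1]`` is the share of *misclassified* subjects whose
    predicted class is k steps from the reference class.  Per-class
    sensitivity is the share of each reference class predicted as itself;
    per-class specificity the share of non-members identified as
    non-members.
    """
    a = m.array
    total = m.total
    if total == 0:
        raise DomainError("empty confusion table")
    correct = int(np.trace(a))
    accuracy = 100.0 * correct / total

    misclassified = total - correct
    offsets = np.abs(np.subtract.outer(np.arange(4), np.arange(4)))
    shares = []
    for k in (1, 2, 3):
        count = int(a[offsets == k].sum())
        shares.append(100.0 * count / misclassified if misclassified else 0.0)

    sens: List[Optional[float]] = []
    spec: List[Optional[float]] = []
    col_sums = a.sum(axis=0)
    row_sums = a.sum(axis=1)
    for c in range(4):
        members = int(col_sums[c])
        sens.append(100.0 * a[c, c] / members if members else None)
        non_members = total - members
        pred_c_among_non = int(row_sums[c] - a[c, c])
        spec.append(
            100.0 * (non_members - pred_c_among_non) / non_members if non_members else None
        )
    return MultiLevelMetrics(
        accuracy=accuracy,
        off_by_shares=tuple(shares),
        per_class_sensitivity=tuple(sens),
        per_class_specificity=tuple(spec),
    )
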