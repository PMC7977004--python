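"""Cohort-level evaluation: exact binomial CIs, ROC/AUC, 2x2 tests.

Sensitivity, specificity and accuracy are reported with two-sided exact
95% Clopper-Pearson confidence intervals (beta-quantile form).  AUC is the
Mann-Whitney U statistic divided by n_pos * n_neg with ties counted 1/2.
Fisher's exact test sums hypergeometric probabilities no larger than the
observed table's; the Mann-Whitney test enumerates the exact rank-sum
distribution for small samples without ties and uses the tie-corrected
normal approximation otherwise.  Percentages are rounded half-up to two
decimals only at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import ValidationError

__all__ = ["MetricCI", "EvaluationReport", "TwoByTwo", "confusion_stats",
           "clopper_pearson", "auc", "fisher_exact", "mann_whitney",
           "round_percent"]


def round_percent(proportion: float, decimals: int = 2) -> float:
    """Proportion -> percentage, rounded half-up (reporting layer only)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(proportion * 100)).quantize(q, rounding=ROUND_HALF_UP))


def clopper_pearson(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided binomial interval (beta quantiles), as proportions.

    ``successes == 0`` pins the lower bound at 0; ``successes == trials``
    pins the upper bound at 1.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValidationError(
            f"need 0 <= successes <= trials with trials >= 1, "
            f"got {successes}/{trials}"
        )
    alpha = (1.0 - confidence) / 2.0
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1.0 - alpha, successes + 1, trials - successes))
    return lower, upper


@dataclass(frozen=True)
class MetricCI:
    """A proportion with its exact confidence interval (all in [0, 1])."""

    point: float
    lower: float
    upper: float

    def as_percent(self) -> tuple[float, float, float]:
        return (round_percent(self.point), round_percent(self.lower),
                round_percent(self.upper))


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and metrics for resistant-as-positive predictions."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[MetricCI]
    specificity: Optional[MetricCI]
    accuracy: Optional[MetricCI]
    auc: Optional[float] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def summary(self) -> str:
        lines = [
            "Evaluation (positive class: resistant)",
            f"  n = {self.n}  (resistant {self.tp + self.fn}, "
            f"sensitive {self.tn + self.fp})",
            f"  confusion: TP={self.tp} FN={self.fn} FP={self.fp} TN={self.tn}",
        ]
        for name, m in (("sensitivity", self.sensitivity),
                        ("specificity", self.specificity),
                        ("accuracy", self.accuracy)):
            if m is None:
                lines.append(f"  {name}: undefined")
            else:
                p, lo, hi = m.as_percent()
                lines.append(
                    f"  {name}: {p:.2f}% (95% CI, {lo:.2f}%-{hi:.2f}%)")
        if self.auc is not None:
            lines.append(f"  AUC: {self.auc:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def metric(m: Optional[MetricCI]):
            if m is None:
                return None
            p, lo, hi = m.as_percent()
            return {"percent": p, "ci_lower": lo, "ci_upper": hi}

        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": metric(self.sensitivity),
            "specificity": metric(self.specificity),
            "accuracy": metric(self.accuracy),
            "auc": self.auc,
        }


def _as_binary(labels: Sequence, positive) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr.astype(int)
    return (arr == positive).astype(int)


def confusion_stats(
    predictions: Sequence,
    truth: Sequence,
    positive="resistant",
    confidence: float = 0.95,
) -> EvaluationReport:
    """Confusion-matrix metrics with exact CIs; resistant is the positive class.

    ``predictions`` and ``truth`` are equal-length binary label vectors
    (booleans, or labels compared against ``positive``; predicted labels of
    the form ``resistant-predicted`` also match).  A metric whose
    denominator is empty is reported as undefined, never as 0.
    """
    pred = np.asarray(predictions)
    if pred.dtype != bool and np.issubdtype(pred.dtype, np.str_):
        pred = np.char.replace(pred.astype(str), "-predicted", "")
    p = _as_binary(pred, positive)
    t = _as_binary(truth, positive)
    if len(p) != len(t):
        raise ValidationError("predictions and truth differ in length")
    tp = int(((p == 1) & (t == 1)).sum())
    fn = int(((p == 0) & (t == 1)).sum())
    fp = int(((p == 1) & (t == 0)).sum())
    tn = int(((p == 0) & (t == 0)).sum())

    def metric(k: int, n: int) -> Optional[MetricCI]:
        if n == 0:
            return None
        lo, hi = clopper_pearson(k, n, confidence)
        return MetricCI(k / n, lo, hi)

    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=metric(tp, tp + fn),
        specificity=metric(tn, tn + fp),
        accuracy=metric(tp + tn, tp + fp + tn + fn),
    )


def auc(scores: Sequence[float], truth: Sequence) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic, ties 1/2."""
    s = np.asarray(scores, dtype=float)
    t = _as_binary(truth, "resistant")
    n_pos = int(t.sum())
    n_neg = int(len(t) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    u = ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table [[a, b], [c, d]] (group x binary trait)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(table: TwoByTwo) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities <= observed's."""
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(probs[probs <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0)


@lru_cache(maxsize=None)
def _rank_sum_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of subsets of size n1 from ranks 1..n1+n2 by rank-sum offset.

    Entry u of the returned array is the number of ways the smaller group's
    rank sum exceeds its minimum by exactly u, i.e. the exact null
    distribution of the Mann-Whitney U statistic without ties.
    """
    # dp[k][u]: subsets of size k with U statistic u, ranks added one by one
    max_u = n1 * n2
    dp = np.zeros((n1 + 1, max_u + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n1 + n2 + 1):
        for k in range(min(r, n1), 0, -1):
            # choosing rank r as the k-th member adds (r - k) to U
            add = r - k
            if add > max_u:
                continue
            dp[k, add:] += dp[k - 1, :max_u + 1 - add]
    return dp[n1]


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact enumeration of the rank-sum distribution when the smaller group
    has at most 8 observations and there are no ties; tie-corrected normal
    approximation (no continuity correction) otherwise.  Degenerate inputs
    with zero rank variance give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(a), len(b)
    u_a = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)

    if min(n1, n2) <= 8 and not has_ties:
        if n1 <= n2:
            counts, u = _rank_sum_counts(n1, n2), u_a
        else:
            counts, u = _rank_sum_counts(n2, n1), n1 * n2 - u_a
        total = counts.sum()
        u = int(round(u))
        # symmetric null: two-sided p doubles the smaller tail
        lo_tail = counts[: u + 1].sum() / total
        hi_tail = counts[u:].sum() / total
        return float(min(1.0, 2.0 * min(lo_tail, hi_tail)))

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (u_a - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))
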