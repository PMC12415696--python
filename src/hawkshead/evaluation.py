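"""Classifier evaluation: confusion metrics, AUROC, DeLong and McNemar tests.

The binary metrics follow the standard confusion-matrix identities

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

with the positive class being the neoplastic one (label 1).  Scores at or
above the threshold (default 0.5) count as positive predictions.  A metric
with a zero denominator is reported as *undefined* (``None``), never as a
silent zero or NaN.

AUROC is the Mann-Whitney probability that a random positive outscores a
random negative, ties counted one half.  Correlated AUROCs are compared
with DeLong's structural-components estimator; paired classifications with
McNemar's test on the discordant counts b (A wrong, B right) and c
(A right, B wrong), exact two-sided binomial by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .records import PredictionRecord

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Fraction-valued metrics; ``None`` marks an undefined (0/0) metric."""

    accuracy: Optional[float]
    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    f1: Optional[float]
    auroc: Optional[float] = None

    @property
    def undefined(self) -> list[str]:
        return [
            name
            for name in ("accuracy", "precision", "sensitivity", "specificity", "f1", "auroc")
            if getattr(self, name) is None
        ]


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    alpha: float = ALPHA_DEFAULT
    b: Optional[int] = None  # A wrong, B right
    c: Optional[int] = None  # A right, B wrong

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def confusion(predictions: Sequence[PredictionRecord], threshold: float = 0.5) -> ConfusionCounts:
    """Count the confusion cells; score >= threshold predicts positive."""
    if len(predictions) == 0:
        raise ValueError("cannot build a confusion matrix from zero predictions")
    scores = np.array([p.score for p in predictions])
    labels = np.array([p.label for p in predictions])
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> MetricsReport:
    if c.total == 0:
        raise ValueError("confusion counts sum to zero")
    precision = _ratio(c.tp, c.tp + c.fp)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    f1 = f1_score(precision, sensitivity)
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        sensitivity=sensitivity,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f1=f1,
    )


def f1_score(precision: Optional[float], sensitivity: Optional[float]) -> Optional[float]:
    """Harmonic mean of precision and sensitivity (undefined if either is,
    or if both are zero)."""
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        return None
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def auroc(predictions: Sequence[PredictionRecord]) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    labels = np.array([p.label for p in predictions])
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    scores = np.array([p.score for p in predictions])
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# Pairing


def _pair(
    preds_a: Sequence[PredictionRecord], preds_b: Sequence[PredictionRecord]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align two prediction sets by tile_id; returns (scores_a, scores_b, labels)."""
    a = {p.tile_id: p for p in preds_a}
    b = {p.tile_id: p for p in preds_b}
    if len(a) != len(preds_a) or len(b) != len(preds_b):
        raise ValueError("duplicate tile ids within a prediction set")
    only_a = sorted(set(a) - set(b))
    only_b = sorted(set(b) - set(a))
    if only_a or only_b:
        raise ValueError(
            f"prediction sets are not pairable; only in A: {only_a[:5]}, only in B: {only_b[:5]}"
        )
    mismatched = [t for t in a if a[t].label != b[t].label]
    if mismatched:
        raise ValueError(f"paired records disagree on labels for tiles {sorted(mismatched)[:5]}")
    keys = sorted(a)
    return (
        np.array([a[k].score for k in keys]),
        np.array([b[k].score for k in keys]),
        np.array([a[k].label for k in keys]),
    )


# ---------------------------------------------------------------------------
# DeLong's test


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=np.float64)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j < len(sx) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
    return ranks


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    rank_all = _midrank(all_scores)
    rank_pos = _midrank(pos)
    rank_neg = _midrank(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return auc, v10, v01


def delong_test(
    preds_a: Sequence[PredictionRecord],
    preds_b: Sequence[PredictionRecord],
    alpha: float = ALPHA_DEFAULT,
) -> PairedTestResult:
    """DeLong's test for the difference of two correlated AUROCs.

    Uses the fast structural-components estimator of
    ``var(AUC_A - AUC_B)`` (variances plus the covariance induced by shared
    cases) and a two-sided normal p-value.  If the variance degenerates to
    zero with equal AUCs (e.g. a model against itself), p = 1.
    """
    sa, sb, labels = _pair(preds_a, preds_b)
    if len(np.unique(labels)) < 2:
        raise ValueError("DeLong's test needs both classes present")
    auc_a, v10_a, v01_a = _delong_components(sa, labels)
    auc_b, v10_b, v01_b = _delong_components(sb, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return PairedTestResult(statistic=0.0, p_value=1.0, alpha=alpha)
        return PairedTestResult(statistic=np.inf if diff > 0 else -np.inf, p_value=0.0, alpha=alpha)
    z = diff / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return PairedTestResult(statistic=float(z), p_value=min(p, 1.0), alpha=alpha)


# ---------------------------------------------------------------------------
# McNemar's test


def mcnemar_test(
    preds_a: Sequence[PredictionRecord],
    preds_b: Sequence[PredictionRecord],
    threshold: float = 0.5,
    exact: bool = True,
    alpha: float = ALPHA_DEFAULT,
) -> PairedTestResult:
    """McNemar's paired test on discordant classifications.

    b counts tiles misclassified by model A but correct under model B;
    c the reverse.  ``exact=True`` gives the two-sided binomial test on
    (b, c); ``exact=False`` the chi-square approximation with continuity
    correction (for large b + c).
    """
    sa, sb, labels = _pair(preds_a, preds_b)
    correct_a = (sa >= threshold) == (labels == 1)
    correct_b = (sb >= threshold) == (labels == 1)
    b = int(np.sum(~correct_a & correct_b))
    c = int(np.sum(correct_a & ~correct_b))
    n11 = int(np.sum(correct_a & correct_b))
    n00 = int(np.sum(~correct_a & ~correct_b))
    table = np.array([[n11, b], [c, n00]])
    if b + c == 0:
        return PairedTestResult(statistic=0.0, p_value=1.0, alpha=alpha, b=b, c=c)
    result = _sm_mcnemar(table, exact=exact, correction=not exact)
    return PairedTestResult(
        statistic=float(result.statistic),
        p_value=min(float(result.pvalue), 1.0),
        alpha=alpha,
        b=b,
        c=c,
    )
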