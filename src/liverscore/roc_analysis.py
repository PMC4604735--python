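"""ROC curves, AUC with DeLong confidence intervals, and Youden cut points.

The AUC is computed two ways on every call — trapezoidal integration of the
empirical curve and the Mann-Whitney rank formula with ties counted 1/2 —
and the two are asserted to agree to 1e-12, a cheap internal consistency
check of the curve construction.

Variance and curve comparison use DeLong's structural components: the
placement value of a positive subject is the fraction of negatives it
outscores (ties half-weighted), and vice versa; the empirical covariance of
placement values yields the AUC variance and the paired test for two
correlated curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RocResult",
    "CutPointResult",
    "roc_curve",
    "youden_cut_point",
    "delong_ci",
    "delong_paired_test",
    "clinically_useful",
]

#: AUC threshold conventionally read as "clinically useful"
CLINICAL_AUC_THRESHOLD = 0.8

ORIENTATIONS = ("higher_is_positive", "lower_is_positive")


@dataclass
class RocResult:
    """Empirical ROC curve for one score against a binary outcome."""

    name: str
    orientation: str
    thresholds: np.ndarray  # candidate cut points (midpoints + sentinels)
    sensitivity: np.ndarray  # P(score > t | positive) at each threshold
    specificity: np.ndarray  # P(score <= t | negative)
    auc: float
    auc_ci95: tuple[float, float]
    n_positive: int
    n_negative: int
    scores: np.ndarray  # oriented scores (higher = positive), pairwise-complete
    labels: np.ndarray  # 1 = positive (death), 0 = negative


@dataclass
class CutPointResult:
    """Youden-optimal operating point of a ROC curve."""

    cut_point: float
    sensitivity: float
    specificity: float
    youden_j: float


def _drop_missing(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.array([math.nan if v is None else float(v) for v in scores])
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    keep = ~np.isnan(s) & ~np.isnan(y)
    s, y = s[keep], y[keep].astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return s, y


def _placements(scores: np.ndarray, labels: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (V10 for positives, V01 for negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formula (midranks handle ties)."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = sps.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve(scores: Sequence, labels: Sequence,
              orientation: str = "higher_is_positive",
              name: str = "score") -> RocResult:
    """Empirical ROC curve with AUC and a DeLong 95 % confidence interval.

    Records with a missing score are dropped pairwise. Candidate thresholds
    are the midpoints between consecutive distinct score values, flanked by
    sentinels below the minimum and above the maximum; the classification
    rule is "positive when score > threshold" (after orientation). With
    integer-valued scores this yields the familiar half-integer cut points.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    s, y = _drop_missing(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"roc_curve({name}): need both outcome classes "
                         f"(got {n_pos} positive, {n_neg} negative)")
    oriented = s if orientation == "higher_is_positive" else -s

    distinct = np.unique(oriented)
    if distinct.size == 1:
        mids = np.array([])
    else:
        mids = (distinct[:-1] + distinct[1:]) / 2.0
    span = max(distinct[-1] - distinct[0], 1.0)
    thresholds = np.concatenate([[distinct[0] - 0.5 * span], mids,
                                 [distinct[-1] + 0.5 * span]])

    pos = oriented[y == 1]
    neg = oriented[y == 0]
    sens = (pos[:, None] > thresholds[None, :]).mean(axis=0)
    spec = (neg[:, None] <= thresholds[None, :]).mean(axis=0)

    # trapezoidal AUC over the curve (fpr decreasing along thresholds)
    fpr = 1.0 - spec
    auc_trap = float(np.trapezoid(sens[::-1], fpr[::-1]))
    auc_rank = _rank_auc(oriented, y)
    if abs(auc_trap - auc_rank) > 1e-12:
        raise AssertionError(
            f"trapezoidal ({auc_trap}) and rank ({auc_rank}) AUC disagree")

    result = RocResult(name=name, orientation=orientation,
                       thresholds=thresholds, sensitivity=sens,
                       specificity=spec, auc=auc_rank, auc_ci95=(0.0, 1.0),
                       n_positive=n_pos, n_negative=n_neg,
                       scores=oriented, labels=y)
    result.auc_ci95 = delong_ci(result)
    return result


def youden_cut_point(roc: RocResult) -> CutPointResult:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity, then toward the lower
    threshold. For a ``lower_is_positive`` score the returned cut point is
    on the original scale (predicted positive when score < cut point).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    order = np.lexsort((roc.thresholds, -roc.specificity, -j))
    best = order[0]
    cut = float(roc.thresholds[best])
    if roc.orientation == "lower_is_positive":
        cut = -cut
    return CutPointResult(cut_point=cut,
                          sensitivity=float(roc.sensitivity[best]),
                          specificity=float(roc.specificity[best]),
                          youden_j=float(j[best]))


def delong_variance(roc: RocResult) -> float:
    """DeLong variance of the AUC from placement-value dispersion."""
    if roc.n_positive < 2 or roc.n_negative < 2:
        raise ValueError("delong variance needs >= 2 per class")
    v10, v01 = _placements(roc.scores, roc.labels)
    return float(v10.var(ddof=1) / roc.n_positive
                 + v01.var(ddof=1) / roc.n_negative)


def delong_ci(roc: RocResult, level: float = 0.95) -> tuple[float, float]:
    """Wald interval on the AUC scale, truncated to [0, 1].

    A degenerate curve (AUC exactly 0 or 1, zero placement variance) yields
    a zero-width interval with a warning.
    """
    var = delong_variance(roc)
    if var == 0.0:
        warnings.warn(f"roc {roc.name!r}: degenerate DeLong variance; "
                      "zero-width confidence interval", stacklevel=2)
        return (roc.auc, roc.auc)
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return (max(0.0, roc.auc - half), min(1.0, roc.auc + half))


def delong_paired_test(scores_a: Sequence, scores_b: Sequence,
                       labels: Sequence) -> tuple[float, float]:
    """DeLong's test for two correlated ROC curves (two-sided).

    Both scores must be measured on the same subjects; records missing
    either score are dropped pairwise. Returns ``(z, p)`` for the null
    hypothesis AUC_a = AUC_b. Identical score vectors give z = 0, p = 1
    exactly.
    """
    sa = np.array([math.nan if v is None else float(v) for v in scores_a])
    sb = np.array([math.nan if v is None else float(v) for v in scores_b])
    y = np.asarray(labels, dtype=float)
    if not (sa.shape == sb.shape == y.shape):
        raise ValueError("paired test needs equal-length inputs")
    keep = ~np.isnan(sa) & ~np.isnan(sb) & ~np.isnan(y)
    sa, sb, y = sa[keep], sb[keep], y[keep].astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("paired DeLong test needs >= 2 per class")

    v10a, v01a = _placements(sa, y)
    v10b, v01b = _placements(sb, y)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    diff = auc_a - auc_b
    if np.array_equal(sa, sb):
        return 0.0, 1.0
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n_pos
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n_neg)
    if var <= 0:
        return (0.0, 1.0) if diff == 0 else (math.copysign(math.inf, diff), 0.0)
    z = diff / math.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def clinically_useful(auc: float) -> bool:
    """Whether an AUC reaches the conventional clinical-usefulness bar (>= 0.8)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"auc {auc} outside [0, 1]")
    return auc >= CLINICAL_AUC_THRESHOLD
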