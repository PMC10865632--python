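"""Evaluation quantities for freezing-of-gait assessment.

Clinical outcomes
    percent time frozen (%TF): cumulative FOG duration over total trial
    duration x 100, pooled across a subject's trials; number of FOG episodes
    (#FOG): count of maximal FOG runs.

Technical scores
    sample-wise F1 with F1 = TP / (TP + (FP + FN)/2) on per-sample confusion
    counts of the positive class; segment-wise F1 at IoU threshold k
    (Segment-F1@k), the action-segmentation metric that penalizes over- and
    under-segmentation: predicted episodes are matched one-to-one to ground
    truth, a pair with IoU strictly greater than k is a TP, remaining
    predictions are FP, unclaimed ground-truth episodes are FN.

Agreement statistics
    ICC(2,1) - two-way random-effects, absolute-agreement, single-rater
    intraclass correlation with F-based 95% confidence intervals - plus
    Bland-Altman bias and limits of agreement, and the categorical strength
    bands (>= 0.80 strong, 0.60-0.79 moderately strong, 0.30-0.59 fair,
    < 0.30 poor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .datamodel import FrameLabels, LABEL_FOG, Segment, labels_to_segments

__all__ = [
    "ConfusionCounts",
    "SubjectOutcome",
    "AgreementReport",
    "f1_from_counts",
    "sample_f1",
    "segment_iou",
    "segment_f1_at_k",
    "percent_time_frozen",
    "percent_time_frozen_pooled",
    "count_fog_episodes",
    "icc_2_1",
    "bland_altman",
    "strength_category",
    "agreement_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class SubjectOutcome:
    """Per-subject clinical and technical summary under an evaluation."""

    subject_id: str
    percent_tf: float
    n_fog: int
    mean_sample_f1: float
    mean_segment_f1_at_50: float


@dataclass
class AgreementReport:
    icc: float
    icc_ci: tuple[float, float]
    bias: float
    bias_ci: tuple[float, float]
    loa: tuple[float, float]
    loa_cis: tuple[tuple[float, float], tuple[float, float]]
    strength: str


# ---------------------------------------------------------------------------
# F1 family


def f1_from_counts(tp: int, fp: int, fn: int, degenerate: float = 1.0) -> float:
    """F1 = TP / (TP + (FP + FN) / 2).

    With no positives in either annotation (TP = FP = FN = 0) the score is
    undefined; perfect absence-agreement is scored as ``degenerate``
    (default 1.0; pass ``nan`` to exclude such trials from averages).
    """
    denom = tp + 0.5 * (fp + fn)
    if denom == 0:
        return degenerate
    return tp / denom


def _binary(labels) -> np.ndarray:
    if isinstance(labels, FrameLabels):
        return labels.binary()
    arr = np.asarray(labels)
    return (arr == LABEL_FOG).astype(np.int64)


def sample_f1(gt, pred, degenerate: float = 1.0) -> float:
    """Sample-wise F1 of the FOG class between two equal-length label vectors."""
    g, p = _binary(gt), _binary(pred)
    if g.size != p.size:
        raise ValueError(f"length mismatch: ground truth {g.size}, prediction {p.size}")
    tp = int(np.sum((g == 1) & (p == 1)))
    fp = int(np.sum((g == 0) & (p == 1)))
    fn = int(np.sum((g == 1) & (p == 0)))
    return f1_from_counts(tp, fp, fn, degenerate)


def segment_iou(a: Segment, b: Segment) -> float:
    """Intersection-over-union of two half-open sample intervals."""
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    union = max(a.end, b.end) - min(a.start, b.start)
    return inter / union


def _check_disjoint(segments: Sequence[Segment], name: str) -> None:
    ordered = sorted(segments)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise ValueError(f"overlapping {name} segments at [{cur.start}, {cur.end})")


def segment_f1_counts(
    gt_segments: Sequence[Segment],
    pred_segments: Sequence[Segment],
    k: float = 0.5,
) -> ConfusionCounts:
    """Segment-level TP/FP/FN at IoU threshold ``k``.

    Predictions are assigned one-to-one to ground-truth episodes by the
    optimal assignment that first maximizes the number of pairs with
    IoU > k (TP) and then the number of additional overlapping pairs.  A
    prediction whose pair is at or below the threshold - or that overlaps
    nothing - is FP; ground-truth episodes claimed by no prediction are FN.
    """
    _check_disjoint(gt_segments, "ground-truth")
    _check_disjoint(pred_segments, "predicted")
    n_gt, n_pred = len(gt_segments), len(pred_segments)
    if n_pred == 0:
        return ConfusionCounts(tp=0, fp=0, fn=n_gt)
    if n_gt == 0:
        return ConfusionCounts(tp=0, fp=n_pred, fn=0)
    iou = np.zeros((n_pred, n_gt))
    for i, p in enumerate(pred_segments):
        for j, g in enumerate(gt_segments):
            iou[i, j] = segment_iou(p, g)
    big = n_pred + n_gt + 1.0  # lexicographic: a TP outweighs any number of claims
    weight = big * (iou > k) + 1.0 * (iou > 0)
    rows, cols = linear_sum_assignment(weight, maximize=True)
    tp = int(np.sum(iou[rows, cols] > k))
    claimed = int(np.sum(iou[rows, cols] > 0))
    return ConfusionCounts(tp=tp, fp=n_pred - tp, fn=n_gt - claimed)


def segment_f1_at_k(
    gt_segments: Sequence[Segment],
    pred_segments: Sequence[Segment],
    k: float = 0.5,
    degenerate: float = 1.0,
) -> float:
    """Segment-F1@k between ground-truth and predicted episode lists."""
    c = segment_f1_counts(gt_segments, pred_segments, k)
    return f1_from_counts(c.tp, c.fp, c.fn, degenerate)


# ---------------------------------------------------------------------------
# clinical outcomes


def percent_time_frozen(labels) -> float:
    """100 x (#FOG samples) / T for one trial."""
    b = _binary(labels)
    if b.size == 0:
        raise ValueError("empty label vector")
    return 100.0 * float(b.sum()) / b.size


def percent_time_frozen_pooled(trials: Iterable) -> float:
    """Pooled %TF: summed FOG samples over summed trial lengths x 100."""
    num = den = 0
    for labels in trials:
        b = _binary(labels)
        num += int(b.sum())
        den += b.size
    if den == 0:
        raise ValueError("no samples to pool")
    return 100.0 * num / den


def count_fog_episodes(labels) -> int:
    """Number of maximal FOG runs (#FOG)."""
    return len(labels_to_segments(_binary(labels), 1))


# ---------------------------------------------------------------------------
# agreement statistics


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n_subjects x k_raters) table with no missing cells.
    Returns (icc, ci_low, ci_high) with the F-distribution-based confidence
    interval.  With zero between-subject and zero residual variance the
    coefficient is undefined and a ``ValueError`` is raised.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n x k table with n >= 2, k >= 2")
    if not np.isfinite(x).all():
        raise ValueError("ratings contain missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        if msr == 0 and mse == 0 and msc == 0:
            raise ValueError("ICC undefined: no variance in the ratings table")
        return 0.0, np.nan, np.nan
    if msr == 0 and mse == 0:
        raise ValueError("ICC undefined: zero between-subject and error variance")
    icc = (msr - mse) / denom

    # F-based CI (two-way random, absolute agreement, single measure)
    if mse == 0 and msc == 0:
        return float(icc), np.nan, np.nan  # degenerate: identical columns
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return float(icc), np.nan, np.nan
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else np.inf
    fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
    fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
    return float(icc), float(lower), float(upper)


def bland_altman(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> tuple[float, tuple[float, float], tuple[float, float], tuple[tuple[float, float], tuple[float, float]]]:
    """Bland-Altman agreement between two raters.

    Differences are d = a - b.  Returns bias (mean d) with its CI, limits of
    agreement bias +/- 1.96 sd(d), and normal-theory CIs of both limits.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = a.size
    if n < 3:
        raise ValueError("Bland-Altman requires at least 3 paired observations")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    t = stats.t.ppf(1 - alpha / 2, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + 1.96**2 / (2 * (n - 1)))
    bias_ci = (bias - t * se_bias, bias + t * se_bias)
    loa_cis = (
        (loa[0] - t * se_loa, loa[0] + t * se_loa),
        (loa[1] - t * se_loa, loa[1] + t * se_loa),
    )
    return bias, bias_ci, loa, loa_cis


def strength_category(icc: float) -> str:
    """Categorical agreement strength of an ICC value."""
    if icc >= 0.80:
        return "strong"
    if icc >= 0.60:
        return "moderately_strong"
    if icc >= 0.30:
        return "fair"
    return "poor"


def agreement_report(model_values: Sequence[float], expert_values: Sequence[float]) -> AgreementReport:
    """Full rater-agreement summary between model and expert outcome vectors."""
    ratings = np.column_stack([model_values, expert_values])
    icc, lo, hi = icc_2_1(ratings)
    bias, bias_ci, loa, loa_cis = bland_altman(model_values, expert_values)
    return AgreementReport(
        icc=icc,
        icc_ci=(lo, hi),
        bias=bias,
        bias_ci=bias_ci,
        loa=loa,
        loa_cis=loa_cis,
        strength=strength_category(icc),
    )
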