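"""Evaluation machinery: overlap metrics, agreement statistics, reference losses.

Covers segmentation overlap (Dice, Jaccard), manual-vs-automatic agreement
(Pearson r, one-way random-effects ICC(1,1) with exact F-based confidence
intervals, RMSE), per-table summary statistics and risk-band distributions,
and reference implementations of the detector losses (binary cross-entropy
and complete-IoU) for backend validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedMetricError
from .measures import MEASURE_NAMES, RISK_BANDS, MeasurementRecord, classify_risk

# --------------------------------------------------------------------------
# overlap metrics


def _mask_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise UndefinedMetricError("overlap metric undefined for two empty masks")
    return na, nb, int((a & b).sum())


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|), in [0, 1]."""
    na, nb, inter = _mask_counts(a, b)
    return 2.0 * inter / (na + nb)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B|, in [0, 1]."""
    na, nb, inter = _mask_counts(a, b)
    return inter / (na + nb - inter)


# --------------------------------------------------------------------------
# agreement statistics


@dataclass
class RatingsTable:
    """n subjects x k repeated ratings of one measure (no missing cells)."""

    values: np.ndarray
    measure_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D subjects x repeats grid")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need at least 2 subjects and 2 repeats, got {n}x{k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratings contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.values.shape[1]


@dataclass
class PairedMeasurements:
    """Matched manual and automatic measurement sequences for one measure."""

    manual: np.ndarray
    automatic: np.ndarray
    measure_name: str = ""

    def __post_init__(self) -> None:
        self.manual = np.asarray(self.manual, dtype=float)
        self.automatic = np.asarray(self.automatic, dtype=float)
        if self.manual.shape != self.automatic.shape or self.manual.ndim != 1:
            raise ValueError("manual and automatic must be 1-D sequences of equal length")
        if self.manual.size < 3:
            raise ValueError("need at least 3 paired measurements")
        if not (np.all(np.isfinite(self.manual)) and np.all(np.isfinite(self.automatic))):
            raise ValueError("paired measurements contain non-finite values")


def _anova_mean_squares(table: RatingsTable) -> tuple[float, float]:
    """One-way ANOVA decomposition over subjects: (MSB, MSW)."""
    x = table.values
    n, k = x.shape
    row_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msw = float(((x - row_means[:, None]) ** 2).sum()) / (n * (k - 1))
    return msb, msw


def icc_one_way(table: RatingsTable | np.ndarray) -> float:
    """ICC(1,1): single-rating one-way random-effects intraclass correlation.

    (MSB - MSW) / (MSB + (k-1) MSW) from the one-way ANOVA over subjects.
    Can be negative when subjects are less variable than repeats; always <= 1.
    """
    if not isinstance(table, RatingsTable):
        table = RatingsTable(table)
    msb, msw = _anova_mean_squares(table)
    if msb == 0.0 and msw == 0.0:
        raise UndefinedMetricError("all ratings identical; ICC undefined")
    k = table.n_repeats
    return (msb - msw) / (msb + (k - 1) * msw)


def icc_confidence_interval(
    table: RatingsTable | np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided F-based confidence interval for ICC(1,1).

    With F = MSB/MSW on (n-1, n(k-1)) degrees of freedom, the bounds are
    (F/F_u - 1)/(F/F_u + k - 1) and (F/F_l - 1)/(F/F_l + k - 1) where F_u,
    F_l are the upper/lower F quantiles at the requested level.
    """
    if not isinstance(table, RatingsTable):
        table = RatingsTable(table)
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    msb, msw = _anova_mean_squares(table)
    if msb == 0.0 and msw == 0.0:
        raise UndefinedMetricError("all ratings identical; ICC undefined")
    if msw == 0.0:
        return (1.0, 1.0)
    n, k = table.n_subjects, table.n_repeats
    f_obs = msb / msw
    alpha = 1.0 - level
    df1, df2 = n - 1, n * (k - 1)
    f_upper = stats.f.ppf(1 - alpha / 2, df1, df2)
    f_lower = stats.f.ppf(alpha / 2, df1, df2)
    lo = (f_obs / f_upper - 1) / (f_obs / f_upper + k - 1)
    hi = (f_obs / f_lower - 1) / (f_obs / f_lower + k - 1)
    return (lo, hi)


def interpret_icc(icc_value: float) -> str:
    """Conventional reliability label: excellent / good / moderate / poor."""
    if icc_value > 1:
        raise ValueError(f"ICC cannot exceed 1, got {icc_value}")
    if icc_value >= 0.9:
        return "excellent"
    if icc_value >= 0.75:
        return "good"
    if icc_value >= 0.5:
        return "moderate"
    return "poor"


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; rejects constant sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined for a constant sequence")
    return float(stats.pearsonr(x, y).statistic)


def rmse(x: Sequence[float], y: Sequence[float]) -> float:
    """Root of the mean squared residual between paired sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("need two equal-length non-empty 1-D sequences")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def paired_agreement(pairs: PairedMeasurements, level: float = 0.95) -> dict:
    """Pearson r, ICC(1,1) with CI, and RMSE for a manual/automatic pair."""
    table = RatingsTable(
        np.column_stack([pairs.manual, pairs.automatic]), pairs.measure_name
    )
    icc = icc_one_way(table)
    lo, hi = icc_confidence_interval(table, level=level)
    return {
        "measure": pairs.measure_name,
        "n": int(pairs.manual.size),
        "pearson_r": pearson_r(pairs.manual, pairs.automatic),
        "icc": icc,
        "icc_ci_low": lo,
        "icc_ci_high": hi,
        "icc_label": interpret_icc(icc),
        "rmse": rmse(pairs.manual, pairs.automatic),
    }


# --------------------------------------------------------------------------
# reference losses


BCE_EPS = 1e-7


def bce_loss(predicted: float, target: int, weight: float = 1.0) -> float:
    """Binary cross-entropy -W[y log x + (1-y) log(1-x)], x clamped to [eps, 1-eps].

    Clamping at eps = 1e-7 keeps perfect-confidence mistakes finite
    (-log eps ~ 16.12) instead of infinite.
    """
    if target not in (0, 1):
        raise ValueError(f"target must be 0 or 1, got {target}")
    if weight <= 0:
        raise ValueError("weight must be positive")
    x = min(max(float(predicted), BCE_EPS), 1.0 - BCE_EPS)
    return -weight * (target * math.log(x) + (1 - target) * math.log(1.0 - x))


@dataclass(frozen=True)
class Box:
    """Axis-aligned bounding box given by center (cx, cy) and size (w, h)."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box sides must be positive, got w={self.w}, h={self.h}")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max)."""
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )


def box_iou(a: Box, b: Box) -> float:
    ax0, ay0, ax1, ay1 = a.corners
    bx0, by0, bx1, by1 = b.corners
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = a.w * a.h + b.w * b.h - inter
    return inter / union


def ciou_loss(pred: Box, truth: Box) -> float:
    """Complete-IoU loss: 1 - IoU + rho^2/c^2 + alpha v.

    rho is the center distance, c the diagonal of the smallest enclosing
    box, v = (4/pi^2)(atan(w_gt/h_gt) - atan(w/h))^2 the aspect-ratio term
    and alpha = v / ((1 - IoU) + v) its trade-off weight (0 when v = 0; the
    0/0 case at IoU = 1, v = 0 is defined as 0 since the loss is already 0).
    """
    iou = box_iou(pred, truth)
    rho2 = (pred.cx - truth.cx) ** 2 + (pred.cy - truth.cy) ** 2
    px0, py0, px1, py1 = pred.corners
    tx0, ty0, tx1, ty1 = truth.corners
    c2 = (max(px1, tx1) - min(px0, tx0)) ** 2 + (max(py1, ty1) - min(py0, ty0)) ** 2
    v = (4.0 / math.pi**2) * (
        math.atan(truth.w / truth.h) - math.atan(pred.w / pred.h)
    ) ** 2
    alpha = 0.0 if v == 0.0 else v / ((1.0 - iou) + v)
    return 1.0 - iou + rho2 / c2 + alpha * v


# --------------------------------------------------------------------------
# summaries


def summary_stats(values: Sequence[float]) -> tuple[float, float, float, float]:
    """(mean, sample std (n-1), min, max) of a sequence of length >= 2."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D sequence of at least 2 values")
    return (
        float(arr.mean()),
        float(arr.std(ddof=1)),
        float(arr.min()),
        float(arr.max()),
    )


def band_distribution(records: Iterable[MeasurementRecord]) -> dict[str, dict[str, int]]:
    """Counts of studies per risk band per measure; bands partition, so the
    counts for each measure sum to the number of records."""
    records = list(records)
    if not records:
        raise ValueError("band_distribution requires at least one record")
    counts = {m: {band: 0 for band in RISK_BANDS[m]} for m in MEASURE_NAMES}
    for rec in records:
        counts["CSA"][classify_risk("CSA", rec.csa)] += 1
        counts["LAA"][classify_risk("LAA", rec.laa)] += 1
        counts["AI"][classify_risk("AI", rec.ai)] += 1
    return counts
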