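"""Behavioral summary statistics and delta-plot distributional analysis.

Delta plots capture how conflict-induced slowing evolves across the RT
distribution: per subject, pro and correct-anti RTs are each split into six
quantile ranges (0-10, 10-30, 30-50, 50-70, 70-90, 90-100 percent), the mean
RT of the matching ranges is averaged (x-axis) and differenced anti minus
pro (y-axis).  A decreasing delta slope indicates that the conflict between
the prepotent and instructed response is resolved as time passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .data import SubjectData

DEFAULT_RANGES: tuple[tuple[float, float], ...] = (
    (0.0, 0.1),
    (0.1, 0.3),
    (0.3, 0.5),
    (0.5, 0.7),
    (0.7, 0.9),
    (0.9, 1.0),
)


@dataclass
class SummaryStats:
    """Per-subject behavioral summary; empty cells are None, not 0."""

    pro_rt_mean: float | None
    pro_rt_sd: float | None
    anti_correct_rt_mean: float | None
    anti_correct_rt_sd: float | None
    anti_error_rt_mean: float | None
    anti_error_rt_sd: float | None
    anti_accuracy: float
    n_pro: int
    n_anti_correct: int
    n_anti_error: int


def _cell(rts: np.ndarray):
    if rts.size == 0:
        return None, None
    sd = float(np.std(rts, ddof=1)) if rts.size > 1 else None
    return float(np.mean(rts)), sd


def summary_stats(subject: SubjectData) -> SummaryStats:
    """Mean/SD of pro, correct-anti and error-anti RTs plus anti accuracy."""
    n_anti = len(subject.anti_rts)
    if n_anti == 0:
        raise ValueError("anti accuracy is undefined without antisaccade trials")
    pro_m, pro_s = _cell(subject.pro_rts)
    cor_m, cor_s = _cell(subject.anti_correct_rts)
    err_m, err_s = _cell(subject.anti_error_rts)
    return SummaryStats(
        pro_rt_mean=pro_m,
        pro_rt_sd=pro_s,
        anti_correct_rt_mean=cor_m,
        anti_correct_rt_sd=cor_s,
        anti_error_rt_mean=err_m,
        anti_error_rt_sd=err_s,
        anti_accuracy=float(subject.anti_correct.mean()),
        n_pro=len(subject.pro_rts),
        n_anti_correct=int(subject.anti_correct.sum()),
        n_anti_error=int((~subject.anti_correct).sum()),
    )


def quantile_range_means(rts, ranges=DEFAULT_RANGES) -> np.ndarray:
    """Mean RT within each quantile range.

    The sorted i-th of n RTs (i = 1..n) sits at quantile position
    (i - 0.5)/n; a range [lo, hi) collects the RTs whose positions fall in
    it (the last range is closed at 1).  Empty ranges yield NaN.
    """
    rts = np.sort(np.asarray(rts, dtype=float))
    n = rts.size
    if n == 0:
        raise ValueError("need at least one RT")
    pos = (np.arange(1, n + 1) - 0.5) / n
    out = np.full(len(ranges), np.nan)
    for j, (lo, hi) in enumerate(ranges):
        closed = j == len(ranges) - 1
        sel = (pos >= lo) & ((pos <= hi) if closed else (pos < hi))
        if sel.any():
            out[j] = rts[sel].mean()
    return out


@dataclass
class DeltaPlot:
    """Six-point delta plot: x = (anti + pro)/2 range means, y = anti - pro."""

    x: np.ndarray
    y: np.ndarray
    ranges: tuple = DEFAULT_RANGES


def delta_plot(subject: SubjectData, ranges=DEFAULT_RANGES, min_trials: int = 6) -> DeltaPlot:
    """Per-subject delta plot from pro and correct-anti RTs.

    Error antisaccades are excluded.  With fewer than ``min_trials`` in
    either condition all points are NaN (missing, propagated downstream).
    """
    pro = subject.pro_rts
    anti = subject.anti_correct_rts
    k = len(ranges)
    if len(pro) < min_trials or len(anti) < min_trials:
        return DeltaPlot(x=np.full(k, np.nan), y=np.full(k, np.nan), ranges=tuple(ranges))
    mp = quantile_range_means(pro, ranges)
    ma = quantile_range_means(anti, ranges)
    return DeltaPlot(x=(ma + mp) / 2.0, y=ma - mp, ranges=tuple(ranges))


def group_delta_plot(subjects, ranges=DEFAULT_RANGES):
    """Pointwise mean and standard error across subjects' delta plots.

    Subjects with missing points are dropped pointwise.  Returns
    ``(x_mean, y_mean, y_se)`` arrays of length ``len(ranges)``.
    """
    xs, ys = [], []
    for s in subjects:
        dp = delta_plot(s, ranges)
        xs.append(dp.x)
        ys.append(dp.y)
    X = np.vstack(xs)
    Y = np.vstack(ys)
    with np.errstate(invalid="ignore"):
        x_mean = np.nanmean(X, axis=0)
        y_mean = np.nanmean(Y, axis=0)
        n = np.sum(np.isfinite(Y), axis=0)
        y_se = np.nanstd(Y, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return x_mean, y_mean, y_se


@dataclass
class GroupCompareResult:
    statistic: float
    df: float
    pvalue: float
    degenerate: bool = False  # both groups constant and equal-variance-zero


def group_compare(group_a, group_b, welch: bool = False) -> GroupCompareResult:
    """Two-sample t test of per-subject values (pooled variance by default).

    The pooled test matches the df convention n1 + n2 - 2; ``welch=True``
    switches to the unequal-variance form.  Zero pooled variance is flagged
    rather than raising.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return GroupCompareResult(0.0, a.size + b.size - 2, 1.0, degenerate=True)
        return GroupCompareResult(np.inf, a.size + b.size - 2, 0.0, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else a.size + b.size - 2
    return GroupCompareResult(float(res.statistic), df, float(res.pvalue))
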