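"""Nonparametric circadian rhythm indicators.

Interdaily stability (IS), intradaily variability (IV), the most-active
10-hour (M10) and least-active 5-hour (L5) windows, social jet lag, and
per-participant aggregation into an indicator row.

IS is the ratio of the variance of the average 24-hour profile to the
total variance,

    IS = N * sum_h (xbar_h - xbar)^2 / (p * sum_i (x_i - xbar)^2),

where N is the total number of data points, p the number of points per
day, xbar_h the per-hour means and xbar the grand mean.  It lies in
[0, 1]; 1 means every day repeats the same profile.  IV is the
normalized mean squared successive difference,

    IV = N * sum_i (x_i - x_{i-1})^2 / ((N - 1) * sum_i (x_i - xbar)^2),

roughly 0-2 for rhythmic data (2 for white noise); it quantifies
rest-activity fragmentation.  Both are computed on hourly-binned data
(p = 24) for both modalities and are invariant to affine rescaling of
the counts.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from datetime import date as Date
from datetime import time, timedelta
from typing import Optional, Sequence

import numpy as np

from .timeseries import (
    MIDNIGHT,
    EpochSeries,
    HourlyProfile,
    bin_to_hours,
    hourly_matrix,
    hourly_profile,
    segment_days,
)

__all__ = [
    "CircadianIndicators",
    "WindowResult",
    "M10L5",
    "interdaily_stability",
    "is_from_profile",
    "intradaily_variability",
    "m10_l5",
    "social_jetlag",
    "summarize_participant",
]

logger = logging.getLogger(__name__)

#: Wake-morning weekdays counted as free days (Sat=5, Sun=6).
DEFAULT_FREE_WEEKDAYS = frozenset({5, 6})


@dataclass
class WindowResult:
    """Mean level and window-start clock time for an M10/L5 window."""

    mean: float
    onset_hours: float  # clock hours of the window start, [0, 24)


@dataclass
class M10L5:
    m10: WindowResult
    l5: WindowResult
    n_days: int


@dataclass
class CircadianIndicators:
    """One participant x modality row of circadian and sleep indicators."""

    participant_id: str
    source: str  # "app" | "actigraphy"
    IS: float = math.nan
    IV: float = math.nan
    M10: float = math.nan
    M10_onset: float = math.nan
    L5: float = math.nan
    L5_onset: float = math.nan
    mean_onset: float = math.nan
    mean_wake: float = math.nan
    mean_midpoint: float = math.nan
    mean_waso: float = math.nan
    mean_tst: float = math.nan
    social_jetlag: float = math.nan
    n_days: int = 0


# ---------------------------------------------------------------------------
# IS / IV


def is_from_profile(profile: HourlyProfile, points: np.ndarray) -> float:
    """Evaluate the IS ratio from a profile and its underlying points.

    ``points`` are the valid (hourly-binned) data points the profile was
    built from.  Raises on zero total variance.
    """
    xbar = profile.grand_mean
    dev = points - xbar
    sst = float(np.sum(dev * dev))
    if sst <= 0.0:
        raise ValueError("IS undefined for constant input")
    h = profile.bin_means[~np.isnan(profile.bin_means)]
    num = profile.n_points * float(np.sum((h - xbar) ** 2))
    value = num / (profile.bins_per_day * sst)
    if value > 1.0 or value < 0.0:
        logger.info("IS %.6f outside [0, 1]; clipping", value)
        value = min(max(value, 0.0), 1.0)
    return value


def _hourly_points(matrix: np.ndarray) -> np.ndarray:
    flat = matrix.reshape(-1)
    return flat[~np.isnan(flat)]


def interdaily_stability(
    series: EpochSeries,
    day_anchor: time = MIDNIGHT,
) -> float:
    """Interdaily stability of a count series, hourly-binned (p = 24).

    Requires at least two complete days and nonzero total variance.
    """
    hourly = series if series.epoch_length == 3600 else bin_to_hours(
        series, day_anchor
    )
    segs = [s for s in segment_days(hourly, day_anchor) if s.valid]
    if len(segs) < 2:
        raise ValueError("IS needs at least 2 complete days")
    mat = hourly_matrix(hourly, segs, bin_seconds=3600, agg="mean")
    profile = hourly_profile(hourly, segs, bin_seconds=3600)
    return is_from_profile(profile, _hourly_points(mat))


def intradaily_variability(
    series: EpochSeries,
    day_anchor: time = MIDNIGHT,
    hourly_bin: bool = True,
) -> float:
    """Intradaily variability (normalized mean squared successive diff).

    First differences are taken between consecutive valid epochs only;
    pairs spanning an invalid gap are skipped (the denominator count of
    difference pairs shrinks accordingly).
    """
    if hourly_bin and series.epoch_length != 3600:
        series = bin_to_hours(series, day_anchor)
    vals = series.values
    ok = series.valid_mask
    pts = vals[ok]
    if pts.size < 2:
        raise ValueError("IV needs at least 2 valid epochs")
    xbar = pts.mean()
    sst = float(np.sum((pts - xbar) ** 2))
    if sst <= 0.0:
        raise ValueError("IV undefined for constant input")
    pair = ok[1:] & ok[:-1]
    n_pairs = int(pair.sum())
    if n_pairs == 0:
        raise ValueError("no consecutive valid epoch pairs")
    diffs = (vals[1:] - vals[:-1])[pair]
    return pts.size * float(np.sum(diffs * diffs)) / (n_pairs * sst)


# ---------------------------------------------------------------------------
# M10 / L5


def _window_stats(
    day_vals: np.ndarray, day_ok: np.ndarray, width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Means of every wrap-around window of ``width`` epochs.

    Returns (means, usable) where windows containing any invalid epoch
    are flagged unusable.
    """
    n = day_vals.size
    ext = np.concatenate([day_vals, day_vals[: width - 1]])
    ext_ok = np.concatenate([day_ok, day_ok[: width - 1]])
    kern = np.ones(width)
    sums = np.convolve(np.where(ext_ok, ext, 0.0), kern, mode="valid")[:n]
    bad = np.convolve((~ext_ok).astype(float), kern, mode="valid")[:n]
    usable = bad == 0
    with np.errstate(invalid="ignore"):
        means = sums / width
    return means, usable


def _circular_mean_hours(hours: np.ndarray) -> float:
    ang = np.asarray(hours) * (2 * np.pi / 24.0)
    mean = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
    return (mean * 24.0 / (2 * np.pi)) % 24.0


def m10_l5(
    series: EpochSeries,
    day_anchor: time = MIDNIGHT,
) -> M10L5:
    """Most-active 10-h and least-active 5-h windows, averaged over days.

    Per day, sliding (epoch-stride, wrap-around) window means are
    computed over the counts; M10 is the maximum 10-h window mean and L5
    the minimum 5-h window mean, with the window start reported as a
    clock time.  A day is skipped when missing epochs contaminate every
    candidate window.  Participant-level values average across days; the
    onsets are averaged circularly.
    """
    segs = [s for s in segment_days(series, day_anchor) if s.valid]
    if not segs:
        raise ValueError("M10/L5 need at least one complete day")
    w10 = 10 * 3600 // series.epoch_length
    w5 = 5 * 3600 // series.epoch_length
    hours_per_epoch = series.epoch_length / 3600.0
    anchor_h = day_anchor.hour + day_anchor.minute / 60.0

    m10s, m10_on, l5s, l5_on = [], [], [], []
    for seg in segs:
        vals = series.values[seg.start_idx : seg.stop_idx]
        ok = series.valid_mask[seg.start_idx : seg.stop_idx]
        means10, use10 = _window_stats(vals, ok, w10)
        means5, use5 = _window_stats(vals, ok, w5)
        if not use10.any() or not use5.any():
            continue
        i10 = int(np.nanargmax(np.where(use10, means10, -np.inf)))
        i5 = int(np.nanargmin(np.where(use5, means5, np.inf)))
        m10s.append(means10[i10])
        l5s.append(means5[i5])
        m10_on.append((anchor_h + i10 * hours_per_epoch) % 24.0)
        l5_on.append((anchor_h + i5 * hours_per_epoch) % 24.0)
    if not m10s:
        raise ValueError("no day had a complete candidate window")
    return M10L5(
        m10=WindowResult(float(np.mean(m10s)), _circular_mean_hours(np.array(m10_on))),
        l5=WindowResult(float(np.mean(l5s)), _circular_mean_hours(np.array(l5_on))),
        n_days=len(m10s),
    )


# ---------------------------------------------------------------------------
# Social jet lag


def _is_free(night_date: Date, free_weekdays: frozenset[int]) -> bool:
    # a night belongs to the morning it ends on
    return (night_date + timedelta(days=1)).weekday() in free_weekdays


def social_jetlag(
    episodes: Sequence,
    free_weekdays: frozenset[int] = DEFAULT_FREE_WEEKDAYS,
) -> Optional[float]:
    """|mean free-day midsleep - mean workday midsleep| in decimal hours.

    A night is a "free-day" night when the morning it ends on falls on a
    free weekday (default Sat/Sun).  Returns None (unavailable) unless
    both classes have at least two episodes.
    """
    free = [e.midpoint for e in episodes if _is_free(e.date, free_weekdays)]
    work = [e.midpoint for e in episodes if not _is_free(e.date, free_weekdays)]
    if len(free) < 2 or len(work) < 2:
        return None
    return abs(float(np.mean(free)) - float(np.mean(work)))


# ---------------------------------------------------------------------------
# Aggregation


def summarize_participant(
    participant_id: str,
    source: str,
    episodes: Sequence,
    counts: EpochSeries,
    day_anchor: time = MIDNIGHT,
    free_weekdays: frozenset[int] = DEFAULT_FREE_WEEKDAYS,
) -> CircadianIndicators:
    """Aggregate one participant's episodes and counts into one row.

    IS/IV use hourly-binned counts; fewer than 7 complete days triggers a
    low-confidence warning (the values are still computed).  An empty
    episode list leaves the sleep fields NaN but still emits the row.
    """
    row = CircadianIndicators(participant_id=participant_id, source=source)

    segs = [s for s in segment_days(counts, day_anchor) if s.valid]
    row.n_days = len(segs)
    if row.n_days < 7:
        warnings.warn(
            f"{participant_id}/{source}: only {row.n_days} complete days; "
            "IS/IV are low-confidence below 7 days",
            stacklevel=2,
        )
    try:
        row.IS = interdaily_stability(counts, day_anchor)
        row.IV = intradaily_variability(counts, day_anchor)
    except ValueError:
        pass  # constant / too-short series: indicators stay NaN

    try:
        windows = m10_l5(counts, day_anchor)
    except ValueError:
        windows = None
    if windows is not None:
        row.M10 = windows.m10.mean
        row.M10_onset = windows.m10.onset_hours
        row.L5 = windows.l5.mean
        row.L5_onset = windows.l5.onset_hours

    episodes = [e for e in episodes if e is not None]
    if episodes:
        row.mean_onset = float(np.mean([e.onset for e in episodes]))
        row.mean_wake = float(np.mean([e.wake for e in episodes]))
        row.mean_midpoint = float(np.mean([e.midpoint for e in episodes]))
        row.mean_waso = float(np.mean([e.waso for e in episodes]))
        row.mean_tst = float(np.mean([e.tst for e in episodes]))
        sjl = social_jetlag(episodes, free_weekdays)
        row.social_jetlag = math.nan if sjl is None else sjl
    return row
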