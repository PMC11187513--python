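"""Smartphone app-count rhythm extraction and sleep detection.

The "app-count" method treats timestamped human-smartphone interaction
events the way actigraphy treats wrist movement: events are counted per
minute, the per-minute counts are summed into nonoverlapping 5-minute
epochs (288 per day), the epoch series is band-pass filtered to the
near-24-hour band (16-24 h periods), putative sleep is located at the
half-cycle around the filtered signal's nadir, and sleep onset / wake
are detected inside that window by run-length rules:

* onset  = start of the first run of >= 8 consecutive zero-count epochs,
* wake   = start of the first run of >= 6 consecutive nonzero epochs
  after onset (window end if no such run occurs),
* WASO   = 5 min x number of nonzero epochs strictly between onset and
  wake,
* TST    = (wake - onset) - WASO.

Times are reported in decimal clock hours past the midnight of the
night's reference date; times after that midnight carry +24 (00:21 on
the following morning is 24.35), so averaging across nights does not
wrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, time, timedelta
from typing import Optional

import numpy as np
from scipy import signal

from .timeseries import (
    MIDNIGHT,
    EpochSeries,
    EventLog,
    segment_days,
)

__all__ = [
    "APP_EPOCH_SECONDS",
    "EPOCHS_PER_DAY",
    "InactiveWindow",
    "SleepEpisode",
    "events_to_appcounts",
    "circadian_bandpass",
    "extract_inactive_window",
    "detect_sleep_episode",
    "app_sleep_episodes",
]

APP_EPOCH_SECONDS = 300
EPOCHS_PER_DAY = 86400 // APP_EPOCH_SECONDS  # 288

#: Run-length rules (config-overridable through detect_sleep_episode).
ONSET_ZERO_RUN = 8
WAKE_NONZERO_RUN = 6

#: Half-cycle window length bounds, hours.
MIN_WINDOW_H = 4.0
MAX_WINDOW_H = 16.0


@dataclass(frozen=True)
class InactiveWindow:
    """One night's putative-sleep search window.

    ``date`` is the noon-to-noon day containing the filtered-cycle
    trough (i.e. the evening the night starts); ``start_epoch`` /
    ``stop_epoch`` index the parent app-count series (half-open).
    """

    date: Date
    start_epoch: int
    stop_epoch: int
    trough_epoch: int


@dataclass
class SleepEpisode:
    """One night's sleep episode in decimal clock hours.

    onset/wake/midpoint are hours past midnight of ``date``; values > 24
    denote times after that midnight (24.35 == 00:21 the next morning).
    """

    date: Date
    onset: float
    wake: float
    midpoint: float
    waso: float  # minutes
    tst: float  # minutes
    source: str  # "app" | "actigraphy"

    def __post_init__(self) -> None:
        if self.wake <= self.onset:
            raise ValueError("wake must be after onset")
        if self.waso < 0:
            raise ValueError("WASO must be nonnegative")


# ---------------------------------------------------------------------------
# Events -> app-counts


def events_to_appcounts(
    log: EventLog,
    include_notifications: bool = False,
    span: Optional[tuple[Date, int]] = None,
) -> EpochSeries:
    """Aggregate an event log into 5-minute app-counts.

    The per-minute use count is the number of interaction events whose
    timestamp falls in that minute (screen on/off and app_use; whether a
    notification arrival counts as use is configurable and off by
    default, since it is not a user action).  Each 5-minute epoch value
    is the sum of its minutes' counts; minutes without events contribute
    zero.  The series spans whole calendar days: midnight of the first
    event's date through midnight after the last (or the explicit
    ``span`` = (first_date, n_days)).
    """
    counted = {"screen_on", "screen_off", "app_use"}
    if include_notifications:
        counted = counted | {"notification"}
    events = [e for e in log.records if e.kind in counted]
    if span is not None:
        first, n_days = span
    else:
        if not events:
            raise ValueError(
                "no countable events and no explicit span; span required"
            )
        first = events[0].timestamp.date()
        n_days = (events[-1].timestamp.date() - first).days + 1
    start = datetime.combine(first, MIDNIGHT)
    n_epochs = n_days * EPOCHS_PER_DAY
    values = np.zeros(n_epochs)
    for e in events:
        idx = math.floor(
            (e.timestamp - start).total_seconds() / APP_EPOCH_SECONDS
        )
        if 0 <= idx < n_epochs:
            values[idx] += 1
    return EpochSeries(start, APP_EPOCH_SECONDS, values)


# ---------------------------------------------------------------------------
# 16-24 h cycle extraction


def circadian_bandpass(
    values: np.ndarray,
    epoch_seconds: int = APP_EPOCH_SECONDS,
    period_band_hours: tuple[float, float] = (16.0, 24.0),
) -> np.ndarray:
    """Zero-phase band-pass keeping ~16-24 h periods.

    Second-order-section Butterworth run forward and backward
    (scipy ``sosfiltfilt``) so sleep timing is not phase-shifted.  The
    series is extended by two days of circular (wrap-around) padding
    before filtering: the signal of interest is near-day-periodic, so
    periodic extension keeps the edge days' phase intact where mirror
    reflection leaves a multi-hour trough drift on the first and last
    day (the filter's transient is long at a 24 h corner).
    """
    fs = 1.0 / epoch_seconds  # Hz
    lo_p, hi_p = period_band_hours
    f_lo = 1.0 / (hi_p * 3600.0)
    f_hi = 1.0 / (lo_p * 3600.0)
    sos = signal.butter(2, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    pad = min(2 * 86400 // epoch_seconds, len(values))
    ext = np.concatenate([values[-pad:], values, values[:pad]])
    filtered = signal.sosfiltfilt(sos, ext, padtype="even")
    return filtered[pad : pad + len(values)]


def _dominant_period_epochs(filtered: np.ndarray, epoch_seconds: int) -> float:
    """Dominant period of the filtered signal, in epochs, via the FFT peak."""
    x = filtered - filtered.mean()
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0)
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if freqs[k] <= 0:
        return 24 * 3600 / epoch_seconds
    return 1.0 / freqs[k]


def extract_inactive_window(
    appcounts: EpochSeries,
    day_anchor: time = MIDNIGHT,
) -> list[InactiveWindow]:
    """Locate each day's putative-sleep half-cycle.

    The epoch series is band-passed to 16-24 h periods; per calendar
    day the trough of the filtered signal is found and the window is the
    half-cycle centred there (trough +/- a quarter of the dominant
    period), clipped to [4 h, 16 h] and to the series bounds.  Windows
    truncated below 4 h by a series edge are dropped.  Raises on a flat
    (constant) series — no circadian cycle is detectable.
    """
    segs = [s for s in segment_days(appcounts, day_anchor) if s.valid]
    if len(segs) < 2:
        raise ValueError("need at least 2 complete days of app-counts")
    vals = appcounts.values
    if np.ptp(vals) == 0:
        raise ValueError("no circadian cycle detectable: constant input")
    filt = circadian_bandpass(vals, appcounts.epoch_length)
    if float(np.std(filt)) < 1e-9 * max(1.0, float(np.std(vals))):
        raise ValueError("no circadian cycle detectable: flat filtered signal")

    period = _dominant_period_epochs(filt, appcounts.epoch_length)
    quarter = period / 4.0
    eph = 3600.0 / appcounts.epoch_length  # epochs per hour
    quarter = min(max(quarter, MIN_WINDOW_H / 2 * eph), MAX_WINDOW_H / 2 * eph)

    by_date: dict[Date, InactiveWindow] = {}
    for seg in segs:
        trough = seg.start_idx + int(
            np.argmin(filt[seg.start_idx : seg.stop_idx])
        )
        lo = max(0, int(round(trough - quarter)))
        hi = min(len(appcounts), int(round(trough + quarter)))
        if (hi - lo) < MIN_WINDOW_H * eph:
            continue  # truncated by the recording edge
        night = (
            appcounts.epoch_time(trough) - timedelta(hours=12)
        ).date()
        prev = by_date.get(night)
        if prev is None or filt[trough] < filt[prev.trough_epoch]:
            by_date[night] = InactiveWindow(night, lo, hi, trough)
    return [by_date[d] for d in sorted(by_date)]


# ---------------------------------------------------------------------------
# Run-length sleep detection


def _first_run_at_least(mask: np.ndarray, length: int) -> Optional[int]:
    """Start index of the first run of True of at least ``length``."""
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= length:
            return i - length + 1
    return None


def detect_sleep_episode(
    appcounts: EpochSeries,
    window: InactiveWindow,
    onset_zero_run: int = ONSET_ZERO_RUN,
    wake_nonzero_run: int = WAKE_NONZERO_RUN,
) -> Optional[SleepEpisode]:
    """Apply the run-length rules inside one inactive window.

    Returns None when no qualifying onset run exists for that date.
    """
    seg = appcounts.values[window.start_epoch : window.stop_epoch]
    zero = seg == 0

    onset_rel = _first_run_at_least(zero, onset_zero_run)
    if onset_rel is None:
        return None
    wake_off = _first_run_at_least(~zero[onset_rel:], wake_nonzero_run)
    if wake_off is None:
        wake_rel = len(seg)
    else:
        wake_rel = onset_rel + wake_off
    waso_epochs = int(np.count_nonzero(seg[onset_rel:wake_rel] != 0))
    waso = 5.0 * waso_epochs

    midnight = datetime.combine(window.date, MIDNIGHT)
    epoch_h = appcounts.epoch_length / 3600.0

    def decimal_hours(rel: int) -> float:
        t = appcounts.epoch_time(window.start_epoch + rel)
        return (t - midnight).total_seconds() / 3600.0

    onset = decimal_hours(onset_rel)
    wake = decimal_hours(wake_rel)
    tst = (wake - onset) * 60.0 - waso
    return SleepEpisode(
        date=window.date,
        onset=onset,
        wake=wake,
        midpoint=(onset + wake) / 2.0,
        waso=waso,
        tst=tst,
        source="app",
    )


def app_sleep_episodes(
    appcounts: EpochSeries,
    day_anchor: time = MIDNIGHT,
    onset_zero_run: int = ONSET_ZERO_RUN,
    wake_nonzero_run: int = WAKE_NONZERO_RUN,
) -> list[SleepEpisode]:
    """Full app pipeline: inactive windows then per-night episodes."""
    windows = extract_inactive_window(appcounts, day_anchor)
    episodes = []
    for w in windows:
        ep = detect_sleep_episode(
            appcounts, w, onset_zero_run, wake_nonzero_run
        )
        if ep is not None:
            episodes.append(ep)
    return episodes
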