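"""Core time-series containers and day-level plumbing.

Both measurement modalities — wrist actigraphy counts and smartphone
app-counts — are regularly sampled nonnegative count series with a
validity mask.  This module provides the shared containers
(:class:`EventLog`, :class:`EpochSeries`), anchor-to-anchor day
segmentation, per-day-bin (hourly) profiles, and delimited-text I/O.

Conventions
-----------
* All timestamps are timezone-naive local wall-clock datetimes.
* Missing epochs are marked ``valid_mask=False``; a zero value is a
  meaningful observation (no interaction / no movement), never a gap.
* Epochs are half-open intervals ``[t, t + epoch_length)``; an event at
  time ``t`` belongs to the epoch whose start floor-aligns to ``t``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, time, timedelta
from typing import Iterable, Optional, Sequence, TextIO

import numpy as np

__all__ = [
    "EVENT_KINDS",
    "Event",
    "EventLog",
    "EpochSeries",
    "DailySegment",
    "HourlyProfile",
    "read_event_log",
    "read_epoch_series",
    "write_epoch_series",
    "segment_days",
    "hourly_matrix",
    "hourly_profile",
    "bin_to_hours",
    "write_indicators",
    "read_indicators",
]

#: Closed set of smartphone interaction event kinds.
EVENT_KINDS = frozenset({"screen_on", "screen_off", "notification", "app_use"})

SECONDS_PER_DAY = 86400
MIDNIGHT = time(0, 0)


@dataclass(frozen=True)
class Event:
    """A single timestamped smartphone interaction record."""

    timestamp: datetime
    kind: str
    app_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(
                f"unknown event kind {self.kind!r}; expected one of "
                f"{sorted(EVENT_KINDS)}"
            )


@dataclass
class EventLog:
    """Ordered smartphone interaction events.

    Timestamps are nondecreasing; the constructor sorts if needed.
    """

    records: list[Event]

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda e: e.timestamp)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def start(self) -> datetime:
        return self.records[0].timestamp

    @property
    def end(self) -> datetime:
        return self.records[-1].timestamp

    def dates(self) -> list[Date]:
        """Calendar dates touched by the log, sorted."""
        return sorted({e.timestamp.date() for e in self.records})

    def shifted(self, delta: timedelta) -> "EventLog":
        """A copy with every timestamp shifted by ``delta``."""
        return EventLog(
            [Event(e.timestamp + delta, e.kind, e.app_id) for e in self.records]
        )


@dataclass
class EpochSeries:
    """Regularly sampled nonnegative values with a validity mask.

    Parameters
    ----------
    start
        Wall-clock datetime of the first epoch's left edge, aligned to an
        epoch boundary relative to midnight.
    epoch_length
        Epoch length in seconds (60 for acti-counts, 300 for app-counts,
        3600 for hourly-binned series).
    values
        Nonnegative counts, one per epoch.
    valid_mask
        Booleans aligned to ``values``; ``False`` marks missing epochs.
    """

    start: datetime
    epoch_length: int
    values: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.values), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(self.values) != len(self.valid_mask):
            raise ValueError("values and valid_mask lengths differ")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if np.any(self.values[self.valid_mask] < 0):
            raise ValueError("values must be nonnegative")
        offset = (
            self.start - datetime.combine(self.start.date(), MIDNIGHT)
        ).total_seconds()
        if offset % self.epoch_length != 0:
            raise ValueError("start is not aligned to an epoch boundary")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> datetime:
        return self.start + timedelta(seconds=self.epoch_length * len(self))

    @property
    def epochs_per_day(self) -> int:
        if SECONDS_PER_DAY % self.epoch_length != 0:
            raise ValueError(
                f"epoch length {self.epoch_length} s does not divide 24 h"
            )
        return SECONDS_PER_DAY // self.epoch_length

    def epoch_time(self, index: int) -> datetime:
        """Wall-clock left edge of epoch ``index``."""
        return self.start + timedelta(seconds=self.epoch_length * index)

    def index_of(self, when: datetime) -> int:
        """Epoch index containing ``when`` (may be out of range)."""
        return math.floor(
            (when - self.start).total_seconds() / self.epoch_length
        )

    def shifted(self, delta: timedelta) -> "EpochSeries":
        return EpochSeries(
            self.start + delta,
            self.epoch_length,
            self.values.copy(),
            self.valid_mask.copy(),
        )


@dataclass(frozen=True)
class DailySegment:
    """One anchor-to-anchor day's slice into a parent :class:`EpochSeries`.

    ``valid=False`` marks partial first/last days (and days failing
    modality-specific exclusion rules downstream).
    """

    date: Date
    start_idx: int
    stop_idx: int
    valid: bool

    def __len__(self) -> int:
        return self.stop_idx - self.start_idx


@dataclass
class HourlyProfile:
    """Per-day-bin means of an epoch series.

    ``bin_means[h]`` is the mean of all valid epoch values falling in bin
    ``h`` across days (NaN where the bin has no valid epoch);
    ``grand_mean`` is the mean of all valid epochs; ``n_points`` (N) and
    ``bins_per_day`` (p) feed the interdaily-stability formula.
    """

    bin_means: np.ndarray
    grand_mean: float
    n_days: int
    n_points: int
    bins_per_day: int


# ---------------------------------------------------------------------------
# I/O


def _open_text(source) -> TextIO:
    if isinstance(source, (str, bytes)):
        return open(source, "r", newline="")
    return source


def read_event_log(source, delimiter: str = ",") -> EventLog:
    """Parse a delimited event-log stream into an :class:`EventLog`.

    Expected columns: ``timestamp`` (ISO-8601), ``kind``, ``app_id``
    (optional, may be empty).  A header row is required.  Any
    unparseable row raises :class:`ValueError` naming its line number.
    """
    close = isinstance(source, (str, bytes))
    fh = _open_text(source)
    try:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError("empty event log") from None
        header = [h.strip().lower() for h in header]
        try:
            t_col = header.index("timestamp")
            k_col = header.index("kind")
        except ValueError:
            raise ValueError(
                f"event log header must contain 'timestamp' and 'kind'; got {header}"
            ) from None
        a_col = header.index("app_id") if "app_id" in header else None

        records: list[Event] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                ts = datetime.fromisoformat(row[t_col].strip())
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"line {lineno}: unparseable timestamp {row!r}"
                ) from exc
            kind = row[k_col].strip()
            if kind not in EVENT_KINDS:
                raise ValueError(
                    f"line {lineno}: unknown event kind {kind!r}"
                )
            app_id = None
            if a_col is not None and len(row) > a_col and row[a_col].strip():
                app_id = row[a_col].strip()
            records.append(Event(ts, kind, app_id))
    finally:
        if close:
            fh.close()
    if not records:
        raise ValueError("event log contains no records")
    return EventLog(records)


def read_epoch_series(source, delimiter: str = ",") -> EpochSeries:
    """Read an epoch series from delimited text (timestamp,value,valid)."""
    close = isinstance(source, (str, bytes))
    fh = _open_text(source)
    try:
        reader = csv.reader(fh, delimiter=delimiter)
        header = [h.strip().lower() for h in next(reader)]
        t_col, v_col = header.index("timestamp"), header.index("value")
        m_col = header.index("valid") if "valid" in header else None
        times: list[datetime] = []
        values: list[float] = []
        mask: list[bool] = []
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            times.append(datetime.fromisoformat(row[t_col].strip()))
            values.append(float(row[v_col]))
            mask.append(
                row[m_col].strip().lower() in ("1", "true", "t")
                if m_col is not None
                else True
            )
    finally:
        if close:
            fh.close()
    if len(times) < 2:
        raise ValueError("epoch series needs at least two rows")
    step = (times[1] - times[0]).total_seconds()
    if step <= 0 or any(
        abs((times[i + 1] - times[i]).total_seconds() - step) > 1e-6
        for i in range(len(times) - 1)
    ):
        raise ValueError("timestamps are not regularly spaced")
    return EpochSeries(times[0], int(step), np.array(values), np.array(mask))


def write_epoch_series(series: EpochSeries, sink, delimiter: str = ",") -> None:
    close = isinstance(sink, (str, bytes))
    fh = open(sink, "w", newline="") if close else sink
    try:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["timestamp", "value", "valid"])
        for i, (v, ok) in enumerate(zip(series.values, series.valid_mask)):
            writer.writerow(
                [series.epoch_time(i).isoformat(), f"{v:.10g}", int(ok)]
            )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Day segmentation and profiles


def segment_days(
    series: EpochSeries, day_anchor: time = MIDNIGHT
) -> list[DailySegment]:
    """Split a series into anchor-to-anchor day segments.

    One segment is returned for every day touched by the recording;
    partial first/last days are flagged ``valid=False``.  Segments tile
    the recording without overlap.
    """
    if len(series) == 0:
        raise ValueError("cannot segment an empty series")
    epd = series.epochs_per_day  # raises if epoch_length does not divide 24 h

    anchor = datetime.combine(series.start.date(), day_anchor)
    if anchor > series.start:
        anchor -= timedelta(days=1)
    segments: list[DailySegment] = []
    n = len(series)
    while True:
        nxt = anchor + timedelta(days=1)
        lo = series.index_of(anchor)
        hi = series.index_of(nxt)
        start_idx = max(lo, 0)
        stop_idx = min(hi, n)
        if start_idx >= n:
            break
        if stop_idx > start_idx:
            complete = lo >= 0 and hi <= n
            segments.append(
                DailySegment(anchor.date(), start_idx, stop_idx, complete)
            )
        anchor = nxt
        if hi >= n:
            break
    return segments


def hourly_matrix(
    series: EpochSeries,
    segments: Sequence[DailySegment],
    bin_seconds: int = 3600,
    agg: str = "mean",
) -> np.ndarray:
    """Stack valid day segments into a (n_days, bins_per_day) matrix.

    Each cell aggregates the valid epochs of one bin of one day
    (``agg`` in {"mean", "sum"}); cells with no valid epoch are NaN.
    """
    if SECONDS_PER_DAY % bin_seconds or bin_seconds % series.epoch_length:
        raise ValueError("bin length must divide 24 h and be a multiple of the epoch")
    per_bin = bin_seconds // series.epoch_length
    p = SECONDS_PER_DAY // bin_seconds
    days = [s for s in segments if s.valid]
    out = np.full((len(days), p), np.nan)
    for d, seg in enumerate(days):
        vals = series.values[seg.start_idx : seg.stop_idx].reshape(p, per_bin)
        ok = series.valid_mask[seg.start_idx : seg.stop_idx].reshape(p, per_bin)
        cnt = ok.sum(axis=1)
        tot = np.where(ok, vals, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            cell = tot / cnt if agg == "mean" else tot.astype(float)
        cell[cnt == 0] = np.nan
        out[d] = cell
    return out


def hourly_profile(
    series: EpochSeries,
    segments: Sequence[DailySegment],
    bin_seconds: int = 3600,
) -> HourlyProfile:
    """Per-bin means across valid days plus the grand mean.

    Raises if no segment is valid or every bin is empty; individual
    empty bins are carried as NaN.
    """
    days = [s for s in segments if s.valid]
    if not days:
        raise ValueError("no valid day segments")
    mat = hourly_matrix(series, days, bin_seconds=bin_seconds, agg="mean")
    if np.all(np.isnan(mat)):
        raise ValueError("all bins empty")
    with np.errstate(invalid="ignore"):
        bin_means = np.nanmean(mat, axis=0)
    idx = np.concatenate(
        [np.arange(s.start_idx, s.stop_idx) for s in days]
    )
    ok = series.valid_mask[idx]
    pts = series.values[idx][ok]
    return HourlyProfile(
        bin_means=bin_means,
        grand_mean=float(pts.mean()),
        n_days=len(days),
        n_points=int(pts.size),
        bins_per_day=SECONDS_PER_DAY // bin_seconds,
    )


def bin_to_hours(
    series: EpochSeries,
    day_anchor: time = MIDNIGHT,
    agg: str = "sum",
) -> EpochSeries:
    """Rebin a finer epoch series to hourly epochs over its complete days.

    App-counts are summed 12 epochs -> 1 hour (``agg="sum"``); the choice
    of sum vs mean only rescales and the nonparametric indicators are
    affine-invariant.  Hours containing no valid epoch are masked.
    """
    segs = [s for s in segment_days(series, day_anchor) if s.valid]
    if not segs:
        raise ValueError("no complete days to bin")
    mat = hourly_matrix(series, segs, bin_seconds=3600, agg=agg)
    values = mat.reshape(-1)
    mask = ~np.isnan(values)
    values = np.where(mask, values, 0.0)
    start = datetime.combine(segs[0].date, day_anchor)
    return EpochSeries(start, 3600, values, mask)


# ---------------------------------------------------------------------------
# Indicator table I/O


def write_indicators(rows: Iterable, sink, delimiter: str = ",") -> None:
    """Write CircadianIndicators-like dataclass rows as delimited text.

    One header plus one row per participant; floats carry 10 significant
    digits so a round trip reproduces values well within 1e-6.
    """
    import dataclasses

    rows = list(rows)
    close = isinstance(sink, (str, bytes))
    fh = open(sink, "w", newline="") if close else sink
    try:
        writer = csv.writer(fh, delimiter=delimiter)
        if rows:
            names = [f.name for f in dataclasses.fields(rows[0])]
        else:
            from .metrics import CircadianIndicators

            names = [f.name for f in dataclasses.fields(CircadianIndicators)]
        writer.writerow(names)
        for row in rows:
            rec = dataclasses.asdict(row)
            out = []
            for name in names:
                v = rec[name]
                if v is None:
                    out.append("")
                elif isinstance(v, float):
                    out.append(f"{v:.10g}")
                else:
                    out.append(v)
            writer.writerow(out)
    finally:
        if close:
            fh.close()


def read_indicators(source, delimiter: str = ","):
    """Round-trip reader for :func:`write_indicators` output."""
    import pandas as pd

    return pd.read_csv(source, delimiter=delimiter)
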