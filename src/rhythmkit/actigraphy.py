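"""Wrist actigraphy processing: counts, wear detection, sleep scoring.

Pipeline
--------
1. :func:`accel_to_counts` — tri-axial acceleration (30 Hz expected) to
   1-minute activity counts: per-sample Euclidean norm of the deviations
   from zero, band-pass 0.5-3 Hz, rectification with a noise dead-band,
   integration over nonoverlapping 2-s windows, and averaging of the 30
   window values per minute.
2. :func:`flag_off_wrist_and_days` — sustained sub-threshold runs are
   off-wrist; a day with more than 6 h off-wrist is discarded.
3. :func:`cole_kripke_score` — the Cole-Kripke weighted moving sum over
   minute counts; D < 1 scores a minute as sleep.
4. :func:`actigraphy_sleep_episode` — the main (longest consolidated)
   sleep block per night window, with onset/wake/WASO/TST.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, time, timedelta
from typing import Optional

import numpy as np
from scipy import signal

from .timeseries import MIDNIGHT, EpochSeries, segment_days
from .smartphone import SleepEpisode

__all__ = [
    "RawAccel",
    "CountParams",
    "WearMask",
    "ColeKripkeParams",
    "MinuteSleepScores",
    "EpisodeRules",
    "accel_to_counts",
    "flag_off_wrist_and_days",
    "cole_kripke_score",
    "actigraphy_sleep_episode",
    "actigraphy_sleep_episodes",
    "SLEEP",
    "WAKE",
    "INVALID",
]

SLEEP, WAKE, INVALID = 0, 1, 2


@dataclass
class RawAccel:
    """Raw tri-axial acceleration in g."""

    start: datetime
    sample_rate: float  # Hz
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("axis arrays must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.ax)


@dataclass
class CountParams:
    """Count-derivation configuration.

    band_hz
        Pass band of the movement filter; 0.5-3 Hz keeps voluntary
        wrist movement and rejects both posture drift and tremor.
    noise_threshold
        Rectified magnitudes below this (g) are zeroed before
        integration (sensor noise dead-band).
    integration_seconds
        Nonoverlapping integration window; the per-minute count is the
        average of the windows in that minute.
    """

    band_hz: tuple[float, float] = (0.5, 3.0)
    noise_threshold: float = 0.01
    integration_seconds: float = 2.0
    filter_order: int = 2  # per-pass SOS order; zero-phase doubles it


def accel_to_counts(raw: RawAccel, params: CountParams = CountParams()) -> EpochSeries:
    """Derive 1-minute activity counts from raw acceleration.

    Output has one count per complete minute (floor of the recording
    duration); the filter is applied zero-phase so sleep timing is not
    delayed.
    """
    if raw.sample_rate < 2 * params.band_hz[1]:
        raise ValueError(
            f"sample rate {raw.sample_rate} Hz cannot represent the "
            f"{params.band_hz[1]} Hz passband edge (need >= "
            f"{2 * params.band_hz[1]} Hz)"
        )
    n_minutes = int(len(raw) // (raw.sample_rate * 60))
    if n_minutes < 1:
        raise ValueError("need at least one full minute of samples")

    norm = np.sqrt(raw.ax**2 + raw.ay**2 + raw.az**2)
    sos = signal.butter(
        params.filter_order,
        list(params.band_hz),
        btype="bandpass",
        fs=raw.sample_rate,
        output="sos",
    )
    filt = signal.sosfiltfilt(sos, norm)
    mag = np.abs(filt)
    mag[mag < params.noise_threshold] = 0.0

    win = int(round(params.integration_seconds * raw.sample_rate))
    n_win = int(len(raw) // win)
    integrated = mag[: n_win * win].reshape(n_win, win).sum(axis=1)
    per_min = int(round(60.0 / params.integration_seconds))
    counts = integrated[: n_minutes * per_min].reshape(n_minutes, per_min).mean(axis=1)
    return EpochSeries(raw.start, 60, counts)


# ---------------------------------------------------------------------------
# Wear detection


@dataclass
class WearMask:
    """Per-minute worn flags plus per-day off-wrist budgets."""

    worn: np.ndarray  # bool per minute; False = off-wrist
    day_offwrist_minutes: dict[Date, int]
    day_valid: dict[Date, bool]


def _runs(mask: np.ndarray):
    """Yield (start, stop) half-open runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    for lo, hi in idx.reshape(-1, 2):
        yield int(lo), int(hi)


def flag_off_wrist_and_days(
    counts: EpochSeries,
    threshold: float = 0.0,
    min_run_minutes: int = 30,
    max_offwrist_minutes: int = 360,
    day_anchor: time = MIDNIGHT,
) -> WearMask:
    """Detect off-wrist minutes and discard over-budget days.

    Contiguous runs of counts <= ``threshold`` lasting at least
    ``min_run_minutes`` are off-wrist; any day whose off-wrist total
    exceeds ``max_offwrist_minutes`` (default 6 h) is marked invalid and
    excluded from every downstream indicator.
    """
    n = len(counts)
    worn = np.ones(n, dtype=bool)
    if n == 0:
        return WearMask(worn, {}, {})
    sub = counts.values <= threshold
    for lo, hi in _runs(sub):
        if hi - lo >= min_run_minutes:
            worn[lo:hi] = False

    day_off: dict[Date, int] = {}
    day_valid: dict[Date, bool] = {}
    for seg in segment_days(counts, day_anchor):
        off = int(np.count_nonzero(~worn[seg.start_idx : seg.stop_idx]))
        day_off[seg.date] = off
        day_valid[seg.date] = seg.valid and off <= max_offwrist_minutes
    return WearMask(worn, day_off, day_valid)


def apply_wear_mask(counts: EpochSeries, mask: WearMask) -> EpochSeries:
    """Counts with off-wrist minutes (and whole invalid days) masked out."""
    valid = counts.valid_mask & mask.worn
    for seg in segment_days(counts):
        if not mask.day_valid.get(seg.date, False):
            valid[seg.start_idx : seg.stop_idx] = False
    return EpochSeries(counts.start, counts.epoch_length, counts.values, valid)


# ---------------------------------------------------------------------------
# Cole-Kripke scoring


@dataclass
class ColeKripkeParams:
    """Cole-Kripke weighted-sum configuration (1-minute-epoch variant).

    D = scale * sum_k w_k * A_{t+k} over the window k = -4 ... +2
    (four preceding minutes, the current minute, two following); a
    minute is scored sleep when D < criterion.  Weights and scale are
    exposed so device-specific recalibrations can be expressed.
    """

    weights: tuple[float, ...] = (106, 54, 58, 76, 230, 74, 67)
    offsets: tuple[int, ...] = (-4, -3, -2, -1, 0, 1, 2)
    scale: float = 0.001
    criterion: float = 1.0


@dataclass
class MinuteSleepScores:
    start: datetime
    state: np.ndarray  # int8: SLEEP / WAKE / INVALID
    score: np.ndarray  # the weighted sum D

    def __len__(self) -> int:
        return len(self.state)

    def minute_time(self, index: int) -> datetime:
        return self.start + timedelta(minutes=index)

    def index_of(self, when: datetime) -> int:
        return int((when - self.start).total_seconds() // 60)


def cole_kripke_score(
    counts: EpochSeries,
    mask: Optional[WearMask] = None,
    params: ColeKripkeParams = ColeKripkeParams(),
) -> MinuteSleepScores:
    """Score each minute sleep/wake with the Cole-Kripke weighted sum.

    Boundary minutes use zero-padded neighbours; off-wrist minutes are
    reported INVALID and contribute zero activity to their neighbours'
    sums.
    """
    if counts.epoch_length != 60:
        raise ValueError("Cole-Kripke scoring expects 1-minute counts")
    vals = counts.values.copy()
    valid = counts.valid_mask.copy()
    if mask is not None:
        valid &= mask.worn
    vals[~valid] = 0.0

    n = len(vals)
    D = np.zeros(n)
    for w, k in zip(params.weights, params.offsets):
        shifted = np.zeros(n)
        if k < 0:
            shifted[-k:] = vals[:k] if k != 0 else vals
        elif k > 0:
            shifted[:-k] = vals[k:]
        else:
            shifted = vals
        D += w * shifted
    D *= params.scale

    state = np.where(D < params.criterion, SLEEP, WAKE).astype(np.int8)
    state[~valid] = INVALID
    return MinuteSleepScores(counts.start, state, D)


# ---------------------------------------------------------------------------
# Nightly episode extraction


@dataclass
class EpisodeRules:
    """Main-sleep-episode extraction rules.

    The night window (default 18:00 to 12:00 the next day) is scanned
    for sleep runs of at least ``min_sleep_run_minutes``; runs separated
    by wake gaps of at most ``max_gap_minutes`` consolidate into blocks;
    the longest block (ties: earlier onset) is the main episode and must
    reach ``min_episode_minutes``.
    """

    night_start: time = time(18, 0)
    night_end: time = time(12, 0)
    min_sleep_run_minutes: int = 20
    max_gap_minutes: int = 120
    min_episode_minutes: int = 60


def actigraphy_sleep_episode(
    scores: MinuteSleepScores,
    night_date: Date,
    rules: EpisodeRules = EpisodeRules(),
) -> Optional[SleepEpisode]:
    """Extract the main sleep episode for the night starting ``night_date``.

    onset = start of the block's first qualifying sleep run, wake = end
    of its last; WASO = wake-scored minutes between them; TST =
    (wake - onset) - WASO.  Returns None when no block reaches the
    minimum episode duration.
    """
    midnight = datetime.combine(night_date, MIDNIGHT)
    win_start = datetime.combine(night_date, rules.night_start)
    win_end = datetime.combine(
        night_date + timedelta(days=1), rules.night_end
    )
    lo = max(scores.index_of(win_start), 0)
    hi = min(scores.index_of(win_end), len(scores))
    if hi - lo < rules.min_episode_minutes:
        return None
    win = scores.state[lo:hi]

    runs = [
        (s, e)
        for s, e in _runs(win == SLEEP)
        if e - s >= rules.min_sleep_run_minutes
    ]
    if not runs:
        return None
    # consolidate runs separated by short gaps into blocks
    blocks: list[tuple[int, int]] = [runs[0]]
    for s, e in runs[1:]:
        if s - blocks[-1][1] <= rules.max_gap_minutes:
            blocks[-1] = (blocks[-1][0], e)
        else:
            blocks.append((s, e))
    blocks.sort(key=lambda b: (-(b[1] - b[0]), b[0]))
    b_lo, b_hi = blocks[0]
    if b_hi - b_lo < rules.min_episode_minutes:
        return None

    span = win[b_lo:b_hi]
    waso = float(np.count_nonzero(span == WAKE))
    onset_dt = scores.minute_time(lo + b_lo)
    wake_dt = scores.minute_time(lo + b_hi)
    onset = (onset_dt - midnight).total_seconds() / 3600.0
    wake = (wake_dt - midnight).total_seconds() / 3600.0
    return SleepEpisode(
        date=night_date,
        onset=onset,
        wake=wake,
        midpoint=(onset + wake) / 2.0,
        waso=waso,
        tst=(wake - onset) * 60.0 - waso,
        source="actigraphy",
    )


def actigraphy_sleep_episodes(
    counts: EpochSeries,
    wear: Optional[WearMask] = None,
    ck_params: ColeKripkeParams = ColeKripkeParams(),
    rules: EpisodeRules = EpisodeRules(),
) -> list[SleepEpisode]:
    """Full actigraphy pipeline: scoring then one episode per valid night.

    Nights whose evening or morning day failed the off-wrist budget are
    skipped.
    """
    if wear is None:
        wear = flag_off_wrist_and_days(counts)
    scores = cole_kripke_score(counts, wear, ck_params)
    episodes = []
    for seg in segment_days(counts):
        night = seg.date
        if not wear.day_valid.get(night, False):
            continue
        nxt = night + timedelta(days=1)
        if nxt in wear.day_valid and not wear.day_valid[nxt]:
            continue
        ep = actigraphy_sleep_episode(scores, night, rules)
        if ep is not None:
            episodes.append(ep)
    return episodes
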