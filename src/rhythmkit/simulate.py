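"""Synthetic paired smartphone + actigraphy recordings with ground truth.

The generator emulates the structure of a multi-week field recording:
a near-24-hour rest-activity cycle with day-to-day phase jitter, night
awakenings (WASO events) with phone-use bursts, dense daytime phone
interaction, and a weekend phase delay.  Both modalities share the same
nightly schedule, so every pipeline stage has a parameter-recovery test
against known truth.  It is a test harness, not a population model:
events are homogeneous Poisson within awake/asleep states and wrist
counts are Gamma-distributed around state levels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date as Date
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from .timeseries import MIDNIGHT, Event, EventLog, EpochSeries

__all__ = [
    "SimulationConfig",
    "NightTruth",
    "GroundTruth",
    "PairedRecording",
    "simulate_pair",
    "simulate_cohort",
]

MIN_PER_DAY = 1440
_EVENT_KIND_CYCLE = ("screen_on", "app_use", "screen_off")


@dataclass
class OffWristConfig:
    """Optional off-wrist gap injection (device removed, counts zero)."""

    events_per_day: float = 0.5
    duration_minutes: float = 60.0


@dataclass
class NapConfig:
    """Optional afternoon naps (asleep for both modalities)."""

    probability_per_day: float = 0.3
    start_hour: float = 14.0
    duration_minutes: float = 45.0


@dataclass
class SimulationConfig:
    """Ground-truth circadian architecture for one synthetic participant.

    Units: clock hours for timing, events/hour for usage rates,
    counts/minute for activity levels.  ``seed`` fixes all randomness.
    """

    n_days: int = 28
    start_date: Date = Date(2024, 1, 1)  # a Monday
    mean_onset: float = 23.5
    onset_jitter_sd: float = 0.5
    sleep_duration_mean: float = 7.5
    sleep_duration_sd: float = 0.5
    waso_events_per_night: float = 1.0
    waso_event_duration: float = 15.0
    day_usage_rate: float = 60.0
    night_usage_rate: float = 0.0
    weekend_phase_delay: float = 0.0
    activity_day_level: float = 150.0
    activity_night_level: float = 0.5
    offwrist: Optional[OffWristConfig] = None
    naps: Optional[NapConfig] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 7:
            raise ValueError("simulate at least 7 days")
        if not (0 < self.sleep_duration_mean < 16):
            raise ValueError("sleep_duration_mean must be in (0, 16) hours")
        for name in (
            "onset_jitter_sd",
            "waso_events_per_night",
            "day_usage_rate",
            "night_usage_rate",
            "activity_day_level",
            "activity_night_level",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class NightTruth:
    """True schedule of one night, decimal hours past its date's midnight."""

    date: Date
    onset: float
    wake: float
    waso: float  # minutes
    tst: float  # minutes


@dataclass
class GroundTruth:
    nights: list[NightTruth]

    @property
    def phases(self) -> np.ndarray:
        """Per-day true phase (sleep onset, decimal hours)."""
        return np.array([n.onset for n in self.nights])


@dataclass
class PairedRecording:
    events: EventLog
    acti_counts: EpochSeries
    truth: GroundTruth


def _merge_intervals(ivs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for lo, hi in sorted(ivs):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def simulate_pair(config: SimulationConfig) -> PairedRecording:
    """Generate one participant's paired recording.

    The emitted series span ``n_days + 1`` calendar days so that the
    last night's morning is complete; there are ``n_days`` nights, the
    night of day ``j`` starting around ``mean_onset`` on that date.
    Weekend delay applies to nights whose wake morning falls on Sat/Sun.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    total_days = config.n_days + 1
    total_min = total_days * MIN_PER_DAY
    origin = datetime.combine(config.start_date, MIDNIGHT)

    asleep = np.zeros(total_min, dtype=bool)  # per-minute truth
    waso_burst = np.zeros(total_min, dtype=bool)
    nights: list[NightTruth] = []

    for j in range(config.n_days):
        night_date = config.start_date + timedelta(days=j)
        onset_h = config.mean_onset + rng.normal(0.0, config.onset_jitter_sd)
        if (night_date + timedelta(days=1)).weekday() in (5, 6):
            onset_h += config.weekend_phase_delay
        duration = rng.normal(
            config.sleep_duration_mean, config.sleep_duration_sd
        )
        duration = float(np.clip(duration, 2.0, 15.9))
        if duration >= 24.0:
            raise ValueError("infeasible schedule: sleep duration >= 24 h")
        wake_h = onset_h + duration

        onset_min = j * MIN_PER_DAY + onset_h * 60.0
        wake_min = j * MIN_PER_DAY + wake_h * 60.0
        lo = int(round(onset_min))
        hi = min(int(round(wake_min)), total_min)
        asleep[lo:hi] = True

        # night awakenings: awake intervals inside the sleep period
        n_waso = rng.poisson(config.waso_events_per_night)
        ivs: list[tuple[float, float]] = []
        inner_lo, inner_hi = onset_min + 30.0, wake_min - 30.0
        for _ in range(n_waso):
            if inner_hi - inner_lo < config.waso_event_duration:
                break
            s = rng.uniform(inner_lo, inner_hi - config.waso_event_duration)
            ivs.append((s, s + config.waso_event_duration))
        waso_min = 0.0
        for s, e in _merge_intervals(ivs):
            a, b = int(round(s)), min(int(round(e)), total_min)
            asleep[a:b] = False
            waso_burst[a:b] = True
            waso_min += b - a
        nights.append(
            NightTruth(
                date=night_date,
                onset=onset_h,
                wake=wake_h,
                waso=waso_min,
                tst=(wake_h - onset_h) * 60.0 - waso_min,
            )
        )

    if config.naps is not None:
        for j in range(config.n_days):
            if rng.uniform() < config.naps.probability_per_day:
                s = j * MIN_PER_DAY + int(round(config.naps.start_hour * 60))
                asleep[s : s + int(round(config.naps.duration_minutes))] = True

    # --- smartphone events: Poisson per minute at the state's rate
    rate = np.where(
        asleep, config.night_usage_rate / 60.0, config.day_usage_rate / 60.0
    )
    rate[waso_burst] = config.day_usage_rate / 60.0
    n_events = rng.poisson(rate)
    records: list[Event] = []
    for minute in np.flatnonzero(n_events):
        base = origin + timedelta(minutes=int(minute))
        offsets = np.sort(rng.uniform(0.0, 60.0, int(n_events[minute])))
        for i, off in enumerate(offsets):
            kind = _EVENT_KIND_CYCLE[i % len(_EVENT_KIND_CYCLE)]
            records.append(
                Event(base + timedelta(seconds=float(off)), kind, "sim.app")
            )
    events = EventLog(records)

    # --- actigraphy counts: Gamma around the state level (shape 2)
    level = np.where(
        asleep, config.activity_night_level, config.activity_day_level
    )
    level[waso_burst] = config.activity_day_level
    counts = rng.gamma(shape=2.0, scale=level / 2.0)
    if config.offwrist is not None:
        n_off = rng.poisson(config.offwrist.events_per_day * total_days)
        for _ in range(n_off):
            s = int(rng.uniform(0, total_min))
            counts[s : s + int(round(config.offwrist.duration_minutes))] = 0.0
    acti = EpochSeries(origin, 60, counts)
    return PairedRecording(events, acti, GroundTruth(nights))


@dataclass
class CohortMember:
    participant_id: str
    group: str
    recording: PairedRecording


def simulate_cohort(
    group_configs: dict[str, SimulationConfig],
    n_per_group: int,
) -> list[CohortMember]:
    """Independent participants per group, seeds derived from each
    group's config seed.

    Returns one labelled member per participant; the label table is the
    (participant_id, group) pairing.
    """
    if len(group_configs) < 2:
        raise ValueError("need at least 2 groups")
    if n_per_group < 2:
        raise ValueError("need at least 2 participants per group")
    members: list[CohortMember] = []
    for g_idx, (group, cfg) in enumerate(sorted(group_configs.items())):
        ss = np.random.SeedSequence([cfg.seed, g_idx])
        child_seeds = ss.generate_state(n_per_group)
        for i in range(n_per_group):
            pcfg = replace(cfg, seed=int(child_seeds[i]) % (2**31 - 1))
            members.append(
                CohortMember(
                    participant_id=f"{group}-{i:03d}",
                    group=group,
                    recording=simulate_pair(pcfg),
                )
            )
    return members
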