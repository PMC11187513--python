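"""IS, IV, M10/L5, social jet lag, and participant aggregation."""

import math
from datetime import date, datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmkit import (
    EpochSeries,
    SleepEpisode,
    hourly_profile,
    interdaily_stability,
    intradaily_variability,
    m10_l5,
    segment_days,
    social_jetlag,
    summarize_participant,
)
from rhythmkit.metrics import is_from_profile

START = datetime(2024, 1, 1)


def _hourly(values):
    return EpochSeries(START, 3600, np.asarray(values, dtype=float))


class TestInterdailyStability:
    def test_identical_days_give_one(self):
        # two days of [1, 3] with p = 2 half-day bins
        s = EpochSeries(START, 43200, np.array([1.0, 3, 1, 3]))
        prof = hourly_profile(s, segment_days(s), bin_seconds=43200)
        assert is_from_profile(prof, s.values) == pytest.approx(1.0)

    def test_antiphase_days_give_zero(self):
        s = EpochSeries(START, 43200, np.array([1.0, 3, 3, 1]))
        prof = hourly_profile(s, segment_days(s), bin_seconds=43200)
        assert is_from_profile(prof, s.values) == pytest.approx(0.0)

    def test_day_periodic_series_gives_one(self, rng):
        day = rng.uniform(0, 10, 24)
        s = _hourly(np.tile(day, 5))
        assert interdaily_stability(s) == pytest.approx(1.0)

    def test_iid_noise_expectation_near_one_over_days(self, rng):
        d = 7
        vals = [
            interdaily_stability(_hourly(rng.uniform(0, 1, d * 24)))
            for _ in range(500)
        ]
        # E[IS] = (p-1)/(pd-1) ~= 1/d for iid data
        assert np.mean(vals) == pytest.approx((24 - 1) / (24 * d - 1), abs=0.02)

    def test_affine_invariance(self, rng):
        vals = rng.gamma(2.0, 3.0, 7 * 24)
        a = interdaily_stability(_hourly(vals))
        b = interdaily_stability(_hourly(2.5 * vals + 7.0))
        assert a == pytest.approx(b, rel=1e-9)

    def test_constant_series_errors(self):
        with pytest.raises(ValueError, match="constant"):
            interdaily_stability(_hourly(np.full(48, 3.0)))

    def test_needs_two_days(self, rng):
        with pytest.raises(ValueError, match="2 complete days"):
            interdaily_stability(_hourly(rng.uniform(0, 1, 24)))

    def test_five_minute_series_is_binned_hourly(self, rng):
        # IS computed from 5-min app-counts equals IS of their hourly sums
        vals = rng.poisson(2.0, 4 * 288).astype(float)
        s5 = EpochSeries(START, 300, vals)
        hourly_sums = vals.reshape(-1, 12).sum(axis=1)
        assert interdaily_stability(s5) == pytest.approx(
            interdaily_stability(_hourly(hourly_sums))
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounded_between_zero_and_one(self, seed):
        rng = np.random.default_rng(seed)
        days = rng.integers(2, 15)
        vals = rng.uniform(0, 100, days * 24)
        assert 0.0 <= interdaily_stability(_hourly(vals)) <= 1.0


class TestIntradailyVariability:
    def test_alternating_sequence_hand_value(self):
        # sum(diff^2) = 12, sum(dev^2) = 4, N = 4: IV = 4*12/(3*4) = 4
        assert intradaily_variability(_hourly([1, 3, 1, 3])) == pytest.approx(4.0)

    def test_sinusoid_closed_form(self):
        t = np.arange(7 * 24)
        vals = 10 + 5 * np.sin(2 * np.pi * t / 24)
        iv = intradaily_variability(_hourly(vals))
        expected = 2 * (1 - np.cos(2 * np.pi / 24))
        assert iv < 0.5
        assert iv == pytest.approx(expected, rel=0.05)

    def test_iid_noise_near_two(self, rng):
        vals = [
            intradaily_variability(_hourly(rng.uniform(0, 1, 7 * 24)))
            for _ in range(500)
        ]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)

    def test_monotone_ramp_below_noise_value(self):
        iv = intradaily_variability(_hourly(np.linspace(0, 100, 7 * 24)))
        assert iv < 0.1

    def test_affine_invariance(self, rng):
        vals = rng.gamma(2.0, 3.0, 3 * 24)
        a = intradaily_variability(_hourly(vals))
        b = intradaily_variability(_hourly(0.5 * vals + 3.0))
        assert a == pytest.approx(b, rel=1e-9)

    def test_gap_skipping(self):
        # the invalid epoch (value 100) contributes to no difference pair
        vals = np.array([1.0, 3, 100, 1, 3, 1, 3, 1])
        mask = np.ones(8, bool)
        mask[2] = False
        s = EpochSeries(START, 3600, vals, mask)
        iv = intradaily_variability(s, hourly_bin=False)
        pts = vals[mask]  # N = 7, mean 13/7
        sst = float(np.sum((pts - pts.mean()) ** 2))
        # remaining index-adjacent pairs: (0,1), (3,4), (4,5), (5,6), (6,7)
        ssd = (3 - 1) ** 2 * 5
        assert iv == pytest.approx(pts.size * ssd / (5 * sst))

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            intradaily_variability(_hourly(np.full(48, 2.0)))


class TestM10L5:
    def test_block_activity_day(self):
        day = np.zeros(288)
        day[8 * 12 : 18 * 12] = 100.0  # active 08:00-18:00
        s = EpochSeries(START, 300, np.tile(day, 2))
        res = m10_l5(s)
        assert res.m10.mean == pytest.approx(100.0)
        assert res.m10.onset_hours == pytest.approx(8.0)
        assert res.l5.mean == pytest.approx(0.0)

    def test_constant_series(self):
        s = EpochSeries(START, 300, np.full(288, 7.0))
        res = m10_l5(s)
        assert res.m10.mean == pytest.approx(7.0)
        assert res.l5.mean == pytest.approx(7.0)

    def test_l5_never_exceeds_m10(self, rng):
        s = EpochSeries(START, 300, rng.gamma(1.0, 5.0, 3 * 288))
        res = m10_l5(s)
        assert res.l5.mean <= res.m10.mean

    def test_matches_exhaustive_window_enumeration(self, rng):
        vals = rng.gamma(1.0, 5.0, 288)
        s = EpochSeries(START, 300, vals)
        res = m10_l5(s)
        ext = np.concatenate([vals, vals])
        w10 = np.array([ext[i : i + 120].mean() for i in range(288)])
        w5 = np.array([ext[i : i + 60].mean() for i in range(288)])
        assert res.m10.mean == pytest.approx(w10.max())
        assert res.l5.mean == pytest.approx(w5.min())
        assert res.m10.onset_hours == pytest.approx(np.argmax(w10) * 300 / 3600)
        assert res.l5.onset_hours == pytest.approx(np.argmin(w5) * 300 / 3600)

    def test_day_with_contaminated_windows_skipped(self):
        vals = np.ones(2 * 288)
        mask = np.ones(2 * 288, bool)
        mask[:288] = False  # every window of day 1 touches a gap
        s = EpochSeries(START, 300, vals, mask)
        res = m10_l5(s)
        assert res.n_days == 1


def _episode(night, midpoint):
    return SleepEpisode(
        date=night, onset=midpoint - 4, wake=midpoint + 4,
        midpoint=midpoint, waso=0.0, tst=480.0, source="app",
    )


class TestSocialJetlag:
    def _episodes(self, work_mid, free_mid, weeks=2):
        eps = []
        for i in range(weeks * 7):
            night = date(2024, 1, 1) + timedelta(days=i)  # Monday start
            morning = night + timedelta(days=1)
            mid = free_mid if morning.weekday() >= 5 else work_mid
            eps.append(_episode(night, mid))
        return eps

    def test_two_hour_delay(self):
        assert social_jetlag(self._episodes(27.0, 29.0)) == pytest.approx(2.0)

    def test_identical_distributions_give_zero(self):
        assert social_jetlag(self._episodes(27.0, 27.0)) == pytest.approx(0.0)

    def test_missing_class_unavailable(self):
        eps = [
            _episode(date(2024, 1, 1) + timedelta(days=i), 27.0)
            for i in range(4)  # Mon-Thu nights only
        ]
        assert social_jetlag(eps) is None


class TestSummarize:
    def test_28_day_row(self, rng):
        day = np.r_[np.zeros(7 * 12), rng.poisson(5.0, 17 * 12)]
        vals = np.concatenate([np.roll(day, rng.integers(-6, 6)) for _ in range(28)])
        s = EpochSeries(START, 300, vals.astype(float))
        eps = [
            _episode(date(2024, 1, 1) + timedelta(days=i), 27.0 + 0.1 * (i % 3))
            for i in range(28)
        ]
        row = summarize_participant("P1", "app", eps, s)
        assert row.n_days == 28
        assert 0 <= row.IS <= 1
        assert row.IV >= 0
        assert row.L5 <= row.M10
        assert row.mean_midpoint == pytest.approx(np.mean([e.midpoint for e in eps]))

    def test_empty_episode_list_still_emits_row(self, rng):
        s = EpochSeries(START, 300, rng.poisson(3.0, 7 * 288).astype(float))
        row = summarize_participant("P2", "actigraphy", [], s)
        assert row.participant_id == "P2"
        assert math.isnan(row.mean_onset)
        assert row.n_days == 7

    def test_short_recording_warns(self, rng):
        s = EpochSeries(START, 300, rng.poisson(3.0, 3 * 288).astype(float))
        with pytest.warns(UserWarning, match="low-confidence"):
            summarize_participant("P3", "app", [], s)
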