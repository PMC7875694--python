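"""The 15-slot feature vector: occupancy, rate, duration moments, entropy,
windowing."""

import math

import numpy as np
import pandas as pd
import pytest

from mpulse.features import (
    FEATURE_NAMES,
    Window,
    daily_windows,
    duration_moments,
    extract_features,
    freq_per_hour,
    hours_to_minutes,
    occurrence_entropy,
    use_per_hour,
)
from mpulse.ingest import filter_battery

from conftest import make_stream, ts


def window(start, end):
    return Window(ts(start), ts(end))


W_DAY = window("2024-01-01T00:00:00", "2024-01-02T00:00:00")


def random_stream(rng, n=200, sensor="screen", day_span=2):
    starts = [
        ts("2024-01-01") + pd.Timedelta(seconds=float(s))
        for s in np.sort(rng.uniform(0, day_span * 86400, n))
    ]
    durations = rng.uniform(1, 3600, n)
    return make_stream(sensor, starts, durations,
                       span=(ts("2024-01-01"), ts("2024-01-01") + pd.Timedelta(days=day_span)))


class TestUseAndFreq:
    def test_six_minute_unlock_in_one_hour_is_0_1(self):
        s = make_stream("screen", ["2024-01-01T00:10:00"], [360])
        assert use_per_hour(s, window("2024-01-01T00:00:00", "2024-01-01T01:00:00")) == pytest.approx(0.1)

    def test_no_events_zero(self):
        s = make_stream("screen", [], [])
        assert use_per_hour(s, W_DAY) == 0.0
        assert freq_per_hour(s, W_DAY) == 0.0

    def test_48_unlocks_over_24h_freq_2(self):
        starts = [ts("2024-01-01") + pd.Timedelta(minutes=30 * i) for i in range(48)]
        s = make_stream("screen", starts, [10] * 48)
        assert freq_per_hour(s, W_DAY) == pytest.approx(2.0)

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError):
            window("2024-01-01T00:00:00", "2024-01-01T00:00:00")

    def test_use_against_minute_grid_occupancy_oracle(self, rng):
        s = random_stream(rng)
        w = window("2024-01-01T06:00:00", "2024-01-02T06:00:00")
        # brute force: count occupied minutes on a 1-minute grid
        grid = pd.date_range(w.start, w.end, freq="1min", inclusive="left")
        occupied = np.zeros(len(grid))
        for e in s.events:
            mask = (grid >= e.start.floor("1min") - pd.Timedelta(minutes=1)) & (grid < e.end)
            inside = [
                min(e.end, g + pd.Timedelta(minutes=1)) - max(e.start, g)
                for g in grid[mask]
            ]
            occupied[np.flatnonzero(mask)] += [
                max(d.total_seconds(), 0.0) / 60.0 for d in inside
            ]
        oracle = occupied.sum() / 60.0 / w.hours
        assert use_per_hour(s, w) == pytest.approx(oracle, abs=1 / 60)

    def test_edge_straddling_event_clipped_for_use_only(self):
        # event starts before the window, runs 30 min into it
        s = make_stream("screen", ["2024-01-01T23:45:00"], [2700])
        w = window("2024-01-02T00:00:00", "2024-01-03T00:00:00")
        assert use_per_hour(s, w) == pytest.approx(0.5 / 24)
        assert freq_per_hour(s, w) == 0.0  # start outside → not counted

    def test_additivity_over_partition(self, rng):
        s = random_stream(rng)
        w = window("2024-01-01T00:00:00", "2024-01-02T00:00:00")
        parts = [
            window("2024-01-01T00:00:00", "2024-01-01T09:00:00"),
            window("2024-01-01T09:00:00", "2024-01-01T17:00:00"),
            window("2024-01-01T17:00:00", "2024-01-02T00:00:00"),
        ]
        freq_total = sum(freq_per_hour(s, p) * p.hours for p in parts) / w.hours
        use_total = sum(use_per_hour(s, p) * p.hours for p in parts) / w.hours
        assert freq_total == pytest.approx(freq_per_hour(s, w))
        assert use_total == pytest.approx(use_per_hour(s, w))


class TestDurationMoments:
    def test_single_event(self):
        s = make_stream("screen", ["2024-01-01T01:00:00"], [360])
        assert duration_moments(s, W_DAY) == (pytest.approx(0.1), 0.0)

    def test_mean_unit_conversion_helper(self):
        assert hours_to_minutes(0.1) == pytest.approx(6.0)

    def test_no_events_missing(self):
        s = make_stream("screen", [], [])
        mean, sd = duration_moments(s, W_DAY)
        assert math.isnan(mean) and math.isnan(sd)

    def test_against_two_pass_formula(self, rng):
        durations = rng.uniform(1, 5000, 40)
        starts = [ts("2024-01-01") + pd.Timedelta(minutes=20 * i) for i in range(40)]
        s = make_stream("screen", starts, durations)
        mean, sd = duration_moments(s, W_DAY)
        d = durations / 3600.0
        mu = d.sum() / len(d)
        sd_ref = math.sqrt(((d - mu) ** 2).sum() / (len(d) - 1))
        assert mean == pytest.approx(mu, abs=1e-12)
        assert sd == pytest.approx(sd_ref, abs=1e-12)


class TestOccurrenceEntropy:
    def test_concentrated_in_one_hour_is_zero(self):
        starts = [ts("2024-01-01T09:00:00") + pd.Timedelta(minutes=i) for i in range(30)]
        s = make_stream("screen", starts, [10] * 30)
        assert occurrence_entropy(s, W_DAY) == pytest.approx(0.0)

    def test_uniform_over_24_bins_is_ln24(self):
        starts = [ts("2024-01-01") + pd.Timedelta(hours=h, minutes=m)
                  for h in range(24) for m in (5, 35)]
        s = make_stream("screen", starts, [10] * 48)
        assert occurrence_entropy(s, W_DAY) == pytest.approx(math.log(24))

    def test_no_events_missing(self):
        s = make_stream("screen", [], [])
        assert math.isnan(occurrence_entropy(s, W_DAY))

    def test_base_option(self):
        starts = [ts("2024-01-01") + pd.Timedelta(hours=h) for h in range(24)]
        s = make_stream("screen", starts, [10] * 24)
        assert occurrence_entropy(s, W_DAY, base=2) == pytest.approx(math.log2(24))

    def test_multinomial_plugin_oracle(self, rng):
        p = rng.dirichlet(np.full(24, 2.0))
        hours = rng.choice(24, size=1000, p=p)
        starts = sorted(
            ts("2024-01-01") + pd.Timedelta(hours=int(h), minutes=int(m))
            for h, m in zip(hours, rng.integers(0, 60, 1000))
        )
        s = make_stream("screen", starts, [10] * 1000)
        truth = -(p * np.log(p)).sum()
        assert occurrence_entropy(s, W_DAY) == pytest.approx(truth, abs=0.05)

    def test_invariant_to_durations_and_order(self, rng):
        s = random_stream(rng, n=100, day_span=1)
        h0 = occurrence_entropy(s, W_DAY)
        shuffled = list(s.events)
        rng.shuffle(shuffled)
        s2 = make_stream("screen",
                         [e.start for e in shuffled],
                         rng.uniform(1, 9999, 100))
        assert occurrence_entropy(s2, W_DAY) == pytest.approx(h0)


class TestScalingInvariance:
    def test_duration_scaling_moves_only_duration_features(self, rng):
        s = random_stream(rng, n=80, day_span=1)
        c = 2.5
        s_scaled = make_stream("screen", [e.start for e in s.events],
                               [e.duration * c for e in s.events])
        w = window("2024-01-01T00:00:00", "2024-01-02T12:00:00")
        assert use_per_hour(s_scaled, w) == pytest.approx(c * use_per_hour(s, w), rel=0.05)
        m0, sd0 = duration_moments(s, w)
        m1, sd1 = duration_moments(s_scaled, w)
        assert m1 == pytest.approx(c * m0) and sd1 == pytest.approx(c * sd0)
        assert freq_per_hour(s_scaled, w) == freq_per_hour(s, w)
        assert occurrence_entropy(s_scaled, w) == pytest.approx(occurrence_entropy(s, w))


class TestExtractFeatures:
    def test_matches_slotwise_recomputation(self, bundle):
        pid = next(iter(bundle.streams))
        clean = bundle.clean_streams()[pid]
        w = window("2024-01-03T08:00:00", "2024-01-04T08:00:00")
        vec = extract_features(clean, w)
        assert list(vec.index) == list(FEATURE_NAMES)
        for sensor in ("battery", "call", "screen"):
            s = clean[sensor]
            assert vec[f"{sensor}_Use"] == pytest.approx(use_per_hour(s, w))
            assert vec[f"{sensor}_Freq"] == pytest.approx(freq_per_hour(s, w))
            mean, sd = duration_moments(s, w)
            for got, ref in ((vec[f"{sensor}_Mean"], mean), (vec[f"{sensor}_SD"], sd)):
                assert (math.isnan(got) and math.isnan(ref)) or got == pytest.approx(ref)
            ent = occurrence_entropy(s, w)
            got = vec[f"{sensor}_Ent"]
            assert (math.isnan(got) and math.isnan(ent)) or got == pytest.approx(ent)

    def test_empty_window_zero_or_missing(self):
        streams = {k: make_stream(k, [], []) for k in ("battery", "call", "screen")}
        vec = extract_features(streams, W_DAY)
        for sensor in ("battery", "call", "screen"):
            assert vec[f"{sensor}_Use"] == 0.0
            assert vec[f"{sensor}_Freq"] == 0.0
            assert math.isnan(vec[f"{sensor}_Mean"])
            assert math.isnan(vec[f"{sensor}_Ent"])

    def test_missing_sensor_warns_and_leaves_nan(self):
        streams = {"screen": make_stream("screen", ["2024-01-01T01:00:00"], [60])}
        with pytest.warns(UserWarning, match="battery"):
            vec = extract_features(streams, W_DAY)
        assert math.isnan(vec["battery_Use"])
        assert vec["screen_Freq"] > 0

    def test_battery_filter_conservation(self, bundle):
        """Pre- vs post-filter use differs exactly by the removed events'
        duration contribution."""
        pid = next(iter(bundle.streams))
        raw = bundle.streams[pid]["battery"]
        clean, _ = filter_battery(raw)
        w = Window(*raw.observation_span)
        removed_h = sum(e.duration for e in raw.events if e.duration < 10) / 3600.0
        gap = use_per_hour(raw, w) - use_per_hour(clean, w)
        assert gap == pytest.approx(removed_h / w.hours, abs=1e-9)


class TestDailyWindows:
    def test_24h_window_before_assessment(self):
        wins = daily_windows([ts("2024-01-05T08:00:00")])
        assert wins[0].start == ts("2024-01-04T08:00:00")
        assert wins[0].end == ts("2024-01-05T08:00:00")

    def test_adjacent_non_overlapping_for_regular_mornings(self):
        wins = daily_windows([ts("2024-01-05T08:00:00"), ts("2024-01-06T08:00:00")])
        assert wins[0].end == wins[1].start

    def test_irregular_mornings_may_overlap(self):
        t1, t2 = ts("2024-01-05T07:30:00"), ts("2024-01-06T09:10:00")
        wins = daily_windows([t1, t2])
        # interval arithmetic: overlap iff gap between assessments < 24 h
        overlap = (t2 - t1) < pd.Timedelta(hours=24)
        assert (wins[1].start < wins[0].end) == overlap
        t3 = ts("2024-01-05T09:10:00")
        wins2 = daily_windows([t1, t3])
        assert wins2[1].start < wins2[0].end

    def test_duplicate_assessments_rejected(self):
        t = ts("2024-01-05T08:00:00")
        with pytest.raises(ValueError, match="duplicate"):
            daily_windows([t, t])
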