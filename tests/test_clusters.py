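"""Daily binning, cluster detection by the 3-day/5-seizure rule, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srscluster import (
    DailyCountSeries,
    SeizureEvent,
    bin_daily,
    classify_fully_monitored,
    compute_metrics,
    detect_clusters,
    extract_raster,
)


def _series(counts, start_day=0, animal="a"):
    return DailyCountSeries(animal_id=animal, start_day=start_day,
                            counts=tuple(counts))


def _events(hours, animal="a", stages=None):
    stages = stages or [None] * len(hours)
    return [SeizureEvent(animal, h, stage=s) for h, s in zip(hours, stages)]


class TestBinDaily:
    def test_consecutive_day_bins(self):
        s = bin_daily(_events([1.0, 25.0, 49.0]), window=(0, 2))
        assert list(s.counts) == [1, 1, 1]

    def test_stage_filter_keeps_convulsive(self):
        evs = _events([1.0, 2.0, 3.0], stages=[3, 4, 5])
        s = bin_daily(evs, window=(0, 0), stage_filter=4)
        assert s.total == 2

    def test_unstaged_events_are_retained_under_filter(self):
        evs = _events([1.0, 2.0], stages=[None, 3])
        s = bin_daily(evs, window=(0, 0), stage_filter=4)
        assert s.total == 1

    def test_empty_events_gives_zero_series(self):
        s = bin_daily([], window=(5, 9))
        assert list(s.counts) == [0] * 5 and s.start_day == 5

    def test_event_outside_window_is_an_error(self):
        with pytest.raises(ValueError, match="outside window"):
            bin_daily(_events([120.0]), window=(0, 2))

    def test_negative_time_is_an_error(self):
        with pytest.raises(ValueError, match="negative"):
            SeizureEvent("a", -1.0)


class TestDetectClusters:
    def test_basic_cluster(self):
        (c,) = detect_clusters(_series([0, 2, 3, 1, 0]))
        assert (c.onset_day, c.end_day) == (1, 3)
        assert c.duration == 3 and c.total_seizures == 6 and c.peak_frequency == 3

    def test_three_days_but_under_five_seizures(self):
        assert detect_clusters(_series([0, 1, 1, 1, 0])) == []

    def test_maximal_runs_hand_enumeration(self):
        series = _series([2, 0, 3, 2, 1, 0, 4])
        clusters = detect_clusters(series)
        assert len(clusters) == 1
        (c,) = clusters
        assert (c.onset_day, c.end_day, c.total_seizures) == (2, 4, 6)
        m = compute_metrics(series, clusters)
        assert m.outside_seizure_count == 6

    def test_monotone_in_seizure_threshold(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 5, size=20)
            s = _series(counts)
            sizes = [len(detect_clusters(s, min_total=t)) for t in range(5, 12)]
            assert sizes == sorted(sizes, reverse=True)


class TestFullyMonitored:
    def test_cluster_at_series_start_is_not_fm(self):
        s = _series([2, 2, 1, 0, 0])
        (c,) = detect_clusters(s)
        assert classify_fully_monitored(c, s) is False

    def test_zero_flanked_cluster_is_fm(self):
        s = _series([0, 2, 2, 1, 0])
        (c,) = detect_clusters(s)
        assert classify_fully_monitored(c, s) is True

    def test_cluster_at_series_end_is_not_fm(self):
        s = _series([0, 0, 2, 2, 1])
        (c,) = detect_clusters(s)
        assert classify_fully_monitored(c, s) is False


class TestMetrics:
    def test_onset_to_onset_interval(self):
        counts = [0] * 40
        counts[10:13] = [2, 2, 2]
        counts[33:36] = [1, 3, 1]
        s = _series(counts)
        m = compute_metrics(s, detect_clusters(s))
        assert m.cluster_intervals == [23]

    def test_seizure_free_period_clean_gap(self):
        counts = [0] * 35
        counts[12:15] = [2, 2, 1]  # ends day 14
        counts[31:34] = [1, 3, 1]  # next onset day 31
        s = _series(counts)
        m = compute_metrics(s, detect_clusters(s))
        assert m.seizure_free_periods == [16]
        assert m.gaps[0].interval == 31 - 12
        # interval - earlier duration = seizure-free days for a clean gap
        assert m.gaps[0].interval - m.clusters[0].duration == 16

    def test_interrupted_gap_reports_longest_zero_run(self):
        counts = [0] * 30
        counts[2:5] = [2, 2, 1]
        counts[9] = 1  # stray seizure inside the gap
        counts[20:23] = [1, 3, 1]
        s = _series(counts)
        m = compute_metrics(s, detect_clusters(s))
        (gap,) = m.gaps
        assert gap.interrupted
        assert gap.seizure_free_days == 10  # days 10..19
        assert m.seizure_free_periods == []

    def test_rise_fall_identity(self):
        s = _series([0] + [1, 3, 7, 17, 5, 2] + [0])
        (c,) = detect_clusters(s)
        assert c.peak_frequency == 17
        assert c.rise_days == 3 and c.fall_days == 2
        assert c.rise_days + c.fall_days == c.duration - 1

    def test_interval_needs_observed_onset(self):
        counts = [1, 2, 2] + [0] * 17 + [1, 3, 1] + [0]
        s = _series(counts)
        m = compute_metrics(s, detect_clusters(s))
        # first cluster starts on the first monitored day: onset unobserved
        assert m.cluster_intervals == []
        assert len(m.gaps) == 1 and m.gaps[0].interval is None

    def test_no_seizures_fraction_is_missing(self):
        s = _series([0, 0, 0])
        m = compute_metrics(s, [])
        assert m.within_cluster_fraction is None
        assert m.outside_seizure_count == 0


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.lists(st.integers(0, 6), min_size=1, max_size=30))
def test_count_conservation(counts):
    s = _series(counts)
    m = compute_metrics(s, detect_clusters(s))
    assert m.outside_seizure_count + sum(
        c.total_seizures for c in m.clusters
    ) == s.total


class TestRaster:
    def test_projection(self):
        evs = _events([26.0, 26.5, 45.0])  # day 1 at hours 2.0, 2.5, 21.0
        assert extract_raster(evs, day=1) == [2.0, 2.5, 21.0]

    def test_empty_day(self):
        assert extract_raster(_events([26.0]), day=3) == []

    def test_matches_daily_bin_on_cohort(self, small_cohort):
        from srscluster.clusters import events_from_frame

        _, events, windows, _ = small_cohort
        aid = windows.animal_id.iloc[0]
        evs = events_from_frame(events[events.animal_id == aid])
        w = windows[windows.animal_id == aid].iloc[0]
        series = bin_daily(evs, (w.start_day, w.end_day))
        peak_day = series.start_day + int(np.argmax(series.counts))
        assert len(extract_raster(evs, peak_day)) == max(series.counts)
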