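"""Seizure-cluster detection and cluster metrics from daily seizure counts.

The operational definitions implemented here follow the standard rule used
for the chronic pilocarpine mouse model: a *seizure cluster* is one or more
seizures per day on at least three consecutive days with at least five
seizures in total over those days.  A cluster is *fully monitored* (FM) when
both its onset and its end fall strictly inside the monitoring window, i.e.
a monitored zero-seizure day flanks it on each side.  Derived per-cluster
metrics are the cluster duration (days, inclusive), the peak seizure
frequency (maximum daily count), and the rise/fall times from onset to the
peak day and from the peak day to the end.  Series-level metrics are the
onset-to-onset cluster interval, the inter-cluster seizure-free period, and
the percentage of all seizures that fall inside clusters.

All day indices are integer days since status epilepticus (SE, day 0); event
times are hours since SE, so day ``d`` covers hours ``[24 d, 24 (d+1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SeizureEvent",
    "DailyCountSeries",
    "Cluster",
    "GapMetric",
    "ClusterSeriesMetrics",
    "bin_daily",
    "detect_clusters",
    "classify_fully_monitored",
    "compute_metrics",
    "extract_raster",
]

HOURS_PER_DAY = 24.0

#: minimum consecutive days with >=1 seizure for a run to count as a cluster
MIN_CLUSTER_DAYS = 3
#: minimum total seizures within the run
MIN_CLUSTER_SEIZURES = 5


@dataclass(frozen=True)
class SeizureEvent:
    """One detected convulsive seizure.

    ``t_hours_since_SE`` is the event time in hours with SE at 0.  ``stage``
    is the optional Racine stage (0-5); stage >= 4 marks a generalized
    convulsive seizure.  ``onset_s``/``offset_s`` are set when the event was
    derived from an EEG trace.
    """

    animal_id: str
    t_hours_since_SE: float
    stage: Optional[int] = None
    onset_s: Optional[float] = None
    offset_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t_hours_since_SE < 0:
            raise ValueError(
                f"event for {self.animal_id!r} has negative time "
                f"{self.t_hours_since_SE}"
            )
        if self.stage is not None and not 0 <= self.stage <= 5:
            raise ValueError(f"Racine stage must be in 0..5, got {self.stage}")


@dataclass(frozen=True)
class DailyCountSeries:
    """Per-animal seizure counts on consecutive monitored days."""

    animal_id: str
    start_day: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise ValueError("empty daily-count series")
        if any(c < 0 for c in self.counts):
            raise ValueError("daily counts must be non-negative")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def end_day(self) -> int:
        return self.start_day + len(self.counts) - 1

    @property
    def n_days(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def count_on(self, day: int) -> int:
        if not self.start_day <= day <= self.end_day:
            raise IndexError(f"day {day} outside monitored window")
        return self.counts[day - self.start_day]


@dataclass
class Cluster:
    """A detected seizure cluster and its derived metrics."""

    onset_day: int
    end_day: int
    per_day_counts: tuple[int, ...]
    fully_monitored: Optional[bool] = None

    def __post_init__(self) -> None:
        self.per_day_counts = tuple(int(c) for c in self.per_day_counts)
        if self.end_day - self.onset_day + 1 != len(self.per_day_counts):
            raise ValueError("per_day_counts length does not match day span")
        if self.duration < MIN_CLUSTER_DAYS:
            raise ValueError(f"cluster duration {self.duration} < {MIN_CLUSTER_DAYS}")
        if any(c < 1 for c in self.per_day_counts):
            raise ValueError("every cluster day must have >= 1 seizure")
        if self.total_seizures < MIN_CLUSTER_SEIZURES:
            raise ValueError(
                f"cluster total {self.total_seizures} < {MIN_CLUSTER_SEIZURES}"
            )

    @property
    def duration(self) -> int:
        """Cluster duration in days, onset to end inclusive."""
        return self.end_day - self.onset_day + 1

    @property
    def total_seizures(self) -> int:
        return int(sum(self.per_day_counts))

    @property
    def peak_frequency(self) -> int:
        """Maximum seizures/day within the cluster."""
        return int(max(self.per_day_counts))

    @property
    def peak_day(self) -> int:
        """Earliest day attaining the maximum daily count."""
        i = int(np.argmax(self.per_day_counts))
        return self.onset_day + i

    @property
    def rise_days(self) -> int:
        """Days from cluster onset to the peak day."""
        return self.peak_day - self.onset_day

    @property
    def fall_days(self) -> int:
        """Days from the peak day to the cluster end."""
        return self.end_day - self.peak_day

    @property
    def mean_frequency(self) -> float:
        """Within-cluster mean seizures/day."""
        return self.total_seizures / self.duration


@dataclass(frozen=True)
class GapMetric:
    """Metrics for the gap between one cluster and the next.

    ``interval`` is the onset-to-onset distance in days, reported only when
    the earlier cluster's onset was observed (not truncated by the window).
    ``seizure_free_days`` counts zero-seizure days strictly between the two
    clusters when the whole gap is seizure-free; otherwise it is the longest
    zero-run in the gap and ``interrupted`` is set.
    """

    interval: Optional[int]
    seizure_free_days: int
    interrupted: bool


@dataclass
class ClusterSeriesMetrics:
    clusters: list[Cluster]
    outside_seizure_count: int
    within_cluster_fraction: Optional[float]  # percent, None if no seizures
    gaps: list[GapMetric] = field(default_factory=list)

    @property
    def cluster_intervals(self) -> list[int]:
        return [g.interval for g in self.gaps if g.interval is not None]

    @property
    def seizure_free_periods(self) -> list[int]:
        """Seizure-free days of the uninterrupted gaps."""
        return [g.seizure_free_days for g in self.gaps if not g.interrupted]


def bin_daily(
    events: Sequence[SeizureEvent],
    window: tuple[int, int],
    stage_filter: Optional[int] = None,
) -> DailyCountSeries:
    """Bin seizure events into daily counts over a monitoring window.

    ``window`` is ``(start_day, end_day)`` inclusive, in integer days since
    SE; day bins are the consecutive 24-h intervals aligned to the window
    start.  Events carrying a Racine stage below ``stage_filter`` are
    excluded (events without a stage are retained).
    """
    start_day, end_day = int(window[0]), int(window[1])
    if start_day > end_day:
        raise ValueError(f"window start {start_day} > end {end_day}")
    counts = np.zeros(end_day - start_day + 1, dtype=int)
    animal_id = events[0].animal_id if events else ""
    for ev in events:
        if ev.t_hours_since_SE < 0:
            raise ValueError(f"negative event time {ev.t_hours_since_SE}")
        day = int(np.floor(ev.t_hours_since_SE / HOURS_PER_DAY))
        if not start_day <= day <= end_day:
            raise ValueError(
                f"event at t={ev.t_hours_since_SE} h (day {day}) for "
                f"{ev.animal_id!r} lies outside window [{start_day}, {end_day}]"
            )
        if stage_filter is not None and ev.stage is not None and ev.stage < stage_filter:
            continue
        counts[day - start_day] += 1
    return DailyCountSeries(animal_id=animal_id, start_day=start_day, counts=tuple(counts))


def detect_clusters(
    series: DailyCountSeries,
    min_days: int = MIN_CLUSTER_DAYS,
    min_total: int = MIN_CLUSTER_SEIZURES,
) -> list[Cluster]:
    """Detect seizure clusters in a daily-count series.

    Candidate runs are maximal runs of consecutive days with >= 1 seizure;
    a run is a cluster iff it spans at least ``min_days`` days and contains
    at least ``min_total`` seizures.  Returned clusters are sorted and
    disjoint.  The defaults are the operational rule (3 days, 5 seizures);
    they are parameters so threshold-sensitivity can be examined.
    """
    clusters: list[Cluster] = []
    counts = series.counts
    i = 0
    n = len(counts)
    while i < n:
        if counts[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and counts[j + 1] > 0:
            j += 1
        run = counts[i : j + 1]
        if (j - i + 1) >= min_days and sum(run) >= min_total:
            clusters.append(
                Cluster(
                    onset_day=series.start_day + i,
                    end_day=series.start_day + j,
                    per_day_counts=tuple(run),
                )
            )
        i = j + 1
    return clusters


def classify_fully_monitored(cluster: Cluster, series: DailyCountSeries) -> bool:
    """Whether both onset and end of the cluster were observed.

    True iff the day immediately before the onset and the day immediately
    after the end are both monitored and seizure-free.  A cluster abutting
    either edge of the monitoring window cannot be classified as fully
    monitored, because its true onset/end may lie outside the window.
    """
    before = cluster.onset_day - 1
    after = cluster.end_day + 1
    if before < series.start_day or after > series.end_day:
        return False
    return series.count_on(before) == 0 and series.count_on(after) == 0


def compute_metrics(
    series: DailyCountSeries, clusters: Sequence[Cluster]
) -> ClusterSeriesMetrics:
    """Compute series-level cluster metrics.

    ``clusters`` must come from :func:`detect_clusters` on the same series.
    Sets each cluster's ``fully_monitored`` flag as a side effect.  The
    onset-to-onset interval for a consecutive pair is reported only when the
    earlier cluster's onset is observed (the cluster does not start on the
    first monitored day).  The seizure-free period of a pair is the number
    of zero-seizure days strictly between them if the whole gap is free of
    seizures, otherwise the longest zero-run in the gap, flagged as
    interrupted.  The within-cluster percentage is undefined (None) for a
    series with no seizures.
    """
    clusters = list(clusters)
    total = series.total
    in_cluster = sum(c.total_seizures for c in clusters)
    outside = total - in_cluster
    if outside < 0:
        raise ValueError("clusters contain more seizures than the series")
    frac = 100.0 * in_cluster / total if total > 0 else None

    for c in clusters:
        c.fully_monitored = classify_fully_monitored(c, series)

    gaps: list[GapMetric] = []
    for a, b in zip(clusters, clusters[1:]):
        interval: Optional[int] = None
        if a.onset_day > series.start_day:
            interval = b.onset_day - a.onset_day
        gap_counts = [
            series.count_on(d) for d in range(a.end_day + 1, b.onset_day)
        ]
        if all(c == 0 for c in gap_counts):
            gaps.append(GapMetric(interval, len(gap_counts), interrupted=False))
        else:
            gaps.append(
                GapMetric(interval, _longest_zero_run(gap_counts), interrupted=True)
            )

    return ClusterSeriesMetrics(
        clusters=clusters,
        outside_seizure_count=outside,
        within_cluster_fraction=frac,
        gaps=gaps,
    )


def _longest_zero_run(counts: Sequence[int]) -> int:
    best = cur = 0
    for c in counts:
        cur = cur + 1 if c == 0 else 0
        best = max(best, cur)
    return best


def extract_raster(
    events: Sequence[SeizureEvent], day: int, stage_filter: Optional[int] = None
) -> list[float]:
    """Within-day offsets (hours, sorted) of all events on the given day.

    This is the raster-plot projection used to examine how seizures group
    within a single day (typically the day of peak seizure frequency).
    """
    out = []
    for ev in events:
        if stage_filter is not None and ev.stage is not None and ev.stage < stage_filter:
            continue
        if int(np.floor(ev.t_hours_since_SE / HOURS_PER_DAY)) == day:
            out.append(ev.t_hours_since_SE - HOURS_PER_DAY * day)
    return sorted(out)


def events_from_frame(df: pd.DataFrame) -> list[SeizureEvent]:
    """Build events from a DataFrame with the events-CSV schema.

    Expected columns: ``animal_id``, ``t_hours_since_SE``, optional ``stage``.
    """
    has_stage = "stage" in df.columns
    evs = []
    for row in df.itertuples(index=False):
        stage = None
        if has_stage:
            raw = getattr(row, "stage")
            if raw is not None and not (isinstance(raw, float) and np.isnan(raw)):
                stage = int(raw)
        evs.append(
            SeizureEvent(
                animal_id=str(getattr(row, "animal_id")),
                t_hours_since_SE=float(getattr(row, "t_hours_since_SE")),
                stage=stage,
            )
        )
    return evs
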