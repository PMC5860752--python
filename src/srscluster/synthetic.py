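"""Seeded synthetic cohorts of clustered spontaneous recurrent seizures.

The chronic pilocarpine mouse shows a cyclic pattern: unimodal seizure
clusters (slow rise to a daily peak, rapid fall) separated by long
seizure-free periods, with nearly all seizures inside clusters and a
non-uniform distribution of seizure times within a day.  This module
generates event tables, monitoring windows and ground-truth labels that
reproduce that structure so the whole analysis pipeline can be exercised
and validated without any recorded data.  It also generates single-channel
EEG traces with embedded ictal discharges for testing the electrographic
seizure detector.

The generative model is a renewal process: cluster onsets are separated by
truncated-normal intervals, cluster durations are truncated-normal rounded
to whole days, and each cluster's daily counts follow a deterministic
unimodal rise/fall profile scaled to a target peak and mean frequency.
Because onset-to-onset intervals observed inside a finite monitoring window
are length-biased (long intervals are less likely to fit), the interval
sampling location is calibrated so that the *observed* interval mean
matches the configured mean; likewise every truncated-normal location is
solved so the truncated mean equals the configured mean.  Outside-cluster
("isolated") seizures are governed by a per-animal propensity drawn from a
skewed Beta distribution, reflecting that most animals have essentially all
seizures in clusters while a few have many strays.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from functools import lru_cache
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .clusters import HOURS_PER_DAY

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "GroundTruthCluster",
    "GroundTruth",
    "EEGSpec",
    "Discharge",
    "generate_cluster_profile",
    "generate_cohort",
    "generate_eeg",
]


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the cohort generator.

    Defaults are the chronic-phase study conditions (cohort means +- SD with
    truncation at the observed ranges): cluster interval 22.7+-8.7 d in
    [7, 37], duration 5.7+-2.0 d in [3, 11], peak frequency 17.3+-6.5 /d in
    [2, 32], within-cluster mean frequency 8.0 /d, 97% of seizures inside
    clusters, monitoring 53.7+-20.4 d in [30, 102] starting 84.5+-33.7 d
    after SE in [42, 155].  ``rise_fraction`` places the peak day at
    ``round(rise_fraction * (duration - 1))`` from onset; the default comes
    from the observed mean rise and fall times (3.4 and 1.2 d).
    """

    n_mice: int = 27
    # monitoring window (days)
    monitoring_duration_mean: float = 53.7
    monitoring_duration_sd: float = 20.4
    monitoring_duration_min: float = 30.0
    monitoring_duration_max: float = 102.0
    monitoring_start_day_mean: float = 84.5
    monitoring_start_day_sd: float = 33.7
    monitoring_start_day_min: float = 42.0
    monitoring_start_day_max: float = 155.0
    # cluster renewal process (days)
    cluster_interval_mean: float = 22.7
    cluster_interval_sd: float = 8.7
    cluster_interval_min: float = 7.0
    cluster_interval_max: float = 37.0
    cluster_duration_mean: float = 5.7
    cluster_duration_sd: float = 2.0
    duration_min: int = 3
    duration_max: int = 11
    # daily-count profile (seizures/day)
    peak_frequency_mean: float = 17.3
    peak_frequency_sd: float = 6.5
    peak_frequency_min: float = 2.0
    peak_frequency_max: float = 32.0
    within_cluster_mean_frequency: float = 8.0
    rise_fraction: float = 3.4 / (3.4 + 1.2)
    # isolated (outside-cluster) seizures
    within_cluster_fraction: float = 0.97
    outside_dispersion: float = 5.0  # Beta concentration of per-animal rate
    outside_fraction_max: float = 0.375  # 1 - min observed within-fraction
    # within-day timing
    tod_concentration: float = 2.0  # von Mises kappa; 0 = uniform
    tod_peak_hour: float = 18.0
    # plumbing
    allow_edge_truncation: bool = True
    calibrate_interval: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.duration_min < 3:
            raise ValueError("duration_min must be >= 3 (cluster rule)")
        if self.duration_max < self.duration_min:
            raise ValueError("duration_max < duration_min")
        if self.cluster_interval_mean <= self.cluster_duration_mean:
            raise ValueError("cluster_interval_mean must exceed cluster_duration_mean")
        if not 0.0 < self.within_cluster_fraction <= 1.0:
            raise ValueError("within_cluster_fraction must be in (0, 1]")
        if not 0.0 <= self.rise_fraction <= 1.0:
            raise ValueError("rise_fraction must be in [0, 1]")
        if self.peak_frequency_min < 2.0:
            raise ValueError("peak frequency must be >= 2 seizures/day")
        if self.within_cluster_mean_frequency < 1.0:
            raise ValueError("within_cluster_mean_frequency must be >= 1")
        if self.tod_concentration < 0.0:
            raise ValueError("tod_concentration must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SyntheticConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load a config from YAML or JSON; every field addressable by name."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GroundTruthCluster:
    """True (visible) span of one generated cluster."""

    animal_id: str
    onset_day: int
    end_day: int
    peak_day: int
    per_day_counts: tuple[int, ...]
    truncated_start: bool
    truncated_end: bool


@dataclass
class GroundTruth:
    """Generator-side labels for recovery checks.

    ``event_in_cluster`` aligns with the rows of the events table.
    """

    clusters: dict[str, list[GroundTruthCluster]]
    event_in_cluster: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clusters": {
                aid: [
                    {
                        "onset_day": c.onset_day,
                        "end_day": c.end_day,
                        "peak_day": c.peak_day,
                        "per_day_counts": list(c.per_day_counts),
                        "truncated_start": c.truncated_start,
                        "truncated_end": c.truncated_end,
                    }
                    for c in cl
                ]
                for aid, cl in self.clusters.items()
            },
            "event_in_cluster": [bool(x) for x in self.event_in_cluster],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# --------------------------------------------------------------------------
# truncated-normal helpers

def _truncnorm_dist(loc: float, sd: float, lo: float, hi: float):
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm(a, b, loc=loc, scale=sd)


def _solve_truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal whose truncated mean equals target."""
    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} outside ({lo}, {hi})")

    def gap(loc: float) -> float:
        return _truncnorm_dist(loc, sd, lo, hi).mean() - target_mean

    return brentq(gap, lo - 10 * sd, hi + 10 * sd, xtol=1e-6)


def _calibrated_interval_loc(cfg: SyntheticConfig) -> float:
    """Interval-sampling location that inverts window length-bias.

    An onset-to-onset interval of length x is fully observed inside a
    monitoring window of length W with probability proportional to
    (W - 1 - x)+ to first order, so the observed mean falls short of the
    sampled mean by roughly var(x)/(E[W] - E[x]).  This solves for the
    sampling location at which the censoring-weighted mean equals the
    configured interval mean.
    """
    w_loc = _solve_truncnorm_loc(
        cfg.monitoring_duration_mean,
        cfg.monitoring_duration_sd,
        cfg.monitoring_duration_min,
        cfg.monitoring_duration_max,
    )
    wdist = _truncnorm_dist(
        w_loc, cfg.monitoring_duration_sd,
        cfg.monitoring_duration_min, cfg.monitoring_duration_max,
    )
    w = np.linspace(cfg.monitoring_duration_min, cfg.monitoring_duration_max, 513)
    pw = wdist.pdf(w)
    pw /= pw.sum()
    x = np.linspace(cfg.cluster_interval_min, cfg.cluster_interval_max, 1025)
    weight = np.clip(w[None, :] - 1.0 - x[:, None], 0.0, None) @ pw

    lo, hi = cfg.cluster_interval_min, cfg.cluster_interval_max
    sd = cfg.cluster_interval_sd
    fallback = _solve_truncnorm_loc(cfg.cluster_interval_mean, sd, lo, hi)
    if weight.max() <= 0:
        # windows can never hold two onsets: no observable intervals to
        # calibrate against, fall back to plain moment matching
        return fallback

    def gap(loc: float) -> float:
        fx = _truncnorm_dist(loc, sd, lo, hi).pdf(x)
        wgt = fx * weight
        tot = wgt.sum()
        if tot <= 0:
            return hi  # push solver upward
        return float((x * wgt).sum() / tot) - cfg.cluster_interval_mean

    a, b = lo, hi + 10 * sd
    if gap(a) * gap(b) > 0:
        return fallback
    return brentq(gap, a, b, xtol=1e-6)


# --------------------------------------------------------------------------
# daily-count profile

def generate_cluster_profile(
    duration: int,
    peak: float,
    mean_frequency: float,
    rise_fraction: float,
) -> np.ndarray:
    """Deterministic unimodal daily-count profile for one cluster.

    The profile rises linearly from 1 to the peak over the rise days and
    falls linearly back to 1 over the fall days; the peak day index is
    ``round(rise_fraction * (duration - 1))``.  Interior days are scaled
    affinely (clipped to [1, peak - 1], so the peak day is a strict unique
    maximum) and rounded by largest remainder so the counts are integers
    summing to ``round(mean_frequency * duration)``, clamped into the
    feasible range.

    Returns ``duration`` integers, each >= 1, with maximum exactly
    ``round(peak)``, non-decreasing up to the peak day and non-increasing
    after it.
    """
    duration = int(duration)
    if duration < 3:
        raise ValueError("cluster duration must be >= 3 days")
    if peak < 2:
        raise ValueError("peak frequency must be >= 2 seizures/day")
    if mean_frequency > peak:
        raise ValueError("mean_frequency cannot exceed the peak frequency")
    if mean_frequency < 1:
        raise ValueError("mean_frequency must be >= 1 seizure/day")
    if not 0.0 <= rise_fraction <= 1.0:
        raise ValueError("rise_fraction must be in [0, 1]")

    p = int(round(rise_fraction * (duration - 1)))
    P = int(round(peak))
    # interior days are capped below the peak so the maximum day is unique
    # (except at the floor P=2, where total >= 5 requires a plateau)
    cap = P - 1 if P > 2 else P
    T = int(round(mean_frequency * duration))
    T = min(max(T, max(5, P + duration - 1)), P + (duration - 1) * cap)

    idx = np.arange(duration, dtype=float)
    shape = np.empty(duration)
    if p > 0:
        shape[: p + 1] = 1.0 + (P - 1.0) * idx[: p + 1] / p
    if p < duration - 1:
        tail = idx[p:] - p
        shape[p:] = P - (P - 1.0) * tail / (duration - 1 - p)
    shape[p] = P

    interior = np.delete(np.arange(duration), p)
    growable = interior[shape[interior] > 1.0]
    stuck = interior[shape[interior] <= 1.0]  # shape floor: scaling cannot lift

    real = np.empty(duration)
    real[p] = P
    t1_max = P + len(growable) * cap + len(stuck)  # supremum of stage-1 totals
    if T < t1_max:
        # stage 1: affine scaling of the interior, clipped to [1, cap]
        def total(lam: float) -> float:
            c = 1.0 + (shape[interior] - 1.0) * lam
            return float(np.clip(c, 1.0, cap).sum()) + P

        lo, hi = 0.0, 1.0
        while total(hi) < T:
            hi *= 2.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if total(mid) < T:
                lo = mid
            else:
                hi = mid
        lam = 0.5 * (lo + hi)
        real[interior] = np.clip(1.0 + (shape[interior] - 1.0) * lam, 1.0, cap)
    else:
        # stage 2: near-flat cluster — growable days saturate at the interior
        # cap, the remainder water-fills the shape-floor days (cluster ends)
        real[growable] = cap
        real[stuck] = 1.0
        extra = T - t1_max
        for i in sorted(stuck, key=lambda i: (abs(i - p), i)):
            add = min(extra, cap - 1)
            real[i] += add
            extra -= add
        assert extra == 0

    counts = np.floor(real).astype(int)
    counts[p] = P
    deficit = T - int(counts.sum())
    if deficit > 0:
        rema = real - np.floor(real)
        rema[p] = -1.0  # peak stays fixed
        # prefer larger remainder; break ties toward the peak day
        order = sorted(
            interior, key=lambda i: (-rema[i], abs(i - p), i)
        )
        for i in order[:deficit]:
            counts[i] += 1

    assert counts.sum() == T
    assert counts.min() >= 1 and counts.max() == P
    assert np.all(np.diff(counts[: p + 1]) >= 0)
    assert np.all(np.diff(counts[p:]) <= 0)
    return counts


@dataclass(frozen=True)
class _Locs:
    """Solved truncated-normal locations for all sampled quantities."""

    duration: float
    peak: float
    interval: float
    monitoring: float
    start: float


def _solve_locs(cfg: SyntheticConfig) -> _Locs:
    dur_loc = _solve_truncnorm_loc(
        cfg.cluster_duration_mean, cfg.cluster_duration_sd,
        cfg.duration_min - 0.499, cfg.duration_max + 0.499,
    )
    peak_loc = _solve_truncnorm_loc(
        cfg.peak_frequency_mean, cfg.peak_frequency_sd,
        cfg.peak_frequency_min, cfg.peak_frequency_max,
    )
    if cfg.calibrate_interval:
        int_loc = _calibrated_interval_loc(cfg)
    else:
        int_loc = _solve_truncnorm_loc(
            cfg.cluster_interval_mean, cfg.cluster_interval_sd,
            cfg.cluster_interval_min, cfg.cluster_interval_max,
        )
    mon_loc = _solve_truncnorm_loc(
        cfg.monitoring_duration_mean, cfg.monitoring_duration_sd,
        cfg.monitoring_duration_min, cfg.monitoring_duration_max,
    )
    start_loc = _solve_truncnorm_loc(
        cfg.monitoring_start_day_mean, cfg.monitoring_start_day_sd,
        cfg.monitoring_start_day_min, cfg.monitoring_start_day_max,
    )
    return _Locs(dur_loc, peak_loc, int_loc, mon_loc, start_loc)


@dataclass(frozen=True)
class _Span:
    """Visible part of one generated cluster."""

    days: np.ndarray  # monitored day indices
    counts: np.ndarray  # seizures on those days
    peak_day: int  # true peak day (may lie outside the window)
    truncated_start: bool
    truncated_end: bool

    def sum(self) -> int:  # convenience for the calibration loop
        return int(self.counts.sum())


def _sample_animal_spans(
    rng: np.random.Generator, cfg: SyntheticConfig, locs: _Locs
) -> tuple[int, int, list[_Span]]:
    """Sample one animal's window and visible cluster spans."""
    W = int(round(_sample_trunc(
        rng, locs.monitoring, cfg.monitoring_duration_sd,
        cfg.monitoring_duration_min, cfg.monitoring_duration_max)))
    S = int(round(_sample_trunc(
        rng, locs.start, cfg.monitoring_start_day_sd,
        cfg.monitoring_start_day_min, cfg.monitoring_start_day_max)))
    E = S + W - 1

    first_int = _sample_trunc(
        rng, locs.interval, cfg.cluster_interval_sd,
        cfg.cluster_interval_min, cfg.cluster_interval_max)
    offset = int(rng.integers(0, max(1, int(round(first_int)))))
    onset = (S - offset) if cfg.allow_edge_truncation else (S + 1 + offset)

    spans: list[_Span] = []
    while onset <= E:
        d = int(round(_sample_trunc(
            rng, locs.duration, cfg.cluster_duration_sd,
            cfg.duration_min - 0.499, cfg.duration_max + 0.499)))
        d = int(np.clip(d, cfg.duration_min, cfg.duration_max))
        P = float(_sample_trunc(
            rng, locs.peak, cfg.peak_frequency_sd,
            cfg.peak_frequency_min, cfg.peak_frequency_max))
        mf = min(cfg.within_cluster_mean_frequency, P)
        profile = generate_cluster_profile(d, P, mf, cfg.rise_fraction)
        days = np.arange(onset, onset + d)
        peak_day = onset + int(np.argmax(profile))

        visible = (days >= S) & (days <= E)
        fits_untruncated = onset >= S + 1 and onset + d - 1 <= E - 1
        keep = fits_untruncated if not cfg.allow_edge_truncation else bool(visible.any())
        if keep:
            spans.append(_Span(
                days=days[visible],
                counts=profile[visible],
                peak_day=peak_day,
                truncated_start=bool(days[0] < S),
                truncated_end=bool(days[-1] > E),
            ))
        nxt = _sample_trunc(
            rng, locs.interval, cfg.cluster_interval_sd,
            cfg.cluster_interval_min, cfg.cluster_interval_max)
        onset = onset + max(int(round(nxt)), d + 2)
    return S, E, spans


def _fragment_loss_fraction(cfg: SyntheticConfig, locs: Optional[_Locs] = None) -> float:
    """Expected fraction of in-cluster seizures lost to edge fragments.

    When a monitoring window starts or ends inside a cluster, the visible
    fragment may fail the detection rule (< 3 consecutive days or < 5
    seizures) and its seizures are then counted as outside clusters by the
    analysis.  Since the reported within-cluster percentage is such an
    *observed* quantity, the generator compensates for this loss when
    setting the isolated-seizure rate.  The loss is evaluated by an internal
    deterministic span-level simulation (windows, renewal onsets, profiles —
    no event sampling) with a fixed seed, so it reproduces the window/cycle
    geometry of the generator exactly; it is part of the model definition,
    not of the cohort randomness.
    """
    if not cfg.allow_edge_truncation:
        return 0.0
    if locs is None:
        locs = _solve_locs(cfg)
    rng = np.random.default_rng(987654321)
    n_in = 0
    lost = 0
    for _ in range(400):
        _S, _E, spans = _sample_animal_spans(rng, cfg, locs)
        for sp in spans:
            n_in += sp.sum()
            if len(sp.counts) < 3 or sp.sum() < 5:
                lost += sp.sum()
    if n_in == 0:
        return 0.0
    return float(min(lost / n_in, 0.5))


def _outside_beta_params(
    cfg: SyntheticConfig, locs: Optional[_Locs] = None
) -> Optional[tuple[float, float]]:
    """Beta parameters of the per-animal outside-seizure propensity.

    Calibrated so the *observed* within-cluster percentage (after fragment
    losses) matches ``within_cluster_fraction``; returns None when no
    isolated seizures should be generated.
    """
    q = cfg.within_cluster_fraction
    if q >= 1.0:
        return None
    f = _fragment_loss_fraction(cfg, locs)
    r = max((1.0 - f) / q - 1.0, 0.0)  # isolated-to-in-cluster event ratio
    if r <= 0.0:
        return None
    m = r / (1.0 + r)
    return cfg.outside_dispersion * m, cfg.outside_dispersion * (1.0 - m)


@lru_cache(maxsize=32)
def _model_params_cached(norm: SyntheticConfig):
    locs = _solve_locs(norm)
    return locs, _outside_beta_params(norm, locs)


def _model_params(cfg: SyntheticConfig):
    """Solved locations and outside-propensity parameters, cached.

    The solved model is independent of the seed and the cohort size, so it
    is cached on the config with those fields normalized out.
    """
    norm = dataclasses.replace(cfg, seed=0, n_mice=1)
    return _model_params_cached(norm)


# --------------------------------------------------------------------------
# cohort generation

def _sample_trunc(rng: np.random.Generator, loc: float, sd: float,
                  lo: float, hi: float, size: Optional[int] = None):
    a, b = (lo - loc) / sd, (hi - loc) / sd
    u = rng.uniform(size=size)
    return truncnorm.ppf(u, a, b, loc=loc, scale=sd)


def _sample_hours(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    """Within-day event times (hours) from the circular time-of-day profile."""
    if cfg.tod_concentration > 0:
        theta = rng.vonmises(0.0, cfg.tod_concentration, size=n)
    else:
        theta = rng.uniform(-np.pi, np.pi, size=n)
    hours = (theta / (2.0 * np.pi) * HOURS_PER_DAY + cfg.tod_peak_hour) % HOURS_PER_DAY
    return hours


def _would_make_triple(day: int, chosen: set[int]) -> bool:
    """True if adding `day` creates three consecutive isolated-event days."""
    s = chosen | {day}
    for a in (day - 2, day - 1, day):
        if {a, a + 1, a + 2} <= s:
            return True
    return False


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a synthetic cohort of chronically epileptic mice.

    Returns ``(events, windows, ground_truth)`` where ``events`` has columns
    ``animal_id, t_hours_since_SE, stage`` (sorted by animal and time),
    ``windows`` has ``animal_id, start_day, end_day`` (inclusive, days since
    SE), and ``ground_truth`` carries the true cluster spans and per-event
    in-cluster labels.  All randomness flows from ``config.seed`` through a
    named stream per animal, so identical configs give identical output.
    """
    cfg = config
    locs, beta_params = _model_params(cfg)

    rows: list[tuple[str, float, int]] = []
    labels: list[bool] = []
    win_rows: list[tuple[str, int, int]] = []
    gt_clusters: dict[str, list[GroundTruthCluster]] = {}

    width = len(str(cfg.n_mice))
    for i in range(cfg.n_mice):
        aid = f"m{i + 1:0{width}d}"
        rng = np.random.default_rng([cfg.seed, i])

        S, E, spans = _sample_animal_spans(rng, cfg, locs)
        win_rows.append((aid, S, E))

        # per-animal outside-cluster propensity
        if beta_params is None:
            z = 0.0
        else:
            z = min(float(rng.beta(*beta_params)), cfg.outside_fraction_max)

        clusters: list[GroundTruthCluster] = []
        n_in = 0
        for sp in spans:
            clusters.append(GroundTruthCluster(
                animal_id=aid,
                onset_day=int(sp.days[0]),
                end_day=int(sp.days[-1]),
                peak_day=sp.peak_day,
                per_day_counts=tuple(int(c) for c in sp.counts),
                truncated_start=sp.truncated_start,
                truncated_end=sp.truncated_end,
            ))
            for day, c in zip(sp.days, sp.counts):
                hours = _sample_hours(rng, int(c), cfg)
                for h in np.sort(hours):
                    rows.append((aid, day * HOURS_PER_DAY + h,
                                 int(rng.choice([4, 5]))))
                    labels.append(True)
                    n_in += 1

        if not clusters:
            logger.warning(
                "animal %s: monitoring window [%d, %d] holds no cluster", aid, S, E
            )
        gt_clusters[aid] = clusters

        # isolated events on days >= 2 days away from every cluster boundary
        if z > 0.0 and n_in > 0:
            eligible = []
            for day in range(S, E + 1):
                if all(day <= c.onset_day - 2 or day >= c.end_day + 2
                       for c in clusters):
                    eligible.append(day)
            n_iso = int(rng.poisson(n_in * z / (1.0 - z))) if eligible else 0
            chosen: set[int] = set()
            placed_days: list[int] = []
            for _ in range(n_iso):
                for _attempt in range(64):
                    day = int(eligible[rng.integers(0, len(eligible))])
                    if day in chosen or not _would_make_triple(day, chosen):
                        break
                else:
                    continue  # could not place without forming a false run
                chosen.add(day)
                placed_days.append(day)
            for day in placed_days:
                h = float(_sample_hours(rng, 1, cfg)[0])
                rows.append((aid, day * HOURS_PER_DAY + h, int(rng.choice([4, 5]))))
                labels.append(False)

    events = pd.DataFrame(rows, columns=["animal_id", "t_hours_since_SE", "stage"])
    label_arr = np.asarray(labels, dtype=bool)
    order = np.lexsort((events["t_hours_since_SE"].to_numpy(),
                        events["animal_id"].to_numpy()))
    events = events.iloc[order].reset_index(drop=True)
    label_arr = label_arr[order]
    windows = pd.DataFrame(win_rows, columns=["animal_id", "start_day", "end_day"])
    return events, windows, GroundTruth(clusters=gt_clusters, event_in_cluster=label_arr)


def write_cohort(
    out_dir: str | Path,
    events: pd.DataFrame,
    windows: pd.DataFrame,
    ground_truth: Optional[GroundTruth] = None,
) -> dict[str, Path]:
    """Write events/windows CSV (and ground-truth JSON) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / "events.csv",
        "windows": out / "windows.csv",
    }
    events.to_csv(paths["events"], index=False)
    windows.to_csv(paths["windows"], index=False)
    if ground_truth is not None:
        paths["ground_truth"] = out / "ground_truth.json"
        ground_truth.to_json(paths["ground_truth"])
    return paths


# --------------------------------------------------------------------------
# synthetic EEG

@dataclass(frozen=True)
class Discharge:
    """One embedded ictal discharge: repetitive spiking above baseline."""

    onset_s: float
    duration_s: float
    spike_rate: float = 6.0  # spikes/s
    amplitude_ratio: float = 3.0  # segment RMS relative to baseline RMS

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class EEGSpec:
    """Specification of a synthetic single-channel EEG trace.

    Baseline is band-limited Gaussian noise at ``baseline_rms``; each
    discharge segment is a train of sharp positive transients at the given
    spike rate, scaled so the segment RMS is ``amplitude_ratio`` times the
    baseline RMS.  Discharges must be non-overlapping and separated by more
    than ``min_separation_s`` (the detector's merge gap).
    """

    duration_s: float
    sampling_rate: float = 400.0
    baseline_rms: float = 1.0
    discharges: tuple[Discharge, ...] = ()
    min_separation_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.baseline_rms <= 0:
            raise ValueError("baseline_rms must be positive")
        ds = sorted(self.discharges, key=lambda d: d.onset_s)
        for d in ds:
            if d.onset_s < 0 or d.offset_s > self.duration_s:
                raise ValueError(f"discharge {d} outside the trace")
            if d.spike_rate <= 0 or d.amplitude_ratio <= 0:
                raise ValueError("spike_rate and amplitude_ratio must be positive")
        for a, b in zip(ds, ds[1:]):
            if b.onset_s - a.offset_s <= self.min_separation_s:
                raise ValueError(
                    f"discharges at {a.onset_s}s and {b.onset_s}s overlap or are "
                    f"separated by <= {self.min_separation_s}s"
                )
        object.__setattr__(self, "discharges", tuple(ds))


def generate_eeg(spec: EEGSpec) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Synthesize a single-channel trace with embedded ictal discharges.

    Returns ``(trace, intervals)`` with the ground-truth discharge intervals
    in seconds.  Spikes are Gaussian transients (sigma 8 ms) centred at
    ``onset + (k + 1/2)/rate`` so every full one-second window inside a
    discharge holds exactly ``round(rate)`` spikes.
    """
    from scipy.signal import butter, sosfiltfilt

    fs = spec.sampling_rate
    n = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed)

    sos = butter(4, [0.5, min(70.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    noise = sosfiltfilt(sos, rng.standard_normal(n))
    noise *= spec.baseline_rms / np.sqrt(np.mean(noise**2))
    # soft-limit baseline excursions below twice the RMS so that ground
    # truth is unambiguous: baseline never crosses the detector's 2x-baseline
    # spike threshold, only embedded discharges do
    lim = 1.8 * spec.baseline_rms
    noise = lim * np.tanh(noise / lim)
    noise *= spec.baseline_rms / np.sqrt(np.mean(noise**2))
    noise = np.clip(noise, -1.9 * spec.baseline_rms, 1.9 * spec.baseline_rms)
    trace = noise.copy()

    t = np.arange(n) / fs
    sigma = 0.008  # spike width, s
    intervals = []
    for d in spec.discharges:
        i0 = int(round(d.onset_s * fs))
        i1 = int(round(d.offset_s * fs))
        n_spikes = int(np.floor(d.duration_s * d.spike_rate))
        ts = t[i0:i1]
        spikes = np.zeros_like(ts)
        for k in range(n_spikes):
            centre = d.onset_s + (k + 0.5) / d.spike_rate
            spikes += np.exp(-0.5 * ((ts - centre) / sigma) ** 2)
        # quiet background inside the discharge so local extrema are the
        # spikes themselves; the spike train carries the target RMS
        floor = 0.3 * spec.baseline_rms
        target = d.amplitude_ratio * spec.baseline_rms
        spike_rms = float(np.sqrt(np.mean(spikes**2)))
        spike_target = np.sqrt(max(target**2 - floor**2, (0.05 * target) ** 2))
        trace[i0:i1] = 0.3 * noise[i0:i1] + spikes * (spike_target / spike_rms)
        intervals.append((d.onset_s, d.offset_s))
    return trace, intervals
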