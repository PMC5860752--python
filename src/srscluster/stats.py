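"""Cohort-level summaries and hypothesis tests for seizure-cluster metrics.

Summaries are reported as mean +- sample SD with range, per metric.  Group
comparisons use the classic pooled-variance two-sample t test, paired data
use the paired t test, and associations use Pearson's correlation, all with
two-tailed p-values at alpha = 0.05.  Animals are assigned to chronic
phase 1 (monitoring starting 6-14 weeks after SE) or chronic phase 2
(starting >= 15 weeks after SE) by their monitoring start day.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "TestResult",
    "PhaseAssignment",
    "summarize",
    "compare_groups",
    "paired_compare",
    "correlate",
    "assign_phase",
    "cohort_table",
]

ALPHA = 0.05

CHRONIC1_START_MIN = 42  # 6 weeks
CHRONIC1_START_MAX = 98  # 14 weeks
CHRONIC2_START_MIN = 105  # 15 weeks


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: Optional[float]  # None when n == 1
    min: float
    max: float
    n: int

    def __str__(self) -> str:
        sd = f"{self.sd:.1f}" if self.sd is not None else "--"
        return f"{self.mean:.1f}±{sd} ({self.min:g}–{self.max:g}), n={self.n}"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < ALPHA


@dataclass(frozen=True)
class PhaseAssignment:
    animal_id: str
    phase: str  # chronic_1 | chronic_2 | unclassified
    monitoring_start_day: int
    monitoring_end_day: int


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample (n-1) SD, and range of a metric."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty list")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else None
    return SummaryStats(
        mean=float(np.mean(x)), sd=sd, min=float(np.min(x)),
        max=float(np.max(x)), n=int(x.size),
    )


def compare_groups(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Classic pooled-variance two-sample Student's t test (two-tailed)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant groups: no evidence of a difference
            return TestResult(0.0, 1.0)
        # constant groups with different means: degenerate for a t test
        return TestResult(math.inf if np.mean(a) > np.mean(b) else -math.inf,
                          0.0, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant data
        t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(t), float(p))


def paired_compare(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired t test: one-sample t on the within-pair differences."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = x - y
    if np.var(d, ddof=1) == 0:
        return TestResult(math.nan, math.nan, degenerate=True)
    t, p = sps.ttest_rel(x, y)
    return TestResult(float(t), float(p))


def correlate(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with its t-based two-tailed p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for a constant sample")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p))


def assign_phase(
    animal_id: str, start_day: int, end_day: int
) -> PhaseAssignment:
    """Assign an animal to a chronic phase by its monitoring start day.

    Phase 1: start within days [42, 98] after SE (weeks 6-14); phase 2:
    start on day >= 105 (week 15 on).  Starts in the gap (98, 105) or
    before day 42 are unclassified.
    """
    if start_day > end_day:
        raise ValueError("start_day > end_day")
    if CHRONIC1_START_MIN <= start_day <= CHRONIC1_START_MAX:
        phase = "chronic_1"
    elif start_day >= CHRONIC2_START_MIN:
        phase = "chronic_2"
    else:
        phase = "unclassified"
    return PhaseAssignment(animal_id, phase, int(start_day), int(end_day))


# --------------------------------------------------------------------------
# cohort summary table

#: (row label, source, column) — source 'animal' rows aggregate one value per
#: animal; 'cluster' rows aggregate over fully monitored clusters; 'gap' rows
#: aggregate over inter-cluster gaps.
_TABLE_ROWS = [
    ("monitoring_onset_day", "animal", "start_day"),
    ("monitoring_end_day", "animal", "end_day"),
    ("monitoring_days", "animal", "n_days"),
    ("total_seizures", "animal", "total_seizures"),
    ("within_cluster_pct", "animal", "within_cluster_pct"),
    ("clusters_per_animal", "animal", "n_clusters"),
    ("overall_frequency_per_day", "animal", "frequency_per_day"),
    ("cluster_total_seizures", "cluster", "total_seizures"),
    ("within_cluster_frequency_per_day", "cluster", "mean_frequency"),
    ("peak_frequency_per_day", "cluster", "peak_frequency"),
    ("cluster_duration_days", "cluster", "duration"),
    ("rise_days", "cluster", "rise_days"),
    ("fall_days", "cluster", "fall_days"),
    ("cluster_interval_days", "gap", "interval"),
    ("seizure_free_days", "gap", "seizure_free_days"),
]


def cohort_table(
    per_animal: pd.DataFrame,
    per_cluster: pd.DataFrame,
    per_gap: pd.DataFrame,
) -> pd.DataFrame:
    """Summary table: one row per metric, columns total / phase 1 / phase 2 / p.

    ``per_animal`` needs a ``phase`` column; cluster and gap frames need an
    ``animal_id`` column to inherit the animal's phase.  Cluster-level rows
    use fully monitored clusters only; interval rows use gaps with an
    observed earlier onset; seizure-free rows use uninterrupted gaps only.
    """
    phase_of = dict(zip(per_animal["animal_id"], per_animal["phase"]))

    fm = per_cluster[per_cluster["fully_monitored"]] if len(per_cluster) else per_cluster
    gi = per_gap.dropna(subset=["interval"]) if len(per_gap) else per_gap
    gf = per_gap[~per_gap["interrupted"]] if len(per_gap) else per_gap

    def values(source: str, col: str, phase: Optional[str]) -> np.ndarray:
        if source == "animal":
            df = per_animal
        elif source == "cluster":
            df = fm
        else:
            df = gf if col == "seizure_free_days" else gi
        if phase is not None and len(df):
            df = df[df["animal_id"].map(phase_of) == phase]
        if col not in df.columns:
            return np.array([])
        return df[col].dropna().to_numpy(dtype=float)

    rows = []
    for label, source, col in _TABLE_ROWS:
        total = values(source, col, None)
        p1 = values(source, col, "chronic_1")
        p2 = values(source, col, "chronic_2")
        p_val = np.nan
        if len(p1) >= 2 and len(p2) >= 2:
            p_val = compare_groups(p1, p2).p_value
        rec = {"metric": label}
        for name, v in (("total", total), ("phase_1", p1), ("phase_2", p2)):
            if len(v):
                s = summarize(v)
                rec[f"{name}_mean"] = round(s.mean, 4)
                rec[f"{name}_sd"] = round(s.sd, 4) if s.sd is not None else np.nan
                rec[f"{name}_min"] = s.min
                rec[f"{name}_max"] = s.max
                rec[f"{name}_n"] = s.n
            else:
                rec[f"{name}_mean"] = np.nan
                rec[f"{name}_sd"] = np.nan
                rec[f"{name}_min"] = np.nan
                rec[f"{name}_max"] = np.nan
                rec[f"{name}_n"] = 0
        rec["p_phase1_vs_phase2"] = round(p_val, 6) if np.isfinite(p_val) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
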