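"""End-to-end orchestration: simulate / detect -> bin -> cluster -> summarize.

A run takes one of three input modes — a synthetic cohort, an events CSV
with monitoring windows, or raw EEG traces — pushes the events through
daily binning, cluster detection and metric computation, and writes the
per-cluster table, per-animal table, gap table, Table-style cohort summary
and a provenance block.  Outputs are pure functions of the inputs and the
configuration, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .clusters import (
    DailyCountSeries,
    bin_daily,
    compute_metrics,
    detect_clusters,
    events_from_frame,
)
from .eeg import DetectorConfig, detect_seizures, read_trace_csv, read_trace_edf
from .stats import assign_phase, cohort_table
from .synthetic import SyntheticConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "analyze_cohort", "analyze_animal"]


def analyze_animal(
    events,
    window: tuple[int, int],
    stage_filter: Optional[int] = None,
):
    """Bin one animal's events, detect clusters, and compute metrics.

    Returns ``(series, metrics)``; cluster FM flags are filled in.
    """
    series = bin_daily(events, window, stage_filter=stage_filter)
    clusters = detect_clusters(series)
    metrics = compute_metrics(series, clusters)
    return series, metrics


def analyze_cohort(
    events: pd.DataFrame,
    windows: pd.DataFrame,
    stage_filter: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the cluster analysis for every animal in a cohort.

    ``events`` columns: animal_id, t_hours_since_SE, optional stage;
    ``windows`` columns: animal_id, start_day, end_day.  Returns
    ``(per_animal, per_cluster, per_gap)`` DataFrames.
    """
    ev_by_animal = {
        aid: events_from_frame(g) for aid, g in events.groupby("animal_id")
    }
    animal_rows, cluster_rows, gap_rows = [], [], []
    for row in windows.itertuples(index=False):
        aid = str(row.animal_id)
        window = (int(row.start_day), int(row.end_day))
        evs = ev_by_animal.get(aid, [])
        series, metrics = analyze_animal(evs, window, stage_filter=stage_filter)
        phase = assign_phase(aid, window[0], window[1]).phase
        animal_rows.append({
            "animal_id": aid,
            "start_day": window[0],
            "end_day": window[1],
            "n_days": series.n_days,
            "total_seizures": series.total,
            "n_clusters": len(metrics.clusters),
            "outside_seizures": metrics.outside_seizure_count,
            "within_cluster_pct": metrics.within_cluster_fraction,
            "frequency_per_day": series.total / series.n_days,
            "phase": phase,
        })
        for c in metrics.clusters:
            cluster_rows.append({
                "animal_id": aid,
                "onset_day": c.onset_day,
                "end_day": c.end_day,
                "duration": c.duration,
                "total_seizures": c.total_seizures,
                "peak_frequency": c.peak_frequency,
                "peak_day": c.peak_day,
                "rise_days": c.rise_days,
                "fall_days": c.fall_days,
                "mean_frequency": c.mean_frequency,
                "fully_monitored": bool(c.fully_monitored),
            })
        for g in metrics.gaps:
            gap_rows.append({
                "animal_id": aid,
                "interval": g.interval,
                "seizure_free_days": g.seizure_free_days,
                "interrupted": g.interrupted,
            })
    per_animal = pd.DataFrame(animal_rows)
    per_cluster = pd.DataFrame(
        cluster_rows,
        columns=["animal_id", "onset_day", "end_day", "duration",
                 "total_seizures", "peak_frequency", "peak_day", "rise_days",
                 "fall_days", "mean_frequency", "fully_monitored"],
    )
    per_gap = pd.DataFrame(
        gap_rows,
        columns=["animal_id", "interval", "seizure_free_days", "interrupted"],
    )
    return per_animal, per_cluster, per_gap


# --------------------------------------------------------------------------
# full run

@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    mode: str  # synthetic | events-csv | eeg
    out_dir: str
    seed: int = 0
    stage_filter: Optional[int] = None
    log_level: str = "INFO"
    # synthetic mode
    synthetic: Optional[SyntheticConfig] = None
    # events-csv mode
    events_path: Optional[str] = None
    windows_path: Optional[str] = None
    # eeg mode: traces listed as (animal_id, path, channel, day_offset_hours)
    detector: Optional[DetectorConfig] = None
    eeg_traces: tuple = ()

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "events-csv", "eeg"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "events-csv" and not (self.events_path and self.windows_path):
            raise ValueError("events-csv mode needs events_path and windows_path")
        if self.mode == "eeg" and not self.eeg_traces:
            raise ValueError("eeg mode needs at least one trace")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (not the output location)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.mode == "synthetic":
        synth = config.synthetic or SyntheticConfig(seed=config.seed)
        if synth.seed != config.seed:
            synth = dataclasses.replace(synth, seed=config.seed)
        events, windows, _gt = generate_cohort(synth)
        return events, windows
    if config.mode == "events-csv":
        events = pd.read_csv(config.events_path)
        windows = pd.read_csv(config.windows_path)
        return events, windows
    # eeg mode: detect seizures per trace and build an event table
    det = config.detector or DetectorConfig()
    rows = []
    win_rows = []
    for entry in config.eeg_traces:
        aid, path, channel, t0_hours = entry
        path = str(path)
        if path.lower().endswith(".edf"):
            trace, fs = read_trace_edf(path, channel)
        else:
            trace, fs = read_trace_csv(path)
        det_fs = dataclasses.replace(det, sampling_rate=fs)
        intervals = detect_seizures(trace, det_fs)
        for onset_s, _offset_s in intervals:
            rows.append({
                "animal_id": aid,
                "t_hours_since_SE": float(t0_hours) + onset_s / 3600.0,
                "stage": None,
            })
        day0 = int(np.floor(t0_hours / 24.0))
        day1 = int(np.floor((t0_hours + len(trace) / fs / 3600.0) / 24.0))
        win_rows.append({"animal_id": aid, "start_day": day0, "end_day": day1})
    events = pd.DataFrame(rows, columns=["animal_id", "t_hours_since_SE", "stage"])
    windows = (
        pd.DataFrame(win_rows)
        .groupby("animal_id", as_index=False)
        .agg(start_day=("start_day", "min"), end_day=("end_day", "max"))
    )
    return events, windows


def run(config: RunConfig) -> dict:
    """Execute a full pipeline run; returns the run report dictionary.

    Writes clusters.csv, animals.csv, gaps.csv, summary.json and (in
    synthetic mode) the generated events/windows CSVs into ``out_dir``.
    On a stage failure the partially written outputs are removed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        events, windows = _stage("input", _load_inputs, config)
        if config.mode == "synthetic":
            synth = config.synthetic or SyntheticConfig(seed=config.seed)
            if synth.seed != config.seed:
                synth = dataclasses.replace(synth, seed=config.seed)
            _, _, gt = generate_cohort(synth)
            paths = write_cohort(out, events, windows, gt)
            written.extend(paths.values())
        per_animal, per_cluster, per_gap = _stage(
            "cluster-analysis", analyze_cohort, events, windows, config.stage_filter
        )
        table = _stage("summary", cohort_table, per_animal, per_cluster, per_gap)

        for name, df in (("animals", per_animal), ("clusters", per_cluster),
                         ("gaps", per_gap), ("summary_table", table)):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)

        report = {
            "provenance": {
                "package": "srscluster",
                "version": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "mode": config.mode,
            },
            "n_animals": int(len(per_animal)),
            "n_clusters": int(len(per_cluster)),
            "n_fully_monitored": int(per_cluster["fully_monitored"].sum())
            if len(per_cluster) else 0,
            "summary": json.loads(table.to_json(orient="records")),
        }
        p = out / "summary.json"
        p.write_text(json.dumps(report, indent=1, sort_keys=True))
        written.append(p)
        return report
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise


def _stage(name: str, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
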