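"""Rule-based electrographic seizure detection on a single EEG channel.

An electrographic seizure is a discharge with (i) an amplitude change of
more than ``amplitude_ratio_threshold`` times baseline, (ii) repetitive
spiking at 4-12/s, and (iii) a duration of at least 10 s.  The detector
formalizes this written criterion operationally: the trace is split into
non-overlapping windows; a window qualifies iff its RMS exceeds the ratio
threshold times baseline AND its spike count (local extrema of |x| above
the amplitude threshold with >= 40 ms separation) divided by the window
length falls inside the spike-rate band.  Maximal runs of qualifying
windows, after closing gaps up to ``merge_gap``, are reported as seizures
iff their span reaches ``min_duration``.  Onsets/offsets are reported at
window-boundary resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "DetectorConfig",
    "estimate_baseline",
    "detect_seizures",
    "read_trace_csv",
    "read_trace_edf",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds of the electrographic seizure rule.

    Defaults are the published criterion: >2x baseline amplitude, repetitive
    spiking at 4-12/s, minimum duration 10 s, on a 400 Hz recording.
    """

    amplitude_ratio_threshold: float = 2.0
    spike_rate_band: tuple[float, float] = (4.0, 12.0)
    min_duration: float = 10.0  # s
    window_length: float = 1.0  # s
    merge_gap: float = 2.0  # s
    baseline_mode: str = "global-median"  # or "reference-segment"
    reference_segment: Optional[tuple[float, float]] = None  # (start_s, end_s)
    spike_refractory: float = 0.040  # s, minimum separation between spikes
    sampling_rate: float = 400.0  # Hz

    def __post_init__(self) -> None:
        low, high = self.spike_rate_band
        if not low < high:
            raise ValueError("spike_rate_band must satisfy low < high")
        if self.min_duration <= self.window_length:
            raise ValueError("min_duration must exceed window_length")
        if self.amplitude_ratio_threshold <= 1.0:
            raise ValueError("amplitude_ratio_threshold must be > 1")
        if self.baseline_mode not in ("global-median", "reference-segment"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")
        if self.baseline_mode == "reference-segment" and self.reference_segment is None:
            raise ValueError("reference-segment mode requires reference_segment")


def _window_rms(trace: np.ndarray, win: int) -> np.ndarray:
    n = len(trace) // win
    if n == 0:
        raise ValueError("trace shorter than one analysis window")
    x = trace[: n * win].reshape(n, win)
    return np.sqrt(np.mean(x**2, axis=1))


def estimate_baseline(trace: np.ndarray, config: DetectorConfig) -> float:
    """Robust baseline amplitude scale (signal units).

    ``global-median`` mode: median of per-window RMS over the whole trace,
    robust as long as ictal activity occupies a minority of windows.
    ``reference-segment`` mode: RMS of the declared seizure-free segment.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < 60 * config.sampling_rate:
        raise ValueError("need at least 60 s of signal to estimate a baseline")
    if config.baseline_mode == "reference-segment":
        s0, s1 = config.reference_segment
        i0, i1 = int(s0 * config.sampling_rate), int(s1 * config.sampling_rate)
        seg = trace[i0:i1]
        if len(seg) == 0:
            raise ValueError("empty reference segment")
        baseline = float(np.sqrt(np.mean(seg**2)))
    else:
        win = int(round(config.window_length * config.sampling_rate))
        baseline = float(np.median(_window_rms(trace, win)))
    if baseline <= 0:
        raise ValueError("no baseline definable: signal is identically zero")
    return baseline


def detect_seizures(
    trace: np.ndarray,
    config: DetectorConfig = DetectorConfig(),
    baseline: Optional[float] = None,
) -> list[tuple[float, float]]:
    """Detect electrographic seizures; returns sorted disjoint intervals (s)."""
    trace = np.asarray(trace, dtype=float)
    fs = config.sampling_rate
    if fs < 2.0 * config.spike_rate_band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz cannot resolve spikes at "
            f"{config.spike_rate_band[1]}/s"
        )
    if baseline is None:
        baseline = estimate_baseline(trace, config)
    if baseline <= 0:
        raise ValueError("baseline must be positive")

    win = int(round(config.window_length * fs))
    rms = _window_rms(trace, win)
    n_win = len(rms)
    thr = config.amplitude_ratio_threshold * baseline

    # spike times over the whole trace, then counted per window
    peaks, _ = find_peaks(
        np.abs(trace),
        height=thr,
        distance=max(1, int(round(config.spike_refractory * fs))),
    )
    spike_win = peaks // win
    counts = np.bincount(spike_win[spike_win < n_win], minlength=n_win)
    rate = counts / config.window_length

    low, high = config.spike_rate_band
    ok = (rms > thr) & (rate >= low) & (rate <= high)

    # close gaps <= merge_gap between qualifying runs
    gap_win = int(round(config.merge_gap / config.window_length))
    runs = _runs(ok)
    merged: list[list[int]] = []
    for i, j in runs:
        if merged and i - merged[-1][1] - 1 <= gap_win:
            merged[-1][1] = j
        else:
            merged.append([i, j])

    out = []
    for i, j in merged:
        span = (j - i + 1) * config.window_length
        if span >= config.min_duration:
            out.append((i * config.window_length, (j + 1) * config.window_length))
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


# --------------------------------------------------------------------------
# I/O

def read_trace_csv(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a two-column time/value CSV; returns (trace, sampling_rate)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("trace CSV needs time and value columns")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-3):
        raise ValueError("trace CSV must be uniformly sampled")
    return x, float(1.0 / dt[0])


def read_trace_edf(
    path: str | Path, channel: int | str = 0
) -> tuple[np.ndarray, float]:
    """Read one channel from an EDF recording (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency "
            "(pip install srscluster[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if isinstance(channel, str):
        picks = [raw.ch_names.index(channel)]
    else:
        picks = [int(channel)]
    data = raw.get_data(picks=picks)[0]
    return np.asarray(data, dtype=float), float(raw.info["sfreq"])


def write_trace_csv(path: str | Path, trace: np.ndarray, fs: float) -> None:
    t = np.arange(len(trace)) / fs
    pd.DataFrame({"t_s": t, "value": trace}).to_csv(path, index=False)


def detections_to_frame(intervals: list[tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame(intervals, columns=["onset_s", "offset_s"])
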