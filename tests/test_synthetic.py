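"""Cohort generator: determinism, label consistency, convergence, EEG."""

import dataclasses
import logging

import numpy as np
import pandas as pd
import pytest

from srscluster import (
    Discharge,
    EEGSpec,
    SyntheticConfig,
    bin_daily,
    detect_clusters,
    generate_cohort,
    generate_eeg,
)
from srscluster.clusters import events_from_frame


def test_seed_determinism():
    cfg = SyntheticConfig(n_mice=8, seed=123)
    ev1, win1, gt1 = generate_cohort(cfg)
    ev2, win2, gt2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(ev1, ev2)
    pd.testing.assert_frame_equal(win1, win2)
    assert np.array_equal(gt1.event_in_cluster, gt2.event_in_cluster)


def test_different_seeds_differ():
    ev1, _, _ = generate_cohort(SyntheticConfig(n_mice=5, seed=1))
    ev2, _, _ = generate_cohort(SyntheticConfig(n_mice=5, seed=2))
    assert not ev1.equals(ev2)


def test_all_within_when_fraction_is_one():
    cfg = SyntheticConfig(n_mice=10, seed=3, within_cluster_fraction=1.0,
                          allow_edge_truncation=False)
    events, windows, gt = generate_cohort(cfg)
    assert gt.event_in_cluster.all()
    # downstream: every seizure inside a detected cluster
    for row in windows.itertuples(index=False):
        evs = events_from_frame(events[events.animal_id == row.animal_id])
        series = bin_daily(evs, (row.start_day, row.end_day))
        clusters = detect_clusters(series)
        assert sum(c.total_seizures for c in clusters) == series.total


def test_exact_span_recovery_without_truncation(clean_cohort):
    """Detected cluster spans equal the generated ground-truth spans."""
    _, events, windows, gt = clean_cohort
    for row in windows.itertuples(index=False):
        evs = events_from_frame(events[events.animal_id == row.animal_id])
        series = bin_daily(evs, (row.start_day, row.end_day))
        detected = [(c.onset_day, c.end_day) for c in detect_clusters(series)]
        truth = [(c.onset_day, c.end_day) for c in gt.clusters[row.animal_id]]
        assert detected == truth


def test_isolated_events_never_form_false_clusters():
    cfg = SyntheticConfig(n_mice=20, seed=5, within_cluster_fraction=0.7,
                          allow_edge_truncation=False)
    events, windows, gt = generate_cohort(cfg)
    assert 0 < (~gt.event_in_cluster).sum()
    for row in windows.itertuples(index=False):
        evs = events_from_frame(events[events.animal_id == row.animal_id])
        series = bin_daily(evs, (row.start_day, row.end_day))
        detected = [(c.onset_day, c.end_day) for c in detect_clusters(series)]
        truth = [(c.onset_day, c.end_day) for c in gt.clusters[row.animal_id]]
        assert detected == truth


def test_event_labels_consistent_with_spans(small_cohort):
    """Every in-cluster event falls inside a labeled span; isolated events
    keep >= 2 days distance from every cluster boundary."""
    _, events, _, gt = small_cohort
    day = np.floor(events.t_hours_since_SE.to_numpy() / 24.0).astype(int)
    for aid, g in events.groupby("animal_id"):
        spans = [(c.onset_day, c.end_day) for c in gt.clusters[aid]]
        for i, d in zip(g.index, day[g.index]):
            inside = any(o <= d <= e for o, e in spans)
            if gt.event_in_cluster[i]:
                assert inside
            else:
                assert all(d <= o - 2 or d >= e + 2 for o, e in spans)


def test_sampled_parameter_convergence():
    """At n=300 the sampled duration/peak/interval means are close to the
    configured means (interval sampling sits above its configured mean by
    design, to offset window censoring, but stays within 10%)."""
    cfg = SyntheticConfig(n_mice=300, seed=1, allow_edge_truncation=False,
                          within_cluster_fraction=1.0)
    _, _, gt = generate_cohort(cfg)
    durations, peaks, intervals = [], [], []
    for clusters in gt.clusters.values():
        for c in clusters:
            durations.append(c.end_day - c.onset_day + 1)
            peaks.append(max(c.per_day_counts))
        for a, b in zip(clusters, clusters[1:]):
            intervals.append(b.onset_day - a.onset_day)
    for got, want in [(np.mean(durations), cfg.cluster_duration_mean),
                      (np.mean(peaks), cfg.peak_frequency_mean),
                      (np.mean(intervals), cfg.cluster_interval_mean)]:
        assert abs(got - want) / want < 0.10


def test_time_of_day_concentration():
    """Concentrated profile has smaller circular variance than uniform."""
    def circ_var(cfg):
        events, _, _ = generate_cohort(cfg)
        theta = events.t_hours_since_SE.to_numpy() % 24.0 / 24.0 * 2 * np.pi
        return 1.0 - np.abs(np.exp(1j * theta).mean())

    v_conc = circ_var(SyntheticConfig(n_mice=20, seed=9, tod_concentration=2.0))
    v_unif = circ_var(SyntheticConfig(n_mice=20, seed=9, tod_concentration=0.0))
    assert v_conc < v_unif


def test_window_too_short_gives_cluster_free_animal(caplog):
    cfg = SyntheticConfig(
        n_mice=6, seed=2, allow_edge_truncation=False,
        cluster_interval_mean=80.0, cluster_interval_sd=10.0,
        cluster_interval_min=60.0, cluster_interval_max=100.0,
        monitoring_duration_mean=31.0, monitoring_duration_sd=1.0,
        monitoring_duration_min=30.0, monitoring_duration_max=33.0,
    )
    with caplog.at_level(logging.WARNING, logger="srscluster.synthetic"):
        events, windows, gt = generate_cohort(cfg)
    empties = [aid for aid, cl in gt.clusters.items() if not cl]
    assert empties  # some animals hold no cluster
    assert any("holds no cluster" in r.message for r in caplog.records)
    assert not events.animal_id.isin(empties).any()
    assert len(windows) == cfg.n_mice


def test_config_roundtrip_and_validation(tmp_path):
    cfg = SyntheticConfig(n_mice=4, seed=5, tod_concentration=1.5)
    p = tmp_path / "cfg.yaml"
    import yaml

    p.write_text(yaml.safe_dump(cfg.to_dict()))
    assert SyntheticConfig.from_file(p) == cfg
    with pytest.raises(ValueError, match="unknown"):
        SyntheticConfig.from_dict({"not_a_field": 1})
    with pytest.raises(ValueError):
        SyntheticConfig(duration_min=2)
    with pytest.raises(ValueError):
        SyntheticConfig(cluster_interval_mean=5.0, cluster_interval_min=1.0)
    with pytest.raises(ValueError):
        SyntheticConfig(within_cluster_fraction=0.0)


class TestSyntheticEEG:
    def test_no_discharges_is_pure_baseline(self):
        spec = EEGSpec(duration_s=80.0, seed=1)
        trace, truth = generate_eeg(spec)
        assert truth == []
        rms = float(np.sqrt(np.mean(trace**2)))
        assert rms == pytest.approx(spec.baseline_rms, rel=0.05)

    def test_single_discharge_ground_truth(self):
        spec = EEGSpec(duration_s=80.0, seed=2,
                       discharges=(Discharge(30.0, 20.0, 6.0, 3.0),))
        trace, truth = generate_eeg(spec)
        assert truth == [(30.0, 50.0)]
        seg = trace[int(30 * 400):int(50 * 400)]
        seg_rms = float(np.sqrt(np.mean(seg**2)))
        assert seg_rms == pytest.approx(3.0 * spec.baseline_rms, rel=0.05)

    def test_sub_threshold_duration_still_in_ground_truth(self):
        spec = EEGSpec(duration_s=80.0, seed=3,
                       discharges=(Discharge(30.0, 9.5, 6.0, 3.0),))
        _, truth = generate_eeg(spec)
        assert truth == [(30.0, 39.5)]

    def test_overlapping_discharges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            EEGSpec(duration_s=80.0,
                    discharges=(Discharge(10.0, 10.0), Discharge(21.0, 10.0)))

    def test_determinism(self):
        spec = EEGSpec(duration_s=70.0, seed=4,
                       discharges=(Discharge(20.0, 15.0),))
        t1, _ = generate_eeg(spec)
        t2, _ = generate_eeg(spec)
        assert np.array_equal(t1, t2)
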