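# srscluster

Detection and quantification of **spontaneous recurrent seizure (SRS)
clusters** in chronically epileptic rodents, built for long-term (weeks to
months) continuous video-EEG cohorts such as the chronic phase of the mouse
pilocarpine model of temporal lobe epilepsy.

In this model, seizures after status epilepticus (SE, day 0 of the
timeline) do not occur at a steady rate: they arrive in multi-day
*clusters* — unimodal waves of daily seizure counts that rise slowly to a
peak and end rapidly — separated by long seizure-free periods, in a cyclic
pattern. Quantifying that structure matters for anyone designing drug
studies in this model (a short monitoring window can confuse the seizure
cycle with a treatment effect) and for studying ictogenesis itself.

## What it computes

Events are binned into daily counts (days since SE). The operational rules:

- **Electrographic seizure**: a discharge with an amplitude change
  \> 2 × baseline, repetitive spiking at 4–12/s, lasting ≥ 10 s
  (single-channel EEG, 400 Hz, 0.1–70 Hz band).
- **Seizure cluster** (*a*): ≥ 1 seizure/day on ≥ 3 consecutive days with
  ≥ 5 seizures in total. A cluster is **fully monitored** (FM, *a′*) when a
  monitored zero-seizure day flanks it on both sides; clusters cut by the
  monitoring window (*a″*) are kept but excluded from duration-type
  summaries.
- Per cluster: **duration** *d* (days, inclusive), **peak seizure
  frequency** *f* (max daily count), rise (onset → peak day) and fall
  (peak day → end), with rise + fall = *d* − 1.
- Per series: **cluster interval** *c* (onset-to-onset days, both onsets
  observed), **seizure-free period** *e* (zero-seizure days between
  consecutive clusters), seizures outside clusters (*b*) and the
  within-cluster percentage.
- Cohort level: mean ± SD (range) summaries, chronic-phase assignment
  (phase 1: monitoring starts 6–14 weeks post-SE; phase 2: ≥ 15 weeks),
  pooled-variance Student's *t*, paired *t*, and Pearson correlation
  (two-tailed, α = 0.05).

A seeded synthetic-cohort generator produces event tables with known
ground truth (cluster spans, per-event labels) that reproduce this
structure — a renewal process of cluster onsets with truncated-normal
intervals, deterministic unimodal daily-count profiles, per-animal
outside-cluster propensities, and a concentrated within-day (circular)
seizure-time profile — so the whole pipeline is testable end-to-end and
usable for parameter-recovery studies. A synthetic EEG generator embeds
ictal spike discharges in band-limited noise for validating the detector.

## Worked example

```bash
srscluster simulate --n-mice 12 --seed 4 --out sim
srscluster cluster --events sim/events.csv --windows sim/windows.csv --out ana
srscluster report --analysis ana --out table.csv
```

which prints `wrote 1388 events for 12 animals`, then
`30 cluster(s) in 12 animal(s)`, and the summary table contains
(mean ± SD over the cohort):

| metric | value |
| --- | --- |
| cluster_duration_days | 5.74 ± 1.51 (n = 23 FM clusters) |
| cluster_interval_days | 23.14 ± 6.80 (n = 14) |
| seizure_free_days | 17.13 ± 7.11 (n = 16) |
| peak_frequency_per_day | 18.09 ± 5.41 |
| within_cluster_frequency_per_day | 7.88 ± 0.41 |
| within_cluster_pct | 97.72 ± 5.44 (n = 12 animals) |
| rise_days / fall_days | 3.39 / 1.35 |
| clusters_per_animal | 2.50 ± 0.52 |

i.e. the pipeline recovers the generator's configured chronic-phase
structure (duration ≈ 5.7 d, interval ≈ 22.7 d, seizure-free ≈ 16 d, peak
≈ 17/d, ~97% of seizures within clusters, rise > fall) from the event
timestamps alone. The same `cluster`/`report` commands run on any
events/windows CSV pair with columns `animal_id, t_hours_since_SE[, stage]`
and `animal_id, start_day, end_day`. `srscluster detect` runs the
electrographic detector on an EDF or time/value CSV trace, and
`srscluster run` drives everything from one YAML config with full
provenance (config hash, seed, versions) and byte-reproducible outputs.

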