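# Methods

## Scope and data model

The package analyzes recurrent-seizure time series from chronically
epileptic animals monitored by continuous video-EEG. Time is measured from
status epilepticus (SE); day *n* covers hours [24 *n*, 24 (*n* + 1)).
Inputs are per-animal seizure events (hours since SE, optional Racine
stage) and inclusive monitoring windows in integer days. Events carrying a
stage below an optional stage filter (convulsive = stage ≥ 4) are dropped
at binning time; unstaged events are retained.

## Cluster rule and metrics

A candidate run is a maximal block of consecutive monitored days with at
least one seizure each; it is a cluster iff it spans ≥ 3 days and holds
≥ 5 seizures. Both thresholds are exposed as parameters (defaults 3/5) so
threshold sensitivity can be examined; detection is monotone in both.

Operational decisions where the verbal definitions leave room:

- **Fully monitored (FM)**: the day before onset and the day after the end
  are both monitored and seizure-free. This is the only observable
  certificate that onset and end were captured; clusters abutting a window
  edge are never FM.
- **Cluster interval** is onset-to-onset and reported only when the
  earlier onset is observed (the earlier cluster does not start on the
  first monitored day); intervals involving start-truncated clusters are
  excluded from summaries to avoid censoring bias.
- **Seizure-free period**: number of zero days strictly between
  consecutive clusters when the whole gap is seizure-free; otherwise the
  longest zero-run in the gap, flagged "interrupted" and excluded from the
  seizure-free summaries. For a clean gap, interval − earlier duration =
  seizure-free days.
- **Peak day** ties break to the earliest maximal day; rise = peak −
  onset, fall = end − peak, so rise + fall = duration − 1. Day-index
  differences (not inclusive day counts) are used throughout.
- The within-cluster percentage is undefined (reported missing, not zero)
  for an animal without seizures.

## Electrographic seizure detector

Single-channel, time-domain, matching the written criterion (amplitude
\> 2 × baseline, repetitive spiking 4–12/s, ≥ 10 s): non-overlapping 1-s
windows; a window qualifies iff its RMS exceeds the ratio threshold times
baseline **and** its spike count lies in the rate band, where spikes are
local extrema of |x| above the same amplitude threshold with ≥ 40 ms
separation (40 ms < 1/12 s keeps 12/s resolvable). Runs of qualifying
windows are merged across gaps ≤ 2 s and reported iff they span ≥ 10 s,
with onset/offset at window-boundary resolution. Baseline is the median of
per-window RMS (robust while ictal activity occupies a minority of
windows) or the RMS of a declared seizure-free reference segment. The rate
band is applied strictly on both sides: discharges spiking faster than
12/s are rejected, a literal reading of the criterion. An all-zero trace
has no definable baseline and is an error, as is a sampling rate below
twice the upper rate band. The detector formalizes the written rule, not a
reviewer's visual judgment, and does no spectral classification.

## Synthetic cohort generator

The generator is the package's validation instrument: it emulates the
statistical structure of chronic-phase cohorts with full ground truth.
Defaults are the chronic-phase study conditions; all are configurable.

- **Monitoring**: duration ~ N(53.7, 20.4²) truncated to [30, 102] d,
  start ~ N(84.5, 33.7²) truncated to [42, 155] d post-SE, rounded to
  days.
- **Cluster process**: a renewal process of onsets with truncated-normal
  intervals (mean 22.7 d, SD 8.7, range [7, 37]); durations
  N(5.7, 2.0²) rounded to integer days in [3, 11]; per-cluster peak
  frequency N(17.3, 6.5²)/d in [2, 32]; within-cluster mean frequency
  8.0/d; intervals within an animal are assumed independent. Successive
  onsets are kept at least duration + 2 apart so clusters cannot touch.
- **Daily-count profile**: deterministic and unimodal. The peak day index
  is round(rise_fraction · (duration − 1)) with rise_fraction =
  3.4/(3.4 + 1.2) ≈ 0.74 from the observed mean rise and fall times. A
  linear rise from 1 to the peak and fall back to 1 is affinely rescaled
  (interior days clipped to [1, peak − 1], keeping the maximum day strictly
  unique) and rounded by largest remainder to integers summing to
  round(mean_frequency · duration), clamped to the feasible range; every
  generated cluster satisfies the 3-day/5-seizure rule by construction.
- **Outside-cluster seizures**: each animal draws a propensity
  z ~ Beta(5 m, 5 (1 − m)) (clipped at 0.375), and adds
  Poisson(n_in · z/(1 − z)) isolated events on days ≥ 2 days away from
  every cluster boundary, never forming three consecutive event days —
  so isolated events can neither extend nor create a cluster, and the
  ground-truth spans are exactly recoverable. The skewed Beta reflects
  that most animals have essentially all seizures in clusters while a few
  have many strays (per-animal within-percentages of 97 ± 7 with a minimum
  near 62%); a homogeneous isolated rate would instead interrupt almost
  every long gap and bias the recovered seizure-free period far downward.
- **Within-day times**: von Mises on the 24-h circle (default
  concentration κ = 2, peak hour 18:00 — the grouping of seizures within a
  day is reproduced, but no mechanistic circadian/sleep model is implied;
  κ = 0 gives uniform times). Stages are drawn from {4, 5}.
- **Determinism**: all randomness flows from one integer seed through a
  named generator stream per animal; identical configs give identical
  outputs.

### Calibrations

The reported cohort statistics are *observed* quantities — measured
through finite monitoring windows — so the generator solves three small
inverse problems once per configuration (cached), rather than sampling
naively from the printed moments:

1. **Truncated-normal moment matching.** For every truncated distribution
   the location is solved (Brent) so the *truncated* mean equals the
   configured mean.
2. **Interval censoring inversion.** An onset-to-onset interval of length
   x fits inside a window of length W with probability ∝ (W − 1 − x)⁺, so
   observed intervals are length-biased short by ≈ var(x)/(E[W] − E[x])
   (about 1.7 d at the defaults). The interval sampling location is solved
   so the censoring-weighted mean equals the configured interval mean; the
   sampled mean then sits ~8% above the configured value while the
   *recovered* mean matches it. If windows can never hold two onsets the
   calibration falls back to plain moment matching.
3. **Fragment-loss compensation.** A window edge that cuts a cluster
   leaves a fragment that may fail the 3-day/5-seizure rule; its seizures
   are then counted as outside clusters downstream (~2% of in-cluster
   seizures at the defaults). The expected loss is computed by an internal
   fixed-seed span-level simulation (no event sampling), and the Beta mean
   m is set so the observed within-cluster percentage matches the
   configured fraction.

These calibrations are part of the model definition: they depend only on
the configuration, not on the cohort seed, and are deterministic.

### Synthetic EEG

Baseline is band-limited (0.5–70 Hz) Gaussian noise scaled to the target
RMS and soft-limited (tanh) below twice the RMS, so that baseline activity
never crosses the detector's spike threshold and ground truth is
unambiguous. Each discharge is a train of 8-ms Gaussian transients at the
requested rate, placed at (k + ½)/rate from onset so every full 1-s window
inside the discharge holds exactly round(rate) spikes, over a quiet
(0.3 × baseline) background, with the spike train scaled so the segment
RMS is amplitude_ratio × baseline RMS — the same amplitude measure the
detector uses. Discharges must be non-overlapping and separated by more
than the detector's merge gap.

## Cohort statistics

Summaries are mean ± sample SD (n − 1) with range; SD is undefined at
n = 1. Group comparison is the classic pooled-variance Student's *t* (not
Welch), pairs use the paired *t* (degenerate when all differences are
equal), association is Pearson's *r* with its *t*-based p-value; all
two-tailed at α = 0.05, with no multiple-testing correction. Chronic-phase
assignment uses the monitoring **start** day (phase 1: [42, 98] d;
phase 2: ≥ 105 d; the gap and earlier starts are unclassified); end-based
classification would contradict the observed phase-1 windows, which end
slightly past day 98. Cluster-level summary rows (duration, peak, rise,
fall, totals, within-cluster frequency) pool FM clusters across animals;
animal-level rows (within-percentage, overall frequency) use one value per
animal.

## Problem sizes and verification

The test suite verifies the cluster rule against a brute-force oracle on
every counts sequence of length ≤ 8 with entries in {0..3}, seizure-count
conservation, the detector's duration/amplitude/rate boundaries (a 9.5-s
discharge is rejected, 10.0 s accepted; 2× amplitude rejected; 4 and 12/s
accepted, 3 and 15/s rejected), seed determinism, and parameter recovery
on a 300-mouse cohort (±10% on duration/interval/seizure-free/peak, ±2
percentage points on the within-cluster percentage, ±15% on mean
frequency, rise days and clusters per animal — the wider bands absorb
profile-rounding and edge-truncation granularity). The acceptance script
pools ten replicate 300-mouse cohorts (~3 × 10⁵ events, seconds of CPU per
replicate) chosen to make sampling error small relative to those bands.

## Limitations

- The generator reproduces summary structure, not physiology: no
  epileptogenesis dynamics between SE and the chronic stage, no severity
  progression, no sleep staging; the within-day profile is a single fixed
  circular mode. Passing recovery tests shows the pipeline inverts this
  model's structure, not that real cohorts follow the model.
- The detector operates at 1-s onset/offset resolution and applies the
  spike-rate band strictly; discharges spiking faster than 12/s are not
  seizures under this rule.
- EDF input requires the optional `mne` dependency; there is no EDF
  writer, so synthetic traces are exchanged as time/value CSV.
- Interval and seizure-free summaries exclude censored/interrupted cases
  rather than modelling censoring explicitly.
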