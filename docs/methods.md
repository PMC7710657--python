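# Methods

## Data model

An `ActivitySeries` is one subject's contiguous, fixed-width-binned sequence
of non-negative integer counts with a minute-resolution start time. The bin
width must divide 1440 min so that day boundaries always align with bin
edges; this removes every straddling ambiguity in phase assignment. Two
modalities share the container: beam-break locomotion counts from monitor
tubes and foraging-trip events from colony recordings (one trip = one count
in its minute bin). The container has no representation for missing bins:
monitor ingestion rejects files whose timestamps are not uniformly spaced,
naming the first offending line, and the pipeline reports such subjects as
excluded. Nothing is ever imputed, because the autocorrelation analysis
assumes contiguity.

A `LightSchedule` is an entrainment block of 12 h:12 h LD days followed by a
block of DD days, parameterised by the lights-on clock time and the
recording start. Only 12:12 photoperiods are supported. The
timestamp → phase map returns day/night on LD days and subjective
day/subjective night on DD days, the subjective phases obtained by
extrapolating the LD lights-on time into darkness.

### Boundary conventions

- Phase intervals are half-open `[lights_on, lights_off)`: a boundary
  timestamp belongs to the phase it begins. This makes the day/night
  partition exact (per-phase counts sum to the total, integer-exactly).
- Bins wider than 1 min are assigned by their midpoint; because bin edges
  align with day boundaries, a bin can never straddle a phase boundary.
- `slice_phase` additionally requires the schedule to start at lights-on or
  lights-off, so each day's phase slice is one contiguous block and can be
  returned as a valid series. The generator and all shipped examples start
  recordings at lights-on.
- Recording durations default to 5 LD + 5 DD days in the generator; both
  are configuration.

## Rhythm strength

The autocorrelogram uses the biased, mean-centred estimator with the
lag-independent denominator Σ(y−ȳ)²: it guarantees r(0)=1 and |r(k)|≤1, and
makes RS invariant under affine transforms of the counts. It is evaluated
with FFT convolution; an O(N²) direct-sum implementation in the test suite
serves as the independent oracle (agreement to 1e−9).

Analysis always runs on 30-min bins (rebinned from the raw resolution), the
standard granularity for this statistic and the same resolution as the
sleep profile. The circadian peak is the highest *interior local maximum*
of the correlogram within an 18–30 h lag window (window configurable),
falling back to the window maximum when no interior local maximum exists.
This is robust to noisy side-lobes; for clean circadian data it coincides
with the classical "third peak" of the symmetric correlogram. The 95 %
confidence line is 2/√N with N the number of 30-min bins analysed.
RS = peak height ÷ confidence line; RS ≤ 1.5 (boundary inclusive) is
classified arrhythmic. The selected peak's lag is the period estimate; for
an arrhythmic subject that lag is reported but carries no inferential
weight. LD and DD segments are always analysed separately, never pooled. A
zero-variance segment has no defined correlogram and is returned as
arrhythmic with a `degenerate` flag and RS = 0.

The correlogram needs at least twice the maximum lag (default 48 h) of
data, i.e. ≥ 4 days per regime at the defaults.

## Sleep and activity

Sleep scoring requires 1-min bins — a 30-min bin of zero is not evidence of
30 min of continuous immobility — and flags any maximal run of ≥ 5
zero-count minutes as a bout. "Longer than 5 min" is implemented as run
length ≥ 5, following the convention of the insect-sleep proxy literature;
the threshold is a parameter. Episodes are attributed to the phase at bout
start ("episodes initiated"), minutes are split per-minute across phases,
which keeps totals conserved. Mean bout length over a phase with zero bouts
is reported as missing, not zero, to avoid biasing group means. Sleep is
summarised over LD days by default (DD behind a flag), and the 48-bin
time-of-day profile reports mean minutes asleep per 30-min bin across the
analysed days. The summary stores raw summed minutes; the pipeline's
results table divides by the number of analysed days to report per-day
means.

Per-phase activity is total counts in each phase divided by the number of
full days of the corresponding regime; a trailing partial day is excluded
and its length reported.

## Synthetic foragers

The generator is the package's specification of the study conditions it is
validated under. Per-minute counts follow an inhomogeneous Poisson law with
waking rate

    λ(t) = base_rate · d(t) · (1 + amplitude · cos(2π (t − t_peak)/τ)),

where d(t) is a daytime multiplier (`day_rate_factor`, 1.0 for controls)
and the cosine free-runs on elapsed time with period τ (default 24 h),
anchored so the day-0 peak falls at the acrophase clock time (14:00,
mid-photophase, for the shipped presets). Sinusoidal rather than
square-wave modulation is the simplest structure satisfying the
correlogram's assumptions; an LD light-masking multiplier is deliberately
absent by default. Sleep/wake follows a two-state Markov chain with
phase-dependent per-minute onset hazard and geometric bout durations (mean
`mean_bout_min`); sleep fully suppresses counts.

Waking minutes draw from a **zero-truncated** Poisson law by default
(`allow_wake_zeros=False`), so an awake minute always registers ≥ 1 count.
This is a deliberate design choice: with unrestricted Poisson emission, the
probability of a ≥ 5-min accidental zero run while awake is
exp(−Σ₅λ) — non-negligible near the trough of a deep modulation — and
latent sleep could then never be recovered exactly from counts alone. With
truncation, zero runs in the counts *are* the sleep runs, and bout recovery
against ground truth is exact for every seed, which is what makes the sleep
scorer's validation sharp. Setting `allow_wake_zeros=True` restores the
unrestricted law (used where pure-Poisson statistics are wanted, e.g. the
law-of-large-numbers check on the mean rate).

Cohorts derive per-subject seeds from a master seed via a seed sequence, so
any cohort is reproducible bit-for-bit from `(preset, n, seed)`.

### Treatment presets

`control`, `imidacloprid_1`, `imidacloprid_10` (in `presets.yaml`) encode
the qualitative signature of chronic low-dose neonicotinoid exposure in
foragers — progressively weaker modulation depth (0.8 → 0.55 → 0.30),
reduced daytime rate (day factor 1.0 → 0.85 → 0.60), elevated daytime
sleep-onset hazard (0.002 → 0.004 → 0.008 /min) with *unchanged* bout
length (20 min) — i.e. more daytime sleep through more episodes, not longer
ones, alongside degraded rhythm strength. The base rate (2 counts/min
awake) gives ~60 counts per 30-min bin, a realistic beam-break load for an
active forager. These numbers are generator conventions pinned in a
versioned config, not pharmacological measurements; they reproduce effect
*directions*, and no attempt is made to calibrate effect *magnitudes* to
any particular dataset.

### What the generator does and does not emulate

It emulates: circadian rate modulation, phase-dependent sleep pressure,
count noise, free-running DD behaviour, dose-graded degradation. It does
not emulate: light masking, ultradian bouts, inter-individual parameter
heterogeneity within a group, drug-induced immobility as distinct from
sleep (indistinguishable in activity data by construction), colony social
dynamics, or missing-data artefacts. Passing tests therefore demonstrate
correctness of the *analysis* under the stated statistical assumptions, not
fidelity of any biological claim about real recordings.

## Group statistics

Mean ± SEM uses the (n−1)-denominator standard deviation. The omnibus test
is the classical one-way ANOVA (df = k−1, Σn−k) with Tukey HSD pairwise
p-values from the studentized-range distribution, Tukey–Kramer-corrected
for unequal n (scipy implementations behind the module surface; the test
suite checks them against hand sum-of-squares computations). Two-group
comparisons use the pooled-variance Student t (df = n₁+n₂−2) by default —
matching the degrees of freedom conventionally printed for such panels —
with Welch as an option. All tests are two-sided at α = 0.05; arrhythmicity
*proportions* are reported descriptively without a test, and no
multiple-testing layer is added beyond Tukey.

## Numerical and validation choices

- FFT correlogram vs direct-sum oracle: agreement to 1e−9 (measured
  ~1e−15).
- Validation cohort sizes: recovery-rate measurements use 100 seeded
  subjects per condition at 5 LD days; pipeline-level demonstrations use
  n = 20 per group (the scale of typical isolated-forager panels), sizes at
  which the whole suite and the acceptance script each run in about a
  minute.
- The amplitude-graded cohorts used for classification and period-recovery
  validation have sleep hazards set to zero: they isolate the rhythm
  estimator, whose input noise is then purely Poisson. Overlaying stochastic
  sleep bouts jitters the correlogram peak (recovery within ±0.5 h at
  amplitude 0.5 drops to roughly three-quarters of subjects) — a property
  of the harder compound condition, not a defect of the estimator; sleep
  detection is validated separately and exactly against latent ground
  truth.
- Determinism: all stochastic stages take explicit seeds; identical
  configs and seeds give byte-identical result files.

## Known limitations

- Activity data cannot distinguish sleep from drug-induced immobility; the
  sleep metrics quantify prolonged inactivity under a validated proxy.
- Only 12:12 schedules; no dawn/dusk ramps or light-intensity modelling.
- The period estimate's resolution equals the analysis bin width (0.5 h),
  and the default 18–30 h window cannot detect strongly non-circadian
  periods.
- No periodogram (Lomb–Scargle, χ²) or cosinor methods; the correlogram
  statistic is the single rhythmicity measure.
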