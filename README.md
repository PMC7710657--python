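# circabee

Circadian rhythmicity and sleep analysis for bumblebee activity-monitor
data: from raw per-minute activity counts to rhythm-strength statistics,
arrhythmicity classification, sleep-bout metrics, day/night activity
summaries, actograms, and group-level statistics.

The package is aimed at behavioural chronobiologists and ecotoxicologists
who record *Bombus terrestris* (or similar insect) foragers either
individually in locomotor-activity monitor tubes (beam-break counts) or in
whole colonies (foraging-trip event counts), under a 12 h:12 h light:dark
(LD) entrainment block followed by constant darkness (DD). It is equally a
test bed: a seeded synthetic forager generator with known circadian and
sleep structure lets every pipeline stage be validated end to end without
any recordings.

## The statistics at the core

**Rhythm strength (RS).** For counts rebinned to 30-min bins, the
autocorrelogram uses the standard normalised estimator

    r(k) = Σᵢ (yᵢ − ȳ)(yᵢ₊ₖ − ȳ) / Σᵢ (yᵢ − ȳ)² ,   k = 0 … K,

so r(0) = 1 and |r(k)| ≤ 1. The circadian peak is the highest interior
local maximum of r in an 18–30 h lag window; its height divided by the 95 %
white-noise confidence line 2/√N (N = number of bins) is the rhythmicity
statistic,

    RS = r(k̂) · √N / 2 ,   τ̂ = k̂ · Δt.

By convention RS > 1.5 indicates rhythmic behaviour; RS ≤ 1.5 is classified
arrhythmic. LD and DD segments are analysed separately, and the lag of the
selected peak estimates the free-running period τ̂.

**Sleep.** Any maximal run of ≥ 5 consecutive zero-count minutes is one
sleep bout (the conventional insect-sleep proxy; threshold configurable).
An episode is counted in the phase (day/night) where it starts, while its
minutes are apportioned to the phases they occupy, so per-phase minutes sum
exactly to total sleep.

**Phases.** Timestamps map to day/night during LD and, by extrapolating the
lights-on time, to subjective day/subjective night during DD. Intervals are
half-open [lights-on, lights-off).

**Group statistics.** Mean ± SEM per group; one-way ANOVA with Tukey's
multiple comparisons (Tukey–Kramer for unequal n) for ≥ 3 groups, pooled
two-sample t-tests (Welch optional) for 2 groups.

## Worked example

```python
from circabee import (compute_rhythmicity, schedule_for, simulate_forager,
                      split_regimes, treatment_preset)

for preset in ("control", "imidacloprid_10"):
    params = treatment_preset(preset, seed=7)
    series, truth = simulate_forager(params, subject_id=preset)
    ld, dd = split_regimes(series, schedule_for(params))
    r = compute_rhythmicity(ld)
    print(f"{preset}: RS = {r.rs:.2f} ({r.label}), peak at "
          f"{r.estimated_period_hours:.1f} h, N = {r.n_bins}")
```

prints

```
control: RS = 5.17 (rhythmic), peak at 24.0 h, N = 240
imidacloprid_10: RS = 0.52 (arrhythmic), peak at 20.0 h, N = 240
```

The control forager's correlogram peaks near lag 24 h at ~5.2 times the
confidence line, a strong diurnal rhythm; the treated preset's weak
modulation leaves no credible circadian peak (RS ≤ 1.5, and the nominal
"peak" lag is then not a meaningful period estimate). The `examples/`
directory has one short script per capability: simulation + monitor-file
I/O, rhythmicity, sleep scoring, group comparison, and the one-call
pipeline with actograms. A thin CLI mirrors the pipeline
(`circabee simulate | analyze | report`).

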