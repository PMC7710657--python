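"""Rhythm strength (RS) of one forager in LD and in constant darkness.

RS is the circadian autocorrelation peak divided by the 95 % white-noise
confidence line 2/sqrt(N); RS <= 1.5 is classified arrhythmic.
"""

from circabee import (
    compute_rhythmicity,
    schedule_for,
    simulate_forager,
    split_regimes,
    treatment_preset,
)

for preset in ("control", "imidacloprid_10"):
    params = treatment_preset(preset, seed=7)
    series, truth = simulate_forager(params, subject_id=preset)
    schedule = schedule_for(params)
    ld, dd = split_regimes(series, schedule)
    for regime, segment in (("LD", ld), ("DD", dd)):
        r = compute_rhythmicity(segment)
        print(
            f"{preset:16s} {regime}: RS = {r.rs:5.2f} ({r.label}), "
            f"peak at {r.estimated_period_hours:.1f} h, "
            f"confidence line {r.confidence_line:.3f} (N = {r.n_bins})"
        )
# The control forager shows RS well above 1.5 with a ~24 h peak; the treated
# preset's weaker modulation drops RS towards or below the threshold.
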