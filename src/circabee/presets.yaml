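# Treatment presets for the synthetic forager generator.
#
# Numeric values are generator conventions chosen to reproduce the
# qualitative effect directions of chronic neonicotinoid exposure reported
# for bumblebee foragers — weaker rhythm strength, reduced daytime activity,
# more daytime sleep episodes with unchanged episode length — not measured
# pharmacological quantities.  Rates are per-minute hazards; base_rate is
# expected counts per waking minute.
control:
  period_hours: 24.0
  amplitude: 0.8
  base_rate: 2.0
  acrophase_hours: 14.0        # clock time of peak activity (mid-photophase)
  day_rate_factor: 1.0
  sleep_onset_rate_day: 0.002
  sleep_onset_rate_night: 0.012
  mean_bout_min: 20.0
  n_days_ld: 5
  n_days_dd: 5
imidacloprid_1:
  period_hours: 24.0
  amplitude: 0.55
  base_rate: 2.0
  acrophase_hours: 14.0
  day_rate_factor: 0.85
  sleep_onset_rate_day: 0.004
  sleep_onset_rate_night: 0.012
  mean_bout_min: 20.0
  n_days_ld: 5
  n_days_dd: 5
imidacloprid_10:
  period_hours: 24.0
  amplitude: 0.30
  base_rate: 2.0
  acrophase_hours: 14.0
  day_rate_factor: 0.60
  sleep_onset_rate_day: 0.008
  sleep_onset_rate_night: 0.012
  mean_bout_min: 20.0
  n_days_ld: 5
  n_days_dd: 5
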