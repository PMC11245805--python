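# Tobacco-control policies as rate modifiers (see shc.impact.PolicySpec).
# The three built-ins, restated here for reference, plus one custom variant.
TCP1:
  start_year: 2023
  start_rate_change: -0.025   # -2.5% of the starting rate per policy year
  ramp_years: 10              # capped at -25% from year 10 onward
  start_ages: [14, 34]
TCP2:
  start_year: 2023
  stop_rate_change: 0.025     # +2.5% of the stopping rate per policy year
  ramp_years: 10
  stop_ages: [25, 100]
TCP3:
  start_year: 2023
  cohort_ban_birth_year: 2009  # no initiation for cohorts born since 2009
aggressive_cessation:
  start_year: 2025
  stop_rate_change: 0.05
  ramp_years: 10
  stop_ages: [25, 100]
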