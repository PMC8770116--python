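# Built-in mouthing exposure scenarios (editable copy).
# Durations are day-averaged min/h; active_hours_per_day converts to min/d.
scenarios:
  - age_group: 3_to_6_months
    percentile: average
    bw_kg: 7.4
    duration_pacifier_min_h: 3.4
    duration_doll_min_h: 0.5
    active_hours_per_day: 24.0
  - age_group: 3_to_6_months
    percentile: p99
    bw_kg: 7.4
    duration_pacifier_min_h: 37.3
    duration_doll_min_h: 2.5
    active_hours_per_day: 24.0
  - age_group: 2_to_3_years
    percentile: average
    bw_kg: 13.8
    duration_pacifier_min_h: 1.8
    duration_doll_min_h: 0.4
    active_hours_per_day: 24.0
  - age_group: 2_to_3_years
    percentile: p99
    bw_kg: 13.8
    duration_pacifier_min_h: 46.3
    duration_doll_min_h: 2.9
    active_hours_per_day: 24.0
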