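# Null preset: no reward modulation (all cues share the Medium parameters).
# Used for type-I error checks of the choking analysis.
cues:
  Small: &base
    ballistic_fraction: 0.93
    ballistic_duration: 300.0
    n_corrections_mean: 1.1
    correction_duration: 170.0
    endpoint_noise_sd: 3.0
    false_start_hazard: 0.03
    delay_drift_hazard: 0.03
    hold_drift_hazard: 0.02
    overshoot_hazard: 0.17
  Medium: *base
  Large: *base
  Jackpot: *base
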