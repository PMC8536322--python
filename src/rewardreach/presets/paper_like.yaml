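# Generator preset emulating the published behavioral signatures:
# ballistic shortening and homing slowing graded with reward, overshoot-heavy
# Small failures, undershoot-heavy Jackpot failures (inverted-U success).
# Mirrors rewardreach.synth.paper_like_params(); usable as a run-config block:
#   data: {synthetic: {cues: <contents of 'cues'>, n_trials: 2000, seed: 1}}
cues:
  Small:
    ballistic_fraction: 0.97
    ballistic_duration: 280.0
    n_corrections_mean: 1.2
    correction_duration: 150.0
    endpoint_noise_sd: 3.0
    false_start_hazard: 0.03
    delay_drift_hazard: 0.03
    hold_drift_hazard: 0.02
    overshoot_hazard: 0.28
  Medium:
    ballistic_fraction: 0.93
    ballistic_duration: 300.0
    n_corrections_mean: 1.1
    correction_duration: 170.0
    endpoint_noise_sd: 3.0
    false_start_hazard: 0.03
    delay_drift_hazard: 0.03
    hold_drift_hazard: 0.02
    overshoot_hazard: 0.17
  Large:
    ballistic_fraction: 0.90
    ballistic_duration: 320.0
    n_corrections_mean: 1.5
    correction_duration: 190.0
    endpoint_noise_sd: 3.0
    false_start_hazard: 0.03
    delay_drift_hazard: 0.03
    hold_drift_hazard: 0.02
    overshoot_hazard: 0.07
  Jackpot:
    ballistic_fraction: 0.80
    ballistic_duration: 340.0
    n_corrections_mean: 1.0
    correction_duration: 220.0
    endpoint_noise_sd: 3.0
    false_start_hazard: 0.05
    delay_drift_hazard: 0.03
    hold_drift_hazard: 0.02
    overshoot_hazard: 0.02
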