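name: UA
light_cycle:
  lights_off_clock: 12.0
  dark_duration: 12.0
access:
  mode: unlimited
  window_start_offset: 0.0
  window_duration: 0.0
stages:
- stage_id: 0
  kind: magazine
  sd: null
  iti:
  - 4.0
  - 8.0
  - 16.0
  - 32.0
  limited_hold: 2.0
  timeout: 5.0
  houselight_on_timeout: true
  punish_incorrect: true
  eat_interval: 0.0
  fixed_trial_quota: 50
  criterion: null
- stage_id: 1
  kind: five_lit
  sd: unbounded
  iti: null
  limited_hold: 2.0
  timeout: 5.0
  houselight_on_timeout: true
  punish_incorrect: true
  eat_interval: 5.0
  fixed_trial_quota: 50
  criterion: null
- stage_id: 2
  kind: single_cue_untimed
  sd: unbounded
  iti: 5.0
  limited_hold: 2.0
  timeout: 5.0
  houselight_on_timeout: true
  punish_incorrect: false
  eat_interval: 5.0
  fixed_trial_quota: null
  criterion:
    window_len: 20
    min_started: 50
    accuracy_gt: 80.0
    omission_lt: 20.0
    correct_alt_gt: 200
- stage_id: 3
  kind: sd_limited
  sd: 16.0
  iti: 5.0
  limited_hold: 2.0
  timeout: 5.0
  houselight_on_timeout: true
  punish_incorrect: true
  eat_interval: 5.0
  fixed_trial_quota: null
  criterion:
    window_len: 20
    min_started: 50
    accuracy_gt: 80.0
    omission_lt: 20.0
    correct_alt_gt: 200
- stage_id: 4
  kind: sd_limited
  sd: 8.0
  iti: 5.0
  limited_hold: 2.0
  timeout: 5.0
  houselight_on_timeout: true
  punish_incorrect: true
  eat_interval: 5.0
  fixed_trial_quota: null
  criterion:
    window_len: 20
    min_started: 50
    accuracy_gt: 80.0
    omission_lt: 20.0
    correct_alt_gt: 200
- stage_id: 5
  kind: sd_limited
  sd: 4.0
  iti: 5.0
  limited_hold: 2.0
  timeout: 5.0
  houselight_on_timeout: true
  punish_incorrect: true
  eat_interval: 5.0
  fixed_trial_quota: null
  criterion:
    window_len: 20
    min_started: 50
    accuracy_gt: 80.0
    omission_lt: 20.0
    correct_alt_gt: 200
- stage_id: 6
  kind: sd_limited
  sd: 2.0
  iti: 5.0
  limited_hold: 2.0
  timeout: 5.0
  houselight_on_timeout: true
  punish_incorrect: true
  eat_interval: 5.0
  fixed_trial_quota: null
  criterion:
    window_len: 20
    min_started: 50
    accuracy_gt: 80.0
    omission_lt: 20.0
    correct_alt_gt: 200
- stage_id: 7
  kind: sd_limited
  sd: 1.5
  iti: 5.0
  limited_hold: 2.0
  timeout: 5.0
  houselight_on_timeout: true
  punish_incorrect: true
  eat_interval: 5.0
  fixed_trial_quota: null
  criterion:
    window_len: 20
    min_started: 50
    accuracy_gt: 80.0
    omission_lt: 20.0
    correct_alt_gt: 200
- stage_id: 8
  kind: sd_limited
  sd: 1.0
  iti: 5.0
  limited_hold: 2.0
  timeout: 5.0
  houselight_on_timeout: true
  punish_incorrect: true
  eat_interval: 5.0
  fixed_trial_quota: null
  criterion:
    window_len: 20
    min_started: 50
    accuracy_gt: 80.0
    omission_lt: 20.0
    correct_alt_gt: 200
- stage_id: 9
  kind: sd_limited
  sd: 1.0
  iti: 5.0
  limited_hold: 2.0
  timeout: 5.0
  houselight_on_timeout: true
  punish_incorrect: true
  eat_interval: 5.0
  fixed_trial_quota: null
  criterion:
    window_len: 20
    min_started: 50
    accuracy_gt: 80.0
    omission_lt: 20.0
    correct_alt_gt: 200
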