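{
  "label": "theophylline_60-70_iv",
  "drug": "theophylline",
  "dose_mg": 200,
  "route": "iv_infusion",
  "infusion_duration_h": 0.5,
  "n_subjects": 10,
  "age_min": 60,
  "age_max": 70,
  "sampling_times_h": [
    0,
    0.25,
    0.5,
    0.75,
    1,
    1.5,
    2,
    3,
    4,
    6,
    8,
    12,
    16,
    24,
    30,
    36,
    42,
    48
  ],
  "n_trials": 10,
  "seed": 0
}
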