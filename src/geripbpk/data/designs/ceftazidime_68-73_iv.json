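{
  "label": "ceftazidime_68-73_iv",
  "drug": "ceftazidime",
  "dose_mg": 1000,
  "route": "iv_infusion",
  "infusion_duration_h": 1.0,
  "n_subjects": 5,
  "age_min": 68,
  "age_max": 73,
  "sampling_times_h": [
    0,
    0.25,
    0.5,
    0.75,
    1.0,
    1.25,
    1.5,
    2,
    2.5,
    3,
    4,
    6,
    8,
    10,
    12,
    16,
    20,
    24
  ],
  "n_trials": 10,
  "seed": 0
}
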