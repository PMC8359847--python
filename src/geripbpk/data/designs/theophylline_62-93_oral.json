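{
  "label": "theophylline_62-93_oral",
  "drug": "theophylline",
  "dose_mg": 157.8,
  "route": "oral",
  "n_subjects": 6,
  "age_min": 62,
  "age_max": 93,
  "n_doses": 8,
  "dosing_interval_h": 12.0,
  "sampling_times_h": [
    0,
    0.5,
    1,
    1.5,
    2,
    3,
    4,
    6,
    8,
    10,
    12
  ],
  "n_trials": 10,
  "seed": 0
}
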