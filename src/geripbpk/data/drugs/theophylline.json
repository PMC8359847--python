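{
  "name": "theophylline",
  "molecular_weight": 180.16,
  "log_p": 0.0,
  "compound_class": "acid",
  "pka": [
    8.8
  ],
  "fu_plasma": 0.6,
  "blood_to_plasma": 0.83,
  "kp_scalar": 0.885013,
  "absorption": {
    "fa": 1.0,
    "ka": 1.5,
    "lag": 0.0
  },
  "elimination": [
    {
      "kind": "enzymatic",
      "enzyme": "CYP1A2",
      "clint_per_pmol": 0.026
    }
  ],
  "vss_literature": 0.45,
  "provenance": {
    "log_p": "literature octanol:water -0.02",
    "pka": "weak acid (xanthine N-H)",
    "fu_plasma": "literature ~40% bound",
    "blood_to_plasma": "literature B:P 0.83",
    "absorption": "complete oral absorption, fa ~1",
    "elimination": "retrograde IVIVE from adult plasma clearance ~0.04 L/h/kg x 60 kg with CYP1A2-mediated fraction ~0.8, at Chinese adult liver ~1200 g, CYP1A2 42 pmol/mg, MPPGL 40 mg/g",
    "kp_scalar": "solved so reference-subject Vss equals vss_literature",
    "vss_literature": "literature Vss ~0.45 L/kg"
  }
}
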