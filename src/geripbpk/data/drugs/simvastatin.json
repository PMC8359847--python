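{
  "name": "simvastatin",
  "molecular_weight": 418.57,
  "log_p": 4.68,
  "compound_class": "neutral",
  "pka": [],
  "fu_plasma": 0.02,
  "blood_to_plasma": 0.56,
  "kp_scalar": 0.021244,
  "absorption": {
    "fa": 0.6,
    "ka": 1.0,
    "lag": 0.0
  },
  "elimination": [
    {
      "kind": "enzymatic",
      "enzyme": "CYP3A4",
      "clint_per_pmol": 108.0
    }
  ],
  "vss_literature": 4.0,
  "provenance": {
    "molecular_weight": "PubChem (lactone)",
    "log_p": "literature octanol:water, lactone",
    "fu_plasma": "literature plasma protein binding ~98%",
    "blood_to_plasma": "literature B:P for statin lactones",
    "absorption.fa": "fa x fg product; oral bioavailability ~5% with high hepatic extraction implies fa.fg ~0.6",
    "elimination": "retrograde IVIVE: oral bioavailability ~3% with fa.fg ~0.6 implies hepatic extraction ~0.95; back-calculated at adult liver 1350 g, hepatic blood flow 90 L/h, CYP3A4 137 pmol/mg, MPPGL 40 mg/g",
    "kp_scalar": "solved so reference-subject Vss equals vss_literature",
    "vss_literature": "literature/model-matched steady-state volume"
  }
}
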