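{
  "name": "midazolam",
  "molecular_weight": 325.77,
  "log_p": 3.53,
  "compound_class": "base",
  "pka": [
    6.2
  ],
  "fu_plasma": 0.032,
  "blood_to_plasma": 0.66,
  "kp_scalar": 0.047675,
  "absorption": {
    "fa": 0.5,
    "ka": 1.5,
    "lag": 0.0
  },
  "elimination": [
    {
      "kind": "enzymatic",
      "enzyme": "CYP3A4",
      "clint_per_pmol": 3.04
    }
  ],
  "vss_literature": 1.0,
  "provenance": {
    "log_p": "literature octanol:water",
    "pka": "weak base, benzodiazepine ring nitrogen",
    "fu_plasma": "literature ~97% bound",
    "blood_to_plasma": "literature B:P 0.66",
    "absorption.fa": "fa x fg product; fg ~0.5 from gut-wall CYP3A extraction, fa ~1",
    "absorption.ka": "first-order ka matched to adult clinical oral profiles (tmax ~0.5-1 h, Cmax ~75-120 ug/L at 15 mg)",
    "elimination": "retrograde IVIVE from adult IV plasma clearance ~25 L/h (medium extraction) at adult liver 1350 g, hepatic blood flow 90 L/h, CYP3A4 137 pmol/mg, MPPGL 40 mg/g",
    "kp_scalar": "solved so reference-subject Vss equals vss_literature",
    "vss_literature": "literature Vss ~1 L/kg"
  }
}
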