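{
  "name": "vancomycin",
  "molecular_weight": 1449.3,
  "log_p": -3.1,
  "compound_class": "zwitterion",
  "pka": [
    2.2,
    8.9
  ],
  "fu_plasma": 0.6,
  "blood_to_plasma": 0.66,
  "kp_scalar": 2.448988,
  "elimination": [
    {
      "kind": "renal",
      "clr_ref": 6.5,
      "gfr_ref": 121.0
    }
  ],
  "vss_literature": 0.5,
  "provenance": {
    "log_p": "literature, large hydrophilic glycopeptide",
    "pka": "carboxyl (acidic) and amine (basic) groups",
    "fu_plasma": "literature ~30-55% bound",
    "blood_to_plasma": "limited red-cell partitioning",
    "elimination": "healthy-adult clearance ~100-110 mL/min, predominantly glomerular filtration, scaled in proportion to GFR",
    "kp_scalar": "solved so reference-subject Vss equals vss_literature",
    "vss_literature": "literature Vss ~0.4-0.7 L/kg"
  }
}
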