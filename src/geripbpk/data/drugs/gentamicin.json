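{
  "name": "gentamicin",
  "molecular_weight": 477.6,
  "log_p": -3.1,
  "compound_class": "base",
  "pka": [
    8.2
  ],
  "fu_plasma": 0.9,
  "blood_to_plasma": 0.6,
  "kp_scalar": 0.250748,
  "elimination": [
    {
      "kind": "renal",
      "clr_ref": 7.2,
      "gfr_ref": 121.0
    }
  ],
  "vss_literature": 0.27,
  "provenance": {
    "log_p": "literature, polar aminoglycoside",
    "pka": "aggregate amino-group basicity",
    "fu_plasma": "literature <10-30% bound",
    "blood_to_plasma": "limited red-cell partitioning",
    "elimination": "aminoglycoside clearance tracks creatinine clearance (~120 mL/min healthy adult), glomerular filtration without active secretion",
    "kp_scalar": "solved so reference-subject Vss equals vss_literature",
    "vss_literature": "literature Vss ~0.25-0.3 L/kg (extracellular)"
  }
}
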