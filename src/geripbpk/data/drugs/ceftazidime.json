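{
  "name": "ceftazidime",
  "molecular_weight": 546.58,
  "log_p": -1.6,
  "compound_class": "acid",
  "pka": [
    2.8
  ],
  "fu_plasma": 0.85,
  "blood_to_plasma": 0.55,
  "kp_scalar": 0.774796,
  "elimination": [
    {
      "kind": "renal",
      "clr_ref": 7.5,
      "gfr_ref": 121.0
    }
  ],
  "vss_literature": 0.23,
  "provenance": {
    "log_p": "literature, hydrophilic cephalosporin",
    "pka": "carboxylic acid",
    "fu_plasma": "literature ~10-20% bound",
    "blood_to_plasma": "plasma-restricted (no red-cell partitioning)",
    "elimination": "healthy-adult clearance ~125 mL/min, essentially all renal without active secretion, scaled in proportion to GFR",
    "kp_scalar": "solved so reference-subject Vss equals vss_literature",
    "vss_literature": "literature Vss ~0.23 L/kg (extracellular)"
  }
}
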