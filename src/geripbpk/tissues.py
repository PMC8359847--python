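"""Reference tissue data for the whole-body PBPK model.

Two tables live here:

* fractional organ volumes (L per kg body weight, assuming unit tissue
  density) and regional blood-flow fractions (fraction of cardiac output)
  for a reference human.  Each virtual subject rescales them to its own
  body weight and cardiac output; liver and kidney volumes are then
  overridden by the subject's calibrated organ weights and the residual
  "rest" compartment closes the volume balance.
* tissue composition (fractional water / lipid / phospholipid content,
  acidic-phospholipid concentration and tissue:plasma protein ratios)
  used by the tissue-composition partition-coefficient method.

Values are standard published reference-human numbers; they are
configuration data, not fitted quantities.
"""

from __future__ import annotations

# Compartment order used throughout the engine (lung is in series with
# cardiac output; "blood" is the carrier, split venous:arterial 2:1).
TISSUES = [
    "lung", "adipose", "bone", "brain", "gut", "heart",
    "kidney", "liver", "muscle", "skin", "spleen", "rest",
]

#: non-lung perfused compartments (flow fractions over these sum to 1)
PERFUSED = [t for t in TISSUES if t != "lung"]

#: fraction of body weight (≈ L/kg at density ~1 kg/L)
VOLUME_FRACTION = {
    "lung": 0.0076,
    "adipose": 0.2142,
    "bone": 0.0856,
    "brain": 0.0200,
    "gut": 0.0171,
    "heart": 0.0047,
    "kidney": 0.0044,   # overridden by calibrated kidney weight
    "liver": 0.0257,    # overridden by calibrated liver weight
    "muscle": 0.4000,
    "skin": 0.0371,
    "spleen": 0.0026,
    "rest": 0.0330,     # placeholder; recomputed to close the balance
    "blood": 0.0771,
}

#: fraction of cardiac output; liver entry is the hepatic artery only.
#: Portal inflow (gut + spleen outflow) brings total liver inflow to the
#: hepatic_flow_fraction of the population spec (default 0.245).
FLOW_FRACTION = {
    "adipose": 0.050,
    "bone": 0.050,
    "brain": 0.120,
    "gut": 0.160,
    "heart": 0.040,
    "kidney": 0.190,
    "liver": 0.065,
    "muscle": 0.170,
    "skin": 0.050,
    "spleen": 0.020,
    "rest": 0.085,
}

#: mean body density, kg/L
BODY_DENSITY = 1.05

#: haematocrit used for blood-cell partition bookkeeping
HEMATOCRIT = 0.45

#: venous fraction of total blood volume (arterial gets the rest)
VENOUS_FRACTION = 2.0 / 3.0

# ---------------------------------------------------------------------------
# Tissue composition for the partition-coefficient method.
# Columns: f_ew extracellular water, f_iw intracellular water,
# f_nl neutral lipid, f_np neutral phospholipid (all volume fractions),
# ap acidic phospholipid (mg/g), alb_ratio and lipo_ratio tissue:plasma
# albumin / lipoprotein concentration ratios.
# ---------------------------------------------------------------------------
COMPOSITION = {
    #            f_ew    f_iw    f_nl     f_np     ap     alb     lipo
    "adipose": (0.135, 0.017, 0.8530, 0.0016, 0.40, 0.049, 0.068),
    "bone":    (0.100, 0.346, 0.0170, 0.0017, 0.67, 0.100, 0.050),
    "brain":   (0.162, 0.620, 0.0510, 0.0565, 0.40, 0.048, 0.041),
    "gut":     (0.282, 0.475, 0.0487, 0.0163, 2.41, 0.158, 0.0324),
    "heart":   (0.320, 0.456, 0.0115, 0.0166, 2.25, 0.157, 0.0305),
    "kidney":  (0.273, 0.483, 0.0207, 0.0162, 5.03, 0.130, 0.0300),
    "liver":   (0.161, 0.573, 0.0348, 0.0252, 4.56, 0.086, 0.0463),
    "lung":    (0.336, 0.446, 0.0220, 0.0128, 3.91, 0.212, 0.0339),
    "muscle":  (0.118, 0.630, 0.0100, 0.0072, 1.53, 0.064, 0.0252),
    "skin":    (0.382, 0.291, 0.0284, 0.0111, 1.32, 0.277, 0.0960),
    "spleen":  (0.207, 0.579, 0.0077, 0.0113, 3.18, 0.097, 0.0270),
    # "rest of body" approximated with muscle-like composition
    "rest":    (0.118, 0.630, 0.0100, 0.0072, 1.53, 0.064, 0.0252),
}

#: blood-cell composition used to back out acidic-phospholipid affinity
BLOOD_CELL = {
    "f_iw": 0.603,
    "f_nl": 0.0017,
    "f_np": 0.0029,
    "ap": 0.5,       # mg/g
    "ph": 7.22,
}

#: plasma neutral lipid / phospholipid fractions
PLASMA = {"f_nl": 0.0023, "f_np": 0.0013}

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
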