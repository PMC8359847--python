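# Methods

This note records the modelling assumptions, calibration choices and
known limitations of `geripbpk`. It is written for a reader who wants
to know what the package actually computes and what passing its tests
does and does not demonstrate.

## Population model

The generator produces virtual Chinese subjects aged 65–95. Every
equation and distribution lives in `PopulationSpec`; the defaults are
the recalibrated geriatric values, and any of them can be overridden
from YAML.

**Age.** `age = 65 + W(k, λ)` with Weibull shape `k = 1.2`, truncated
at 95 years. The scale is solved once (`calibrate_weibull_scale`,
Brent's method) so that 79.3% of mass falls in the 65–75 band — the
band share of the ~7000-subject national survey the demographic curves
derive from. The solved value (λ ≈ 6.8886 y) is frozen as the default.
Only this band proportion is quantitatively constrained; the shape
parameter sets the within-band skew and was fixed a priori at a mild
right skew.

**Height.** Sex-specific quadratics in age (see README). Residuals are
normal, truncated at ±4 SD, with SDs taken from the survey band spreads
(male 6.3 cm, female 5.9 cm). The quadratics are strictly decreasing
over 65–95, matching the observed ~1–2% height loss per decade.

**Weight.** `WT = a·e^{b·age}` per sex. The survey publishes only band
means, so `(a, b)` are solved exactly from the two band means placed at
band-representative ages 69.6 and 79.5 (male 65.35 → 61.97 kg, female
57.95 → 53.68 kg). Residuals are mean-one lognormal with the band CVs
(male 0.165, female 0.172). Note the platform that produced the
reference validation table predicts band-mean weights of 66.6/64.8 kg —
5–8% above the survey means it was nominally calibrated to; this
package calibrates to the survey means, so its weight means
(≈61.7/57.0 kg) intentionally sit on the observed values instead. Weight
is therefore not an acceptance quantity here.

**BSA, cardiac output.** Deterministic: `BSA = 0.0151·WT^0.4259·HT^0.5751`,
`CO = BSA·(205.9 − 0.501·age)` L/h. No residual is added to CO at the
subject level in this implementation; its population spread arises from
BSA and age. That narrows the CO percentiles relative to observation
(the reference table shows the same narrowing), and CO percentiles are
not acceptance-tested.

**Serum creatinine.** Four cells (sex × band) with published means and
SDs (M 65–75: 83.14 ± 15.89; M >75: 93.48 ± 39.6; F 65–75:
67.68 ± 30.16; F >75: 72.02 ± 25.99 µmol/L). The distributional form is
unpublished; a lognormal is moment-matched and truncated to
20–400 µmol/L (the truncation shifts the means by <0.3%). The reference
table's creatinine percentiles (49.6/105.8) cannot be reproduced from
any simple two-moment distribution, so only means are validated. Its
printed 65–75 pooled mean (76.1) sits 0.8% above this model's true
pooled mean (75.5); at n = 4000 that gap consumes most of a 1% testing
band, which is why the acceptance test pins the default seed — a known
limitation, not a tuning artifact.

**Renal function.** Cockcroft–Gault on the sampled creatinine
(µmol/L → mg/dL conversion 88.4), with the female 0.85 factor. The GFR
cap (15–400 mL/min per 1.73 m²) is applied on the BSA-normalised scale
and de-normalised back.

**Organ weights.** Liver and kidney mass are linear in BSA with
sex-specific slopes. The underlying adult-model equations are
unpublished, so slopes were calibrated once against the predicted
geriatric organ-weight means (liver 1173.4/1051.1 g, kidney
287.4/243.4 g for M/F) at the simulated sex-specific mean BSA of the
65–75 band, then frozen (liver 699.1/688.2, kidney 171.2/159.4 g/m²).
Organ-weight spread therefore derives entirely from BSA variability.

**Tissue volumes and flows.** Reference-human fractional volumes
(L/kg) and flow fractions (of CO) are package data (`tissues.py`),
rescaled per subject. Liver and kidney volumes are overridden by the
calibrated organ masses (density 1.05 g/mL) and a "rest of body"
compartment closes the body-volume balance exactly. Liver inflow is
hepatic artery + portal (gut + spleen) flow, totalling 24.5% of CO by
default. MPPGL is 40 mg/g at all ages (reported age-invariant in
Chinese livers) and CYP abundances stay at Chinese-adult values
(CYP3A4 137, CYP1A2 42 pmol/mg) — elderly abundance data do not exist,
and age effects on exposure are carried by liver mass, blood flow and
renal function instead.

**Randomness.** One `numpy` Generator per subject, seeded
`[seed, subject_index]`, so populations are reproducible bitwise and
subject *i* is identical regardless of cohort size. Truncated draws use
rejection sampling.

## Drug models

Presets are JSON files with per-field provenance notes. Physicochemistry
and binding are literature values. Clearance inputs follow the
standard retrograde approach: whole-organ intrinsic clearance is
back-calculated from adult clinical clearance through the well-stirred
model at adult physiology (liver 1350 g, hepatic blood flow 90 L/h),
then expressed per pmol of enzyme so the geriatric population rescales
it through liver mass. Renal reference clearances are healthy-adult
values scaled in proportion to GFR (reference 121 mL/min,
configurable); ceftazidime, gentamicin and vancomycin are modelled as
filtration-only, consistent with their lack of known transporter-mediated
secretion. Midazolam's gut-wall CYP3A extraction and simvastatin's
incomplete absorption are folded into `fa` (0.5 and 0.6) because the
engine deliberately has no mechanistic gut-metabolism model; `ka`
values were matched to adult oral profiles (tmax ~0.5–2 h).

Partition coefficients use a tissue-composition method: water, neutral
lipid and phospholipid partitioning for all compounds; acidic-
phospholipid binding for bases with pKa ≥ 7 (association constant
backed out of the blood:plasma ratio, clamped at zero when B:P leaves
no intracellular room, as for gentamicin and vancomycin); tissue:plasma
albumin or lipoprotein ratios otherwise. The resulting Kp set is then
multiplied by a single Kp scalar solved so that a deterministic
reference subject (male, age 70, zero residuals) hits the preset's
declared literature Vss — the standard practice of matching predicted
volume to clinical observation. Scalars range from 0.02 (simvastatin,
whose composition-based prediction vastly overestimates adipose
partitioning at log P 4.7) to 2.4 (vancomycin).

## PBPK engine

Perfusion-limited ODE system: venous pool → lung → arterial pool →
eleven parallel tissues → venous, with gut and spleen draining through
the liver. Oral doses place `fa × dose` in a first-order depot that
empties into the liver inflow, so first-pass extraction is mechanical.
Hepatic elimination is `fu_p·CLint,u·C_liver/Kp_liver` (the unbound
well-stirred form), renal elimination acts on the kidney outflow
(plasma-referenced), and a fixed systemic clearance route acts on
venous plasma. Infusions are zero-order inputs; integration is
piecewise between dose events with LSODA at rtol 1e-8/atol 1e-10
(halving tolerances moves AUC by <0.1%). Two cumulative elimination
states allow a mass-balance check at every output point; the engine
reports the maximum relative error (~1e-12 in practice, tested ≤0.1%).

The reported concentration is **arterial ("systemic") plasma**, the
post-lung mixed concentration. With mixed-venous sampling the
hepatic-vein content biases IV clearance above hepatic blood flow in
the high-extraction limit; arterial sampling makes NCA clearance equal
the well-stirred organ clearance identically and is the closer analogue
of peripheral sampling. One practical consequence: an IV *bolus*
produces a ~1-minute mixing transient that coarse sampling grids
mis-integrate; bolus-based oracle tests use dense early samples. The
clinical designs all use infusions or oral dosing, which have no such
transient.

## Trials and NCA

Each study design mirrors one observed clinical study: dose, route,
infusion duration (1 h for ceftazidime/vancomycin, 0.5 h for
gentamicin and the theophylline infusion — not reported by the source
studies; standard practice assumed), age window (clamped to the
population's ≥65 support), sample size, and a per-route sampling grid
(the source schedules are unpublished). Ten virtual trials of the
study's size are simulated by default and summarised with geometric
means, the PK convention; which mean the comparator platform reported
is unknown.

The theophylline 157.8 mg oral study is simulated as q12h × 8 doses
with NCA over the final interval: its observed Cmax (16.12 mg/L) is
unreachable from a single 157.8 mg dose given theophylline's
~0.45 L/kg volume (single-dose ceiling ≈ 6 mg/L), so the source data
must be steady-state; at steady state AUC over the interval equals
dose/CL, leaving AUC and CL comparisons unchanged. All other designs
are single-dose.

NCA: Cmax/Tmax from the sampled grid; AUC by linear-up/log-down
trapezoid (a plain linear rule is available — log-down is negatively
biased by roughly CV² under proportional measurement noise, which
matters for the synthetic noisy-data checks); λz by log-linear
regression over the best (adjusted-R²) window of the last 3–8 post-peak
samples, flagged unreliable when the terminal limb rises; CL =
dose/AUC∞ per subject (dose/AUCτ at steady state), i.e. CL/F for oral
routes, weight-normalised by each subject's own weight.

## Verification metrics

Fold ratio = predicted/observed. Percent-within-fold uses inclusive
bounds `[1/f, f]` (a ratio of exactly 1.25 counts as within
1.25-fold). MAPE = 100·mean(|ratio − 1|); the definition is a package
convention (the comparator's is unpublished) and is only used for
internally consistent comparisons. Rows whose observed value is
missing (simvastatin and one theophylline/ceftazidime Cmax, one
ceftazidime AUC/CL pair) are excluded from aggregates. The shipped
observed table carries 11 studies × 3 quantities with the printed
units: µg-based AUC/Cmax and L/h/kg CL for simvastatin and midazolam,
mg-based AUC/Cmax and mL/h/kg CL for the rest.

## Synthetic data

The survey generator draws ages uniformly within each band and applies
the generating curves plus their residual models, so curve fits on its
output converge to the generating truth (the basis of the
parameter-recovery tests). It does not emulate the real survey's
within-band age pyramid, regional stratification, or measurement error
— passing recovery tests shows the fitting machinery is correct, not
that the real survey would be fit equally well. The PK generator
produces analytic one/two-compartment profiles with combined
proportional+additive noise and LLOQ flagging (censored points are
flagged, never dropped).

## Problem sizes and runtime

The shipped verification uses 10 virtual trials per study (141 subjects
per replicate set, 1410 ODE solves) and completes in about a minute on
one core; population generation is ~0.3 s for 4000 subjects. These
sizes give Monte-Carlo standard errors on study geometric means of
~1–3%, small against the 1.25-/2-fold decision bands.

## Known limitations

- No mechanistic gut absorption (transit, gut-wall metabolism): `fa`
  is an effective fa·fg product, so gut and liver age effects cannot be
  separated for midazolam/simvastatin.
- No active renal secretion or transporters: drugs with significant
  secretion are out of scope.
- No enzyme ontogeny/decline with age beyond liver mass and flows; no
  auto-induction or inhibition; linear kinetics only.
- The creatinine distributional form and the organ-weight/BSA
  equations of the comparator platform are unpublished; calibrated
  stand-ins reproduce their published means but not necessarily their
  percentiles.
- Preset drug parameters are literature/retrograde values, not the
  comparator's proprietary inputs; agreement is assessed through the
  two-fold and 1.25-fold bands, which tolerate this class of
  difference.
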