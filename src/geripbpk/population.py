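"""Virtual Chinese geriatric population generation.

Samples virtual subjects aged 65 and above from recalibrated demographic
and physiological equations: a truncated Weibull age distribution, sex-
specific quadratic height-vs-age and exponential weight-vs-age curves, a
power-law body surface area, an age-declining cardiac output, sex- and
age-band-specific serum creatinine distributions, Cockcroft-Gault
creatinine clearance with a BSA-normalised GFR cap, and BSA-proportional
liver and kidney weights.  Downstream tissue volumes and regional blood
flows are reference-human fractions rescaled to each subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq

from . import tissues as T

Sex = Literal["M", "F"]

#: age-band labels used for serum creatinine and reporting
BAND_LOW = "65-75"
BAND_HIGH = ">75"


def age_band(age: float) -> str:
    """Assign an age to a band; the boundary age 75 goes to the lower band."""
    return BAND_LOW if age <= 75.0 else BAND_HIGH


def normalize_sex(sex: str) -> Sex:
    s = str(sex).strip().upper()[:1]
    if s not in ("M", "F"):
        raise ValueError(f"unknown sex code: {sex!r}")
    return s  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

class AgeDistribution(BaseModel):
    """Weibull age model: age = offset + W(shape, scale) truncated at `truncation`."""

    shape: float = 1.2
    scale: float = 6.888645239248054  # solved so P(age <= 75) = 0.793
    offset: float = 65.0
    truncation: float = 95.0

    @model_validator(mode="after")
    def _positive(self) -> "AgeDistribution":
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.truncation <= self.offset:
            raise ValueError("truncation must exceed offset")
        return self


class CreatinineBand(BaseModel):
    mean: float  # µmol/L
    sd: float    # µmol/L

    @model_validator(mode="after")
    def _check(self) -> "CreatinineBand":
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("creatinine mean must be > 0 and SD >= 0")
        return self


class PopulationSpec(BaseModel):
    """All coefficients and distribution parameters of the geriatric model.

    Defaults are the recalibrated Chinese-geriatric equations; weight-curve
    and organ-slope values are calibrated once against the survey band means
    and the predicted organ-weight means (see docs/methods.md).
    """

    age_min: float = 65.0
    age_max: float = 95.0
    male_fraction: float = 0.5
    age_dist: AgeDistribution = Field(default_factory=AgeDistribution)

    # quadratic height-vs-age, cm: c0 + c1*age + c2*age^2
    height_poly_male: tuple[float, float, float] = (166.7, 0.1356, -0.002489)
    height_poly_female: tuple[float, float, float] = (154.6, 0.1889, -0.003178)
    height_resid_sd_male: float = 6.3   # cm
    height_resid_sd_female: float = 5.9  # cm

    # exponential weight-vs-age, kg: a*exp(b*age); solved from the survey
    # band means (65.35/61.97 kg male, 57.95/53.68 kg female) placed at
    # band-representative ages 69.6 and 79.5
    weight_exp_male: tuple[float, float] = (94.92774716565519, -0.005364347787496438)
    weight_exp_female: tuple[float, float] = (99.25382976924811, -0.007731320921447917)
    weight_resid_cv_male: float = 0.165
    weight_resid_cv_female: float = 0.172

    # BSA = c0 * WT^exp_wt * HT^exp_ht  (m², kg, cm)
    bsa_coeffs: tuple[float, float, float] = (0.0151, 0.4259, 0.5751)
    # CO = BSA*k1 - BSA*age*k2  (L/h)
    co_coeffs: tuple[float, float] = (205.9, 0.501)

    scr_dist: dict[str, CreatinineBand] = Field(
        default_factory=lambda: {
            "M|65-75": CreatinineBand(mean=83.14, sd=15.89),
            "M|>75": CreatinineBand(mean=93.48, sd=39.6),
            "F|65-75": CreatinineBand(mean=67.68, sd=30.16),
            "F|>75": CreatinineBand(mean=72.02, sd=25.99),
        }
    )
    scr_truncation: tuple[float, float] = (20.0, 400.0)  # µmol/L
    gfr_cap: tuple[float, float] = (15.0, 400.0)  # mL/min/1.73 m²

    # organ mass = slope * BSA (g per m²); calibrated once so the simulated
    # sex-specific means of the 65-75 band reproduce the predicted
    # liver/kidney weights (1173.4/1051.1 g liver, 287.4/243.4 g kidney)
    organ_slope_liver_male: float = 699.1
    organ_slope_liver_female: float = 688.2
    organ_slope_kidney_male: float = 171.2
    organ_slope_kidney_female: float = 159.4

    hepatic_flow_fraction: float = 0.245
    mppgl: float = 40.0  # mg microsomal protein per g liver
    cyp_abundance: dict[str, float] = Field(
        default_factory=lambda: {"CYP3A4": 137.0, "CYP1A2": 42.0}  # pmol/mg
    )

    volume_fractions: dict[str, float] = Field(
        default_factory=lambda: dict(T.VOLUME_FRACTION)
    )
    flow_fractions: dict[str, float] = Field(
        default_factory=lambda: dict(T.FLOW_FRACTION)
    )

    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "PopulationSpec":
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.age_min < 65.0:
            raise ValueError("geriatric population requires age_min >= 65")
        if self.age_max < self.age_min:
            raise ValueError("age_max must be >= age_min")
        for sd in (self.height_resid_sd_male, self.height_resid_sd_female):
            if sd < 0:
                raise ValueError("height residual SDs must be >= 0")
        for cv in (self.weight_resid_cv_male, self.weight_resid_cv_female):
            if cv < 0:
                raise ValueError("weight residual CVs must be >= 0")
        for slope in (
            self.organ_slope_liver_male, self.organ_slope_liver_female,
            self.organ_slope_kidney_male, self.organ_slope_kidney_female,
        ):
            if slope <= 0:
                raise ValueError("organ-weight slopes must be positive")
        if abs(sum(self.flow_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("flow fractions (excluding lung) must sum to 1")
        return self

    # -- convenience accessors ------------------------------------------------
    def height_poly(self, sex: Sex) -> tuple[float, float, float]:
        return self.height_poly_male if sex == "M" else self.height_poly_female

    def height_resid_sd(self, sex: Sex) -> float:
        return self.height_resid_sd_male if sex == "M" else self.height_resid_sd_female

    def weight_exp(self, sex: Sex) -> tuple[float, float]:
        return self.weight_exp_male if sex == "M" else self.weight_exp_female

    def weight_resid_cv(self, sex: Sex) -> float:
        return self.weight_resid_cv_male if sex == "M" else self.weight_resid_cv_female

    def scr_band(self, sex: Sex, age: float) -> CreatinineBand:
        key = f"{sex}|{age_band(age)}"
        if key not in self.scr_dist:
            raise ValueError(f"no serum-creatinine band for {key}")
        return self.scr_dist[key]

    def organ_slope(self, sex: Sex, organ: str) -> float:
        table = {
            ("M", "liver"): self.organ_slope_liver_male,
            ("F", "liver"): self.organ_slope_liver_female,
            ("M", "kidney"): self.organ_slope_kidney_male,
            ("F", "kidney"): self.organ_slope_kidney_female,
        }
        if (sex, organ) not in table:
            raise ValueError(f"unknown organ {organ!r}")
        return table[(sex, organ)]

    # -- config I/O -----------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def calibrate_weibull_scale(
    shape: float = 1.2,
    band_probability: float = 0.793,
    band_edge: float = 10.0,
    truncation: float = 30.0,
) -> float:
    """Solve the Weibull scale so the truncated distribution puts
    `band_probability` of its mass below `band_edge` (years past offset).

    The target 0.793 is the 65-75 band share of the survey (5613 of 7077).
    """
    if shape <= 0:
        raise ValueError("shape must be positive")

    def cdf(x: float, lam: float) -> float:
        return 1.0 - np.exp(-((x / lam) ** shape))

    return brentq(
        lambda lam: cdf(band_edge, lam) / cdf(truncation, lam) - band_probability,
        1e-3, 1e3, xtol=1e-10,
    )


# ---------------------------------------------------------------------------
# Virtual subject
# ---------------------------------------------------------------------------

@dataclass
class VirtualSubject:
    """One sampled individual with derived physiology.

    Units: age yr, height cm, weight kg, bsa m², cardiac_output L/h,
    serum_creatinine µmol/L, clearances mL/min, organ weights g,
    tissue volumes L, tissue flows L/h, mppgl mg/g, cyp_abundance pmol/mg.
    """

    id: int
    sex: Sex
    age: float
    height: float
    weight: float
    bsa: float
    cardiac_output: float
    serum_creatinine: float
    creatinine_clearance: float
    gfr: float
    liver_weight: float
    kidney_weight: float
    tissue_volumes: dict[str, float] = field(default_factory=dict)
    tissue_flows: dict[str, float] = field(default_factory=dict)
    hepatic_blood_flow: float = 0.0
    mppgl: float = 40.0
    cyp_abundance: dict[str, float] = field(default_factory=dict)

    @property
    def blood_volume(self) -> float:
        return self.tissue_volumes["blood"]

    @property
    def plasma_volume(self) -> float:
        return self.blood_volume * (1.0 - T.HEMATOCRIT)


# ---------------------------------------------------------------------------
# Component samplers / deterministic equations
# ---------------------------------------------------------------------------

def sample_age(
    spec: PopulationSpec,
    n: int,
    rng: np.random.Generator,
    age_range: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Draw ages (years) from the truncated Weibull via inverse CDF.

    `age_range` further restricts the support (used when mimicking a study
    whose inclusion window is narrower than the population's).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    d = spec.age_dist
    lo = max(spec.age_min, d.offset)
    hi = min(spec.age_max, d.truncation)
    if age_range is not None:
        lo, hi = max(lo, age_range[0]), min(hi, age_range[1])
    if hi < lo:
        raise ValueError("empty age support after truncation")
    if hi == lo:
        return np.full(n, lo)

    def cdf(x: float) -> float:
        return 1.0 - np.exp(-(((x - d.offset) / d.scale) ** d.shape))

    u = rng.uniform(cdf(lo), cdf(hi), size=n)
    ages = d.offset + d.scale * (-np.log1p(-u)) ** (1.0 / d.shape)
    return np.clip(ages, lo, hi)


def height_mean(age: float, sex: str, spec: Optional[PopulationSpec] = None) -> float:
    """Population-mean height (cm) at a given age from the quadratic curve."""
    spec = spec or PopulationSpec()
    c0, c1, c2 = spec.height_poly(normalize_sex(sex))
    return c0 + c1 * age + c2 * age * age


def _truncated_standard_normal(
    rng: np.random.Generator, lo: float, hi: float
) -> float:
    """Rejection-sampled standard normal restricted to [lo, hi]."""
    for _ in range(10000):
        z = rng.standard_normal()
        if lo <= z <= hi:
            return float(z)
    raise RuntimeError("truncated-normal rejection sampling failed")  # pragma: no cover


def sample_height(
    age: float, sex: str, spec: PopulationSpec, rng: np.random.Generator
) -> float:
    """Mean height plus a normal residual truncated at ±4 SD."""
    s = normalize_sex(sex)
    mu = height_mean(age, s, spec)
    sd = spec.height_resid_sd(s)
    if sd == 0:
        return mu
    return mu + sd * _truncated_standard_normal(rng, -4.0, 4.0)


def weight_mean(age: float, sex: str, spec: Optional[PopulationSpec] = None) -> float:
    """Population-mean weight (kg) at a given age: a*exp(b*age)."""
    spec = spec or PopulationSpec()
    a, b = spec.weight_exp(normalize_sex(sex))
    if a <= 0:
        raise ValueError("weight curve coefficient a must be positive")
    return a * np.exp(b * age)


def sample_weight(
    age: float, sex: str, spec: PopulationSpec, rng: np.random.Generator
) -> float:
    """Mean weight times a mean-one lognormal residual."""
    s = normalize_sex(sex)
    cv = spec.weight_resid_cv(s)
    mu = weight_mean(age, s, spec)
    if cv == 0:
        return mu
    sigma2 = np.log1p(cv * cv)
    return float(mu * np.exp(rng.normal(-0.5 * sigma2, np.sqrt(sigma2))))


def bsa(weight: float, height: float, spec: Optional[PopulationSpec] = None) -> float:
    """Body surface area (m²) from the power law c0 * WT^a * HT^b."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    spec = spec or PopulationSpec()
    c0, ew, eh = spec.bsa_coeffs
    return c0 * weight**ew * height**eh


def cardiac_output(
    bsa_m2: float, age: float, spec: Optional[PopulationSpec] = None
) -> float:
    """Cardiac output (L/h), linear in BSA and declining with age."""
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    spec = spec or PopulationSpec()
    k1, k2 = spec.co_coeffs
    co = bsa_m2 * k1 - bsa_m2 * age * k2
    if co <= 0:
        raise ValueError(f"cardiac output non-positive at age {age}")
    return co


def sample_serum_creatinine(
    sex: str, age: float, spec: PopulationSpec, rng: np.random.Generator
) -> float:
    """Serum creatinine (µmol/L) from the sex/age-band distribution.

    A lognormal is moment-matched to the band mean/SD and truncated to the
    physiological window; with SD = 0 the band mean is returned.
    """
    if age < 65:
        raise ValueError("geriatric bands start at 65")
    band = spec.scr_band(normalize_sex(sex), age)
    if band.sd == 0:
        return band.mean
    cv2 = (band.sd / band.mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(band.mean) - 0.5 * sigma * sigma
    lo, hi = spec.scr_truncation
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    return float(np.exp(mu + sigma * _truncated_standard_normal(rng, a, b)))


#: µmol/L per mg/dL for creatinine
_SCR_UMOL_PER_MGDL = 88.4


def creatinine_clearance_cg(
    age: float, weight: float, scr_umol_l: float, sex: str
) -> float:
    """Cockcroft-Gault creatinine clearance (mL/min).

    CLcr = (140 - age) * weight / (72 * Scr[mg/dL]), times 0.85 for females.
    """
    if scr_umol_l <= 0:
        raise ValueError("serum creatinine must be positive")
    if age >= 140:
        raise ValueError("Cockcroft-Gault undefined for age >= 140")
    s = normalize_sex(sex)
    scr_mgdl = scr_umol_l / _SCR_UMOL_PER_MGDL
    clcr = (140.0 - age) * weight / (72.0 * scr_mgdl)
    return clcr * (0.85 if s == "F" else 1.0)


def apply_gfr_cap(
    clcr_ml_min: float, bsa_m2: float, spec: Optional[PopulationSpec] = None
) -> float:
    """Clamp the BSA-normalised GFR to the population cap, then de-normalise."""
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    if clcr_ml_min < 0:
        raise ValueError("clearance must be >= 0")
    spec = spec or PopulationSpec()
    lo, hi = spec.gfr_cap
    normalized = clcr_ml_min * 1.73 / bsa_m2
    return float(np.clip(normalized, lo, hi)) * bsa_m2 / 1.73


def organ_weight(
    bsa_m2: float, sex: str, organ: str, spec: Optional[PopulationSpec] = None
) -> float:
    """Liver or kidney weight (g) as a sex-specific linear function of BSA."""
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    spec = spec or PopulationSpec()
    slope = spec.organ_slope(normalize_sex(sex), organ)
    return slope * bsa_m2


# ---------------------------------------------------------------------------
# Subject assembly
# ---------------------------------------------------------------------------

def build_subject(
    spec: PopulationSpec,
    rng: np.random.Generator,
    subject_id: int = 0,
    sex: Optional[str] = None,
    age_range: Optional[tuple[float, float]] = None,
    male_fraction: Optional[float] = None,
) -> VirtualSubject:
    """Sample one virtual subject and derive all downstream physiology."""
    mf = spec.male_fraction if male_fraction is None else male_fraction
    if sex is None:
        s: Sex = "M" if rng.uniform() < mf else "F"
    else:
        s = normalize_sex(sex)
    age = float(sample_age(spec, 1, rng, age_range=age_range)[0])
    height = sample_height(age, s, spec, rng)
    weight = sample_weight(age, s, spec, rng)
    bsa_m2 = bsa(weight, height, spec)
    co = cardiac_output(bsa_m2, age, spec)
    scr = sample_serum_creatinine(s, age, spec, rng)
    clcr = creatinine_clearance_cg(age, weight, scr, s)
    gfr = apply_gfr_cap(clcr, bsa_m2, spec)
    liver_g = organ_weight(bsa_m2, s, "liver", spec)
    kidney_g = organ_weight(bsa_m2, s, "kidney", spec)

    # tissue volumes: reference fractions of body weight, with liver and
    # kidney overridden by the calibrated organ masses (density 1.05 g/mL)
    # and "rest" closing the total-body-volume balance.
    vf = spec.volume_fractions
    body_volume = weight / T.BODY_DENSITY
    volumes = {t: vf[t] * weight for t in T.TISSUES if t != "rest"}
    volumes["liver"] = liver_g / 1000.0 / T.BODY_DENSITY
    volumes["kidney"] = kidney_g / 1000.0 / T.BODY_DENSITY
    volumes["blood"] = vf["blood"] * weight
    rest = body_volume - sum(volumes.values())
    if rest <= 0:
        raise ValueError("tissue volume fractions exceed body volume")
    volumes["rest"] = rest

    flows = {t: spec.flow_fractions[t] * co for t in T.PERFUSED}
    flows["lung"] = co
    hepatic_flow = spec.hepatic_flow_fraction * co
    # hepatic artery = total hepatic flow minus portal inflow (gut + spleen)
    arterial_liver = hepatic_flow - flows["gut"] - flows["spleen"]
    if arterial_liver <= 0:
        raise ValueError("hepatic_flow_fraction below portal flow fraction")
    flows["liver"] = arterial_liver

    return VirtualSubject(
        id=subject_id, sex=s, age=age, height=height, weight=weight,
        bsa=bsa_m2, cardiac_output=co, serum_creatinine=scr,
        creatinine_clearance=clcr, gfr=gfr,
        liver_weight=liver_g, kidney_weight=kidney_g,
        tissue_volumes=volumes, tissue_flows=flows,
        hepatic_blood_flow=hepatic_flow, mppgl=spec.mppgl,
        cyp_abundance=dict(spec.cyp_abundance),
    )


def subject_streams(seed: int, n: int) -> list[np.random.Generator]:
    """One independent RNG stream per subject (stable in n and seed)."""
    return [np.random.default_rng([seed, i]) for i in range(n)]


def generate_population(
    spec: PopulationSpec,
    n: int,
    seed: Optional[int] = None,
    age_range: Optional[tuple[float, float]] = None,
    male_fraction: Optional[float] = None,
) -> list[VirtualSubject]:
    """Sample `n` virtual subjects, one seeded stream per subject."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = spec.seed if seed is None else seed
    return [
        build_subject(
            spec, rng, subject_id=i, age_range=age_range, male_fraction=male_fraction
        )
        for i, rng in enumerate(subject_streams(seed, n))
    ]


def population_frame(subjects: Sequence[VirtualSubject]):
    """Tabular export: one row per subject, SI units as in VirtualSubject."""
    import pandas as pd

    rows = []
    for s in subjects:
        row = {
            "id": s.id, "sex": s.sex, "age_yr": s.age, "height_cm": s.height,
            "weight_kg": s.weight, "bsa_m2": s.bsa,
            "cardiac_output_l_h": s.cardiac_output,
            "serum_creatinine_umol_l": s.serum_creatinine,
            "creatinine_clearance_ml_min": s.creatinine_clearance,
            "gfr_ml_min": s.gfr,
            "liver_weight_g": s.liver_weight, "kidney_weight_g": s.kidney_weight,
            "hepatic_blood_flow_l_h": s.hepatic_blood_flow,
        }
        row.update({f"vol_{t}_l": v for t, v in sorted(s.tissue_volumes.items())})
        row.update({f"flow_{t}_l_h": v for t, v in sorted(s.tissue_flows.items())})
        rows.append(row)
    return pd.DataFrame(rows)
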