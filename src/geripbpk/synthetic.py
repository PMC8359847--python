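"""Synthetic inputs for end-to-end testing without any external data.

Two generators live here:

* survey-style demographic records whose sex/age-band means and SDs
  match the national-survey summary structure (used to exercise the
  curve-fitting module with known ground truth), and
* noisy concentration-time datasets from analytic one/two-compartment
  models with known clearance and volume (used to exercise the NCA
  machinery; noise is the standard combined proportional + additive
  residual model with optional lower-limit-of-quantification flagging).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field


class SurveyGeneratorConfig(BaseModel):
    """Generating truth for survey records; defaults follow the survey
    band summaries and the recalibrated equations."""

    n_per_cell: int = Field(default=2000, ge=1)
    band_edges: tuple[float, float, float] = (65.0, 75.0, 90.0)
    height_poly_male: tuple[float, float, float] = (166.7, 0.1356, -0.002489)
    height_poly_female: tuple[float, float, float] = (154.6, 0.1889, -0.003178)
    height_sd_male: float = 6.3
    height_sd_female: float = 5.9
    weight_exp_male: tuple[float, float] = (94.92774716565519, -0.005364347787496438)
    weight_exp_female: tuple[float, float] = (99.25382976924811, -0.007731320921447917)
    weight_cv_male: float = 0.165
    weight_cv_female: float = 0.172
    # serum creatinine (mean, sd) per sex|band, µmol/L
    scr: dict[str, tuple[float, float]] = Field(default_factory=lambda: {
        "M|65-75": (83.14, 15.89), "M|>75": (93.48, 39.6),
        "F|65-75": (67.68, 30.16), "F|>75": (72.02, 25.99),
    })
    co_coeffs: tuple[float, float] = (205.9, 0.501)
    co_resid_sd_l_h: float = 75.0
    bsa_coeffs: tuple[float, float, float] = (0.0151, 0.4259, 0.5751)
    seed: int = 0


def generate_survey(config: Optional[SurveyGeneratorConfig] = None) -> pd.DataFrame:
    """Survey records: age, sex, height, weight, creatinine, cardiac output.

    Ages are uniform within each band; all other variables follow the
    generating curves plus their residual models, so fitted coefficients
    converge to the generating truth as n grows.
    """
    cfg = config or SurveyGeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, mid, hi = cfg.band_edges
    frames = []
    for sex in ("M", "F"):
        poly = cfg.height_poly_male if sex == "M" else cfg.height_poly_female
        hsd = cfg.height_sd_male if sex == "M" else cfg.height_sd_female
        a, b = cfg.weight_exp_male if sex == "M" else cfg.weight_exp_female
        cv = cfg.weight_cv_male if sex == "M" else cfg.weight_cv_female
        for band, (alo, ahi) in (("65-75", (lo, mid)), (">75", (mid, hi))):
            n = cfg.n_per_cell
            age = rng.uniform(alo, ahi, n)
            height = poly[0] + poly[1] * age + poly[2] * age**2
            height = height + rng.normal(0.0, hsd, n)
            sigma2 = np.log1p(cv * cv)
            weight = a * np.exp(b * age) * np.exp(
                rng.normal(-0.5 * sigma2, np.sqrt(sigma2), n)
            )
            m, s = cfg.scr[f"{sex}|{band}"]
            ls2 = np.log1p((s / m) ** 2)
            scr = np.exp(rng.normal(np.log(m) - 0.5 * ls2, np.sqrt(ls2), n))
            c0, ew, eh = cfg.bsa_coeffs
            bsa = c0 * weight**ew * height**eh
            k1, k2 = cfg.co_coeffs
            co = bsa * k1 - bsa * age * k2 + rng.normal(0.0, cfg.co_resid_sd_l_h, n)
            frames.append(pd.DataFrame({
                "age": age, "sex": sex, "band": band,
                "height_cm": height, "weight_kg": weight,
                "serum_creatinine_umol_l": scr,
                "cardiac_output_l_h": np.clip(co, 1.0, None),
            }))
    return pd.concat(frames, ignore_index=True)


class PKNoiseConfig(BaseModel):
    proportional_cv: float = Field(default=0.0, ge=0)
    additive_sd_mg_l: float = Field(default=0.0, ge=0)
    lloq_mg_l: float = Field(default=0.0, ge=0)
    seed: int = 0


@dataclass
class PKTruth:
    """Ground-truth disposition for the analytic profile generator."""

    cl_l_h: float
    v_central_l: float
    ka_per_h: float = 1.5       # oral only
    fa: float = 1.0             # oral only
    v_peripheral_l: Optional[float] = None  # two-compartment when set
    q_inter_l_h: float = 0.0


def _profile_1c(t, dose, truth: PKTruth, route, duration):
    ke = truth.cl_l_h / truth.v_central_l
    if route == "iv_bolus":
        return dose / truth.v_central_l * np.exp(-ke * t)
    if route == "iv_infusion":
        rate = dose / duration
        c = np.where(
            t <= duration,
            rate / truth.cl_l_h * (1 - np.exp(-ke * t)),
            rate / truth.cl_l_h * (1 - np.exp(-ke * duration))
            * np.exp(-ke * (t - duration)),
        )
        return c
    if route == "oral":
        ka = truth.ka_per_h
        if abs(ka - ke) < 1e-12:
            return truth.fa * dose / truth.v_central_l * ka * t * np.exp(-ka * t)
        return (
            truth.fa * dose * ka / (truth.v_central_l * (ka - ke))
            * (np.exp(-ke * t) - np.exp(-ka * t))
        )
    raise ValueError(f"unknown route {route!r}")


def _profile_2c(t, dose, truth: PKTruth, route, duration):
    # standard bi-exponential macro constants from micro rates
    v1 = truth.v_central_l
    k10 = truth.cl_l_h / v1
    k12 = truth.q_inter_l_h / v1
    k21 = truth.q_inter_l_h / truth.v_peripheral_l
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4 * k10 * k21)
    alpha, beta = (s + disc) / 2, (s - disc) / 2
    A = (alpha - k21) / (alpha - beta) / v1
    B = (k21 - beta) / (alpha - beta) / v1
    if route == "iv_bolus":
        return dose * (A * np.exp(-alpha * t) + B * np.exp(-beta * t))
    if route == "iv_infusion":
        rate = dose / duration

        def integ(tt, lam, coef):
            c_during = coef / lam * (1 - np.exp(-lam * tt))
            c_after = (
                coef / lam * (1 - np.exp(-lam * duration))
                * np.exp(-lam * (tt - duration))
            )
            return np.where(tt <= duration, c_during, c_after)

        return rate * (integ(t, alpha, A) + integ(t, beta, B))
    raise ValueError("two-compartment generator supports IV routes only")


def generate_pk_dataset(
    dose_mg: float,
    times_h: np.ndarray,
    truth: PKTruth,
    noise: Optional[PKNoiseConfig] = None,
    route: str = "iv_bolus",
    infusion_duration_h: float = 1.0,
    n_subjects: int = 1,
) -> pd.DataFrame:
    """Analytic concentration profiles plus residual noise.

    Returns a tidy frame (subject, time_h, conc_mg_l, censored); values
    below the LLOQ are flagged, never dropped.  With zero noise, NCA on
    the output recovers the generating clearance.
    """
    if truth.cl_l_h <= 0 or truth.v_central_l <= 0:
        raise ValueError("truth parameters must be positive")
    noise = noise or PKNoiseConfig()
    t = np.asarray(times_h, float)
    if truth.v_peripheral_l is not None:
        clean = _profile_2c(t, dose_mg, truth, route, infusion_duration_h)
    else:
        clean = _profile_1c(t, dose_mg, truth, route, infusion_duration_h)
    if noise.lloq_mg_l > 0 and np.all(clean < noise.lloq_mg_l):
        raise ValueError("LLOQ above the entire profile: nothing quantifiable")

    rng = np.random.default_rng(noise.seed)
    frames = []
    for subj in range(n_subjects):
        eps_p = rng.normal(0.0, noise.proportional_cv, t.size) \
            if noise.proportional_cv > 0 else 0.0
        eps_a = rng.normal(0.0, noise.additive_sd_mg_l, t.size) \
            if noise.additive_sd_mg_l > 0 else 0.0
        conc = np.clip(clean * (1.0 + eps_p) + eps_a, 0.0, None)
        frames.append(pd.DataFrame({
            "subject": subj, "time_h": t, "conc_mg_l": conc,
            "censored": conc < noise.lloq_mg_l,
        }))
    return pd.concat(frames, ignore_index=True)


def make_fixtures(out_dir, seed: int = 7) -> dict[str, str]:
    """Write survey and PK CSV fixtures plus a manifest of generating truth."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    survey_cfg = SurveyGeneratorConfig(seed=seed)
    survey = generate_survey(survey_cfg)
    survey_path = out / "survey.csv"
    survey.to_csv(survey_path, index=False)

    truth = PKTruth(cl_l_h=5.0, v_central_l=40.0)
    times = np.array([0.25, 0.5, 1, 2, 4, 6, 8, 12, 16, 24], float)
    pk = generate_pk_dataset(
        500.0, times, truth,
        PKNoiseConfig(proportional_cv=0.2, lloq_mg_l=0.05, seed=seed),
        n_subjects=20,
    )
    pk_path = out / "pk_iv.csv"
    pk.to_csv(pk_path, index=False)

    manifest = {
        "survey": {"file": survey_path.name, "config": survey_cfg.model_dump(mode="json")},
        "pk_iv": {"file": pk_path.name, "dose_mg": 500.0,
                  "truth": {"cl_l_h": 5.0, "v_central_l": 40.0}},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return {k: str(v) for k, v in
            {"survey": survey_path, "pk_iv": pk_path, "manifest": manifest_path}.items()}
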