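"""Virtual clinical-trial simulation with NCA read-outs.

A study design mirrors one observed clinical study: drug, dose, route,
age window, sample size and sampling schedule.  Simulation draws
`n_trials` cohorts of `n_subjects` virtual subjects restricted to the
design's age range, integrates the PBPK model for each, runs NCA on the
sampled profile and summarises with geometric means (the PK convention).

Repeated-dose designs (``n_doses`` > 1) are simulated to approximate
steady state and analysed over the final dosing interval, where
AUC over the interval equals dose/CL for linear kinetics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .drugs import DrugModel, load_drug_model
from .nca import nca
from .pbpk import DoseEvent, EngineSettings, simulate_concentration
from .population import PopulationSpec, build_subject


class StudyDesign(BaseModel):
    label: str
    drug: str
    dose_mg: float = Field(gt=0)
    route: str  # oral | iv_bolus | iv_infusion
    infusion_duration_h: float = 0.0
    n_doses: int = Field(default=1, ge=1)
    dosing_interval_h: float = Field(default=24.0, gt=0)
    n_subjects: int = Field(ge=1)
    n_trials: int = Field(default=10, ge=1)
    age_min: float
    age_max: float
    male_fraction: float = Field(default=0.5, ge=0, le=1)
    sampling_times_h: list[float]  # relative to the last dose
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "StudyDesign":
        if self.age_max < self.age_min:
            raise ValueError("age_max must be >= age_min")
        if self.route == "iv_infusion" and self.infusion_duration_h <= 0:
            raise ValueError("infusion route requires a positive duration")
        if len(self.sampling_times_h) < 3:
            raise ValueError("need at least 3 sampling times")
        return self

    @classmethod
    def from_json(cls, source) -> "StudyDesign":
        if isinstance(source, (str, Path)) and not str(source).endswith(".json"):
            ref = resources.files("geripbpk").joinpath(f"data/designs/{source}.json")
            return cls.model_validate(json.loads(ref.read_text()))
        with open(source) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(mode="json"), fh, indent=2)
            fh.write("\n")


def shipped_designs() -> list[str]:
    """Labels of the study-design files shipped with the package."""
    root = resources.files("geripbpk").joinpath("data/designs")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".json"))


@dataclass
class StudyResult:
    design: StudyDesign
    subjects: pd.DataFrame  # one row per virtual subject
    geomean: dict[str, float]
    trial_spread: dict[str, float]  # SD of log10 per-trial geometric means


def _dose_events(design: StudyDesign) -> list[DoseEvent]:
    events = []
    for k in range(design.n_doses):
        start = k * design.dosing_interval_h
        if design.route == "iv_infusion":
            events.append(DoseEvent("iv_infusion", design.dose_mg, start,
                                    design.infusion_duration_h))
        elif design.route == "iv_bolus":
            events.append(DoseEvent("iv_bolus", design.dose_mg, start))
        elif design.route == "oral":
            events.append(DoseEvent("oral", design.dose_mg, start))
        else:
            raise ValueError(f"unknown route {design.route!r}")
    return events


def simulate_study(
    design: StudyDesign,
    spec: Optional[PopulationSpec] = None,
    drug: Optional[DrugModel] = None,
    settings: Optional[EngineSettings] = None,
    seed: Optional[int] = None,
) -> StudyResult:
    """Run one virtual study; reproducible for a fixed seed."""
    spec = spec or PopulationSpec()
    drug = drug or load_drug_model(design.drug)
    seed = design.seed if seed is None else seed
    age_lo = max(design.age_min, spec.age_min)
    age_hi = min(design.age_max, spec.age_max)
    if age_hi < age_lo:
        raise ValueError("design age range does not intersect population support")

    offset = (design.n_doses - 1) * design.dosing_interval_h
    rel_times = np.asarray(sorted(design.sampling_times_h), float)
    grid = offset + rel_times
    events = _dose_events(design)
    steady_state = design.n_doses > 1

    rows = []
    for trial in range(design.n_trials):
        for i in range(design.n_subjects):
            rng = np.random.default_rng([seed, trial, i])
            subj = build_subject(
                spec, rng, subject_id=trial * design.n_subjects + i,
                age_range=(age_lo, age_hi), male_fraction=design.male_fraction,
            )
            prof = simulate_concentration(subj, drug, events, settings, grid=grid)
            res = nca(rel_times, prof.conc_mg_l)
            if steady_state:
                auc = res.auc_0_t  # AUC over the dosing interval at steady state
                cl = design.dose_mg / auc if auc > 0 else np.nan
            else:
                auc = res.auc_0_inf if res.auc_0_inf is not None else res.auc_0_t
                cl = design.dose_mg / auc if auc and auc > 0 else np.nan
            rows.append({
                "trial": trial, "subject": subj.id, "sex": subj.sex,
                "age_yr": subj.age, "weight_kg": subj.weight,
                "auc_mg_h_l": auc, "auc_0_t_mg_h_l": res.auc_0_t,
                "cmax_mg_l": res.cmax, "tmax_h": res.tmax,
                "lambda_z_per_h": res.lambda_z,
                "cl_l_h": cl, "cl_l_h_kg": cl / subj.weight,
                "mass_balance_error": prof.mass_balance_error,
            })
    df = pd.DataFrame(rows)

    def gm(col: str) -> float:
        vals = df[col].dropna()
        return float(np.exp(np.mean(np.log(vals)))) if len(vals) else np.nan

    geomean = {c: gm(c) for c in ("auc_mg_h_l", "cmax_mg_l", "cl_l_h", "cl_l_h_kg")}
    geomean["tmax_h"] = float(df["tmax_h"].median())

    spread = {}
    for c in ("auc_mg_h_l", "cmax_mg_l", "cl_l_h_kg"):
        per_trial = df.groupby("trial")[c].apply(
            lambda v: np.mean(np.log10(v.dropna()))
        )
        spread[c] = float(per_trial.std(ddof=1)) if len(per_trial) > 1 else 0.0

    return StudyResult(design=design, subjects=df, geomean=geomean,
                       trial_spread=spread)
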