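"""Drug-model parameter sets: schema, validation, JSON I/O and presets.

A drug model carries the physicochemistry (MW, log P, ionisation class
and pKa), binding (fraction unbound in plasma, blood:plasma ratio), a
global Kp scalar used to match the observed volume of distribution,
an optional first-order absorption block and one or more elimination
routes (enzyme-specific intrinsic clearance, GFR-proportional renal
clearance, or a fixed systemic clearance).

Six presets ship with the package: simvastatin and midazolam (CYP3A4),
theophylline (CYP1A2) and ceftazidime, gentamicin and vancomycin
(renal, no active secretion).  Preset numbers are literature values or
retrograde-calibrated from adult clinical clearances; each JSON file
records per-field provenance.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Union

from pydantic import BaseModel, Field, model_validator

CompoundClass = Literal["acid", "base", "neutral", "zwitterion"]

PRESETS = [
    "simvastatin", "midazolam", "theophylline",
    "ceftazidime", "gentamicin", "vancomycin",
]


class Absorption(BaseModel):
    """First-order oral absorption: fraction absorbed, rate constant, lag.

    `fa` is the dose fraction reaching the absorption depot; for drugs with
    gut-wall extraction it is the fa x fg product (no mechanistic gut
    metabolism in this engine).
    """

    fa: float = Field(gt=0, le=1)
    ka: float = Field(gt=0)  # 1/h
    lag: float = Field(default=0.0, ge=0)  # h


class EnzymaticRoute(BaseModel):
    kind: Literal["enzymatic"] = "enzymatic"
    enzyme: str
    clint_per_pmol: float = Field(ge=0)  # µL/min/pmol enzyme


class RenalRoute(BaseModel):
    kind: Literal["renal"] = "renal"
    clr_ref: float = Field(gt=0)  # L/h at gfr_ref
    gfr_ref: float = Field(default=121.0, gt=0)  # mL/min, healthy-adult convention


class SystemicRoute(BaseModel):
    kind: Literal["systemic"] = "systemic"
    cl_iv: float = Field(gt=0)  # L/h, plasma-referenced, reference subject


EliminationRoute = Union[EnzymaticRoute, RenalRoute, SystemicRoute]


class DrugModel(BaseModel):
    name: str
    molecular_weight: float = Field(gt=0)  # g/mol
    log_p: float
    compound_class: CompoundClass
    #: pKa values; for zwitterions list acidic first, then basic
    pka: list[float] = Field(default_factory=list)
    fu_plasma: float = Field(gt=0, le=1)
    blood_to_plasma: float = Field(gt=0)
    kp_scalar: float = Field(default=1.0, gt=0)
    absorption: Optional[Absorption] = None
    elimination: list[EliminationRoute] = Field(min_length=1)
    #: declared literature steady-state volume, L/kg (cross-check anchor)
    vss_literature: Optional[float] = None
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "DrugModel":
        if self.compound_class in ("acid", "base") and not self.pka:
            raise ValueError(f"{self.compound_class} compound requires a pKa")
        if self.compound_class == "zwitterion" and len(self.pka) < 2:
            raise ValueError("zwitterion requires acidic and basic pKa values")
        return self

    # -- ionisation bookkeeping ----------------------------------------------
    @property
    def pka_acid(self) -> list[float]:
        if self.compound_class == "acid":
            return list(self.pka)
        if self.compound_class == "zwitterion":
            return [self.pka[0]]
        return []

    @property
    def pka_base(self) -> list[float]:
        if self.compound_class == "base":
            return list(self.pka)
        if self.compound_class == "zwitterion":
            return list(self.pka[1:])
        return []

    @property
    def is_moderate_base(self) -> bool:
        """Bases (incl. zwitterions) with a basic pKa >= 7 partition into
        acidic phospholipids; weaker/neutral species bind plasma proteins."""
        return any(p >= 7.0 for p in self.pka_base)

    @property
    def fu_blood(self) -> float:
        return self.fu_plasma / self.blood_to_plasma

    def route(self, kind: str) -> list[EliminationRoute]:
        return [r for r in self.elimination if r.kind == kind]


def validate_drug_model(model: DrugModel) -> list[str]:
    """Re-check a constructed model; returns a list of violations (empty if OK)."""
    problems: list[str] = []
    if not (0 < model.fu_plasma <= 1):
        problems.append("fu_plasma must lie in (0, 1]")
    if model.blood_to_plasma <= 0:
        problems.append("blood_to_plasma must be positive")
    if model.kp_scalar <= 0:
        problems.append("kp_scalar must be positive")
    if not model.elimination:
        problems.append("at least one elimination route required")
    if model.compound_class in ("acid", "base") and not model.pka:
        problems.append("ionisable compound lacks pKa")
    for r in model.route("renal"):
        if r.gfr_ref <= 0:
            problems.append("renal gfr_ref must be positive")
    return problems


def load_drug_model(source) -> DrugModel:
    """Load a drug model from a JSON file path or a preset name."""
    if isinstance(source, (str, Path)) and not str(source).endswith(".json"):
        name = str(source).lower()
        if name in PRESETS:
            ref = resources.files("geripbpk").joinpath(f"data/drugs/{name}.json")
            return DrugModel.model_validate(json.loads(ref.read_text()))
        raise ValueError(f"unknown preset or non-JSON path: {source!r}")
    with open(source) as fh:
        payload = json.load(fh)
    return DrugModel.model_validate(payload)


def save_drug_model(model: DrugModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.model_dump(mode="json", exclude_none=True), fh, indent=2)
        fh.write("\n")
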