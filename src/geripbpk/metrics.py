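"""Prediction-verification metrics: fold ratios, %-within-fold, MAPE.

The verification convention: for each study and PK quantity (AUC, Cmax,
CL) the fold ratio is predicted/observed.  A prediction is "within
f-fold" when the ratio lies in [1/f, f], bounds inclusive.  MAPE is the
mean absolute prediction error of the ratios, 100 x mean(|ratio - 1|).
Rows without an observed value are excluded from all aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .population import PopulationSpec
from .trials import StudyDesign, StudyResult, shipped_designs, simulate_study

QUANTITIES = ("AUC", "Cmax", "CL")

#: conversion from simulation-native units (AUC mg·h/L, Cmax mg/L,
#: CL L/h/kg) to each drug's reporting units
_UNIT_SCALE = {
    "simvastatin": {"AUC": 1000.0, "Cmax": 1000.0, "CL": 1.0},
    "midazolam": {"AUC": 1000.0, "Cmax": 1000.0, "CL": 1.0},
    "theophylline": {"AUC": 1.0, "Cmax": 1.0, "CL": 1000.0},
    "ceftazidime": {"AUC": 1.0, "Cmax": 1.0, "CL": 1000.0},
    "gentamicin": {"AUC": 1.0, "Cmax": 1.0, "CL": 1000.0},
    "vancomycin": {"AUC": 1.0, "Cmax": 1.0, "CL": 1000.0},
}


@dataclass
class ComparisonRow:
    study: str
    quantity: str  # AUC | Cmax | CL
    predicted: float
    observed: Optional[float]
    units: str = ""

    @property
    def ratio(self) -> Optional[float]:
        if self.observed is None or not np.isfinite(self.observed):
            return None
        return fold_ratio(self.predicted, self.observed)


def fold_ratio(predicted: float, observed: float) -> float:
    """Predicted/observed ratio; requires a positive observed value."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    return predicted / observed


def pct_within_fold(ratios: Iterable[float], fold: float) -> float:
    """Percentage of ratios inside [1/fold, fold], bounds inclusive."""
    if fold < 1:
        raise ValueError("fold must be >= 1")
    arr = np.asarray([r for r in ratios if r is not None and np.isfinite(r)], float)
    if arr.size == 0:
        raise ValueError("no ratios to classify")
    if np.any(arr <= 0):
        raise ValueError("ratios must be positive")
    within = (arr >= 1.0 / fold) & (arr <= fold)
    return 100.0 * within.mean()


def mape(ratios: Iterable[float]) -> float:
    """Mean absolute prediction error, percent: 100 x mean(|ratio - 1|)."""
    arr = np.asarray([r for r in ratios if r is not None and np.isfinite(r)], float)
    if arr.size == 0:
        raise ValueError("no ratios")
    return 100.0 * np.mean(np.abs(arr - 1.0))


def load_observed() -> pd.DataFrame:
    """The shipped observed/printed PK comparison table (one row per
    study x quantity, NA where the source study reported none)."""
    ref = resources.files("geripbpk").joinpath("data/observed_pk.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


def comparison_rows_from_results(
    results: Sequence[StudyResult],
    observed: Optional[pd.DataFrame] = None,
) -> list[ComparisonRow]:
    """Pair simulated study summaries with the observed table."""
    observed = observed if observed is not None else load_observed()
    obs_idx = observed.set_index(["label", "quantity"])
    rows: list[ComparisonRow] = []
    for res in results:
        drug = res.design.drug
        scale = _UNIT_SCALE[drug]
        native = {
            "AUC": res.geomean["auc_mg_h_l"],
            "Cmax": res.geomean["cmax_mg_l"],
            "CL": res.geomean["cl_l_h_kg"],
        }
        for q in QUANTITIES:
            key = (res.design.label, q)
            if key not in obs_idx.index:
                continue
            rec = obs_idx.loc[key]
            obs = float(rec["observed"]) if pd.notna(rec["observed"]) else None
            rows.append(ComparisonRow(
                study=res.design.label, quantity=q,
                predicted=native[q] * scale[q], observed=obs,
                units=str(rec["units"]),
            ))
    return rows


def verification_report(comparisons: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Tidy per-row report with ratios; aggregates via `aggregate_report`."""
    if not comparisons:
        raise ValueError("no comparisons")
    return pd.DataFrame([
        {
            "study": c.study, "quantity": c.quantity, "units": c.units,
            "predicted": c.predicted, "observed": c.observed, "ratio": c.ratio,
        }
        for c in comparisons
    ])


def aggregate_report(report: pd.DataFrame) -> pd.DataFrame:
    """Per-quantity %-within-1.25-fold, %-within-2-fold and MAPE."""
    rows = []
    for q in QUANTITIES:
        ratios = report.loc[report["quantity"] == q, "ratio"].dropna().tolist()
        if not ratios:
            continue
        rows.append({
            "quantity": q, "n": len(ratios),
            "pct_within_1.25": pct_within_fold(ratios, 1.25),
            "pct_within_2": pct_within_fold(ratios, 2.0),
            "mape_pct": mape(ratios),
        })
    return pd.DataFrame(rows)


def run_verification(
    spec: Optional[PopulationSpec] = None,
    labels: Optional[Sequence[str]] = None,
    seed: int = 0,
    n_trials: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every shipped study design and compare with the observed
    table; returns (per-row report, per-quantity aggregates)."""
    spec = spec or PopulationSpec()
    labels = list(labels) if labels is not None else shipped_designs()
    results = []
    for label in labels:
        design = StudyDesign.from_json(label)
        if n_trials is not None:
            design = design.model_copy(update={"n_trials": n_trials})
        results.append(simulate_study(design, spec, seed=seed))
    rows = comparison_rows_from_results(results)
    report = verification_report(rows)
    return report, aggregate_report(report)
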