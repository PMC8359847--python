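"""Fitting the recalibratable demographic curves and summarising populations.

A "survey" is a tidy table with one row per subject and columns
``age``, ``sex`` (M/F) and any of ``height_cm``, ``weight_kg``,
``serum_creatinine_umol_l``, ``cardiac_output_l_h`` (missing values
allowed).  The height curve is an ordinary-least-squares quadratic in
age; the weight curve is an exponential fitted by OLS on log weight.
Population summaries follow the validation-table layout: per variable
and age band, mean, SD and the 5th/95th percentiles (linear
interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .population import BAND_HIGH, BAND_LOW, VirtualSubject, age_band, normalize_sex

SURVEY_COLUMNS = [
    "age", "sex", "height_cm", "weight_kg",
    "serum_creatinine_umol_l", "cardiac_output_l_h",
]


@dataclass
class CurveFit:
    """OLS fit result: coefficients, their standard errors, residual scale."""

    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...]
    residual_sd: float  # cm for height; CV (unitless) for log-weight fits


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"age", "sex"} - set(df.columns)
    if missing:
        raise ValueError(f"survey file lacks required columns: {sorted(missing)}")
    return df


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    n, p = X.shape
    if n < p:
        raise ValueError("not enough records for the fit")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (ages not distinct enough)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - p, 1)  # n == p: exact interpolation, zero residual scale
    s2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(s2 * np.linalg.pinv(X.T @ X)))
    return beta, se, np.sqrt(s2)


def _sex_subset(
    records: pd.DataFrame, sex: str, column: str, min_records: int
) -> pd.DataFrame:
    s = normalize_sex(sex)
    sub = records[
        records["sex"].map(lambda x: str(x).strip().upper()[:1]) == s
    ].dropna(subset=["age", column])
    if len(sub) < min_records:
        raise ValueError(
            f"need >= {min_records} {s} records with {column}, got {len(sub)}"
        )
    return sub


def fit_height_polynomial(records: pd.DataFrame, sex: str) -> CurveFit:
    """Quadratic height-vs-age fit: height = c0 + c1*age + c2*age².

    Three distinct ages are the mathematical minimum (exact interpolation);
    survey-scale fits are expected to bring far more.
    """
    sub = _sex_subset(records, sex, "height_cm", min_records=3)
    age = sub["age"].to_numpy(float)
    X = np.column_stack([np.ones_like(age), age, age**2])
    beta, se, resid_sd = _ols(X, sub["height_cm"].to_numpy(float))
    return CurveFit(tuple(beta), tuple(se), resid_sd)


def fit_weight_exponential(records: pd.DataFrame, sex: str) -> CurveFit:
    """Exponential weight-vs-age fit, weight = a*exp(b*age), via OLS on logs.

    Returns (a, b); the residual scale is the lognormal CV implied by the
    log-scale residual SD.
    """
    sub = _sex_subset(records, sex, "weight_kg", min_records=2)
    if (sub["weight_kg"] <= 0).any():
        raise ValueError("weights must be positive")
    age = sub["age"].to_numpy(float)
    X = np.column_stack([np.ones_like(age), age])
    beta, se, resid_sd = _ols(X, np.log(sub["weight_kg"].to_numpy(float)))
    a, b = np.exp(beta[0]), beta[1]
    # delta-method SE for a; b's SE is direct
    return CurveFit(
        (float(a), float(b)),
        (float(a * se[0]), float(se[1])),
        float(np.sqrt(np.expm1(resid_sd**2))),
    )


def percentile(values: Sequence[float], q: float) -> float:
    """Percentile with linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    return float(np.percentile(arr, q, method="linear"))


_SUMMARY_VARS = {
    "height_cm": "height_cm",
    "weight_kg": "weight_kg",
    "cardiac_output_l_h": "cardiac_output_l_h",
    "serum_creatinine_umol_l": "serum_creatinine_umol_l",
}


def summarize_population(
    subjects: Sequence[VirtualSubject] | pd.DataFrame,
    bands: tuple[str, ...] = (BAND_LOW, BAND_HIGH),
) -> pd.DataFrame:
    """Band-stratified mean/SD/5%/95% summary plus per-sex organ weights.

    Accepts either a list of virtual subjects or an exported population
    table.  Returns a tidy frame with one row per variable × stratum.
    """
    if not isinstance(subjects, pd.DataFrame):
        from .population import population_frame

        if len(subjects) == 0:
            raise ValueError("empty population")
        df = population_frame(subjects)
    else:
        df = subjects
    if df.empty:
        raise ValueError("empty population")

    df = df.assign(band=df["age_yr"].map(age_band))
    rows = []
    for var in _SUMMARY_VARS:
        for band in bands:
            vals = df.loc[df["band"] == band, var].dropna()
            if vals.empty:
                continue
            rows.append({
                "variable": var, "stratum": band, "n": len(vals),
                "mean": vals.mean(), "sd": vals.std(ddof=1),
                "p5": percentile(vals, 5), "p95": percentile(vals, 95),
            })
    for var in ("liver_weight_g", "kidney_weight_g"):
        if var not in df.columns:
            continue
        for sex in ("M", "F"):
            vals = df.loc[df["sex"] == sex, var].dropna()
            if vals.empty:
                continue
            rows.append({
                "variable": var, "stratum": sex, "n": len(vals),
                "mean": vals.mean(), "sd": vals.std(ddof=1),
                "p5": percentile(vals, 5), "p95": percentile(vals, 95),
            })
    out = pd.DataFrame(rows)
    bad = out[(out["p5"] > out["mean"]) | (out["mean"] > out["p95"])]
    if not bad.empty:  # pragma: no cover - defensive
        raise AssertionError("summary violates p5 <= mean <= p95")
    return out


def format_summary(summary: pd.DataFrame) -> str:
    """Plain-text rendering of the summary table."""
    lines = [f"{'variable':<26}{'stratum':<9}{'n':>6}{'5%':>10}{'95%':>10}{'mean':>10}"]
    for _, r in summary.iterrows():
        lines.append(
            f"{r['variable']:<26}{r['stratum']:<9}{r['n']:>6d}"
            f"{r['p5']:>10.1f}{r['p95']:>10.1f}{r['mean']:>10.1f}"
        )
    return "\n".join(lines)
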