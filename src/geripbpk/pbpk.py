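"""Whole-body perfusion-limited PBPK engine.

The model has 12 perfused compartments (lung in series with cardiac
output, eleven parallel tissues including a balance-closing "rest"),
venous and arterial blood pools, an oral absorption depot feeding the
portal inflow of the liver, and two elimination sites: hepatic
(well-stirred, intrinsic clearance scaled from enzyme abundance via
MPPGL and liver weight) and renal (GFR-proportional clearance acting on
the kidney outflow).  Kinetics are linear throughout, so dose
superposition holds and AUC is inversely proportional to clearance.

Tissue:plasma partition coefficients are predicted from tissue
composition (water, neutral lipid, phospholipid, acidic-phospholipid
and protein content) given log P, ionisation class and plasma binding,
then multiplied by the drug's global Kp scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import tissues as T
from .drugs import DrugModel
from .population import VirtualSubject


# ---------------------------------------------------------------------------
# Partition coefficients (tissue-composition method)
# ---------------------------------------------------------------------------

def _ionisation(pka_acid: Sequence[float], pka_base: Sequence[float], ph: float) -> float:
    """1 + ionised:neutral ratios at a given pH (additive multi-pKa form)."""
    x = 1.0
    for p in pka_base:
        x += 10.0 ** (p - ph)
    for p in pka_acid:
        x += 10.0 ** (ph - p)
    return x


def _acidic_phospholipid_affinity(drug: DrugModel) -> float:
    """Back out the acidic-phospholipid association constant from the
    blood:plasma ratio via red-cell partitioning; clamped at zero when the
    measured B:P leaves no room for intracellular binding."""
    fu = drug.fu_plasma
    kpu_bc = (drug.blood_to_plasma - (1.0 - T.HEMATOCRIT)) / (T.HEMATOCRIT * fu)
    if kpu_bc <= 0:
        return 0.0
    p = 10.0 ** drug.log_p
    y = _ionisation(drug.pka_acid, drug.pka_base, T.PH_PLASMA)
    x_bc = _ionisation(drug.pka_acid, drug.pka_base, T.BLOOD_CELL["ph"])
    bc = T.BLOOD_CELL
    bound_free = (
        x_bc / y * bc["f_iw"]
        + (p * bc["f_nl"] + (0.3 * p + 0.7) * bc["f_np"]) / y
    )
    pka = max(drug.pka_base)
    ka = (kpu_bc - bound_free) * y / (bc["ap"] * 10.0 ** (pka - bc["ph"]))
    return max(ka, 0.0)


def predict_kp(drug: DrugModel, tissue: str, apply_scalar: bool = True) -> float:
    """Tissue:plasma partition coefficient for one tissue.

    Moderate-to-strong bases (basic pKa >= 7) use the acidic-phospholipid
    route; acids, weak bases, neutrals and zwitterions without a strong
    basic centre use the plasma-protein route (albumin for ionisable
    compounds, lipoprotein for neutrals).
    """
    if tissue == "blood":
        raise ValueError("blood is the reference compartment, not a tissue")
    if tissue not in T.COMPOSITION:
        raise ValueError(f"unknown tissue {tissue!r}")
    if drug.compound_class in ("acid", "base", "zwitterion") and not drug.pka:
        raise ValueError("ionisable compound requires pKa values")

    f_ew, f_iw, f_nl, f_np, ap, alb, lipo = T.COMPOSITION[tissue]
    p = 10.0 ** drug.log_p
    fu = drug.fu_plasma
    y = _ionisation(drug.pka_acid, drug.pka_base, T.PH_PLASMA)
    x_iw = _ionisation(drug.pka_acid, drug.pka_base, T.PH_INTRACELLULAR)
    lipid = (p * f_nl + (0.3 * p + 0.7) * f_np) / y

    if drug.is_moderate_base:
        ka_ap = _acidic_phospholipid_affinity(drug)
        pka = max(drug.pka_base)
        kpu = (
            f_ew + (x_iw / y) * f_iw + lipid
            + ka_ap * ap * 10.0 ** (pka - T.PH_INTRACELLULAR) / y
        )
    else:
        ratio = lipo if drug.compound_class == "neutral" else alb
        plasma_lipid = (
            p * T.PLASMA["f_nl"] + (0.3 * p + 0.7) * T.PLASMA["f_np"]
        ) / y
        protein = max(1.0 / fu - 1.0 - plasma_lipid, 0.0) * ratio
        kpu = f_ew + (x_iw / y) * f_iw + lipid + protein

    kp = fu * kpu
    if apply_scalar:
        kp *= drug.kp_scalar
    return kp


def all_kp(drug: DrugModel) -> dict[str, float]:
    return {t: predict_kp(drug, t) for t in T.TISSUES}


def vss(drug: DrugModel, subject: VirtualSubject) -> float:
    """Steady-state volume of distribution, L/kg, plasma-referenced:
    Vss = B:P * V_blood + sum Kp_t * V_t, divided by body weight."""
    kps = all_kp(drug)
    v = drug.blood_to_plasma * subject.blood_volume
    v += sum(kps[t] * subject.tissue_volumes[t] for t in T.TISSUES)
    return v / subject.weight


# ---------------------------------------------------------------------------
# Clearance building blocks
# ---------------------------------------------------------------------------

def ivive_hepatic_clint(drug: DrugModel, subject: VirtualSubject) -> float:
    """Whole-liver unbound intrinsic clearance, L/h, scaled from per-pmol
    in vitro values via enzyme abundance, MPPGL and liver weight."""
    routes = drug.route("enzymatic")
    if not routes:
        raise ValueError(f"{drug.name} has no enzymatic route")
    total_ul_min = 0.0
    for r in routes:
        if r.enzyme not in subject.cyp_abundance:
            raise ValueError(f"no abundance for enzyme {r.enzyme!r}")
        total_ul_min += (
            r.clint_per_pmol
            * subject.cyp_abundance[r.enzyme]  # pmol/mg
            * subject.mppgl                    # mg/g
            * subject.liver_weight             # g
        )
    return total_ul_min * 60.0 / 1e6  # µL/min -> L/h


def well_stirred_hepatic_cl(qh: float, fu_blood: float, clint_u: float) -> float:
    """Well-stirred liver model: CLh = Qh*fu_b*CLint / (Qh + fu_b*CLint)."""
    if qh < 0 or fu_blood < 0 or clint_u < 0:
        raise ValueError("well-stirred inputs must be non-negative")
    denom = qh + fu_blood * clint_u
    if denom == 0:
        return 0.0
    return qh * fu_blood * clint_u / denom


def renal_cl_scaled(drug: DrugModel, subject: VirtualSubject) -> float:
    """Renal clearance, L/h, scaled in proportion to the subject's GFR."""
    routes = drug.route("renal")
    if not routes:
        raise ValueError(f"{drug.name} has no renal route")
    total = 0.0
    for r in routes:
        if r.gfr_ref <= 0:
            raise ValueError("gfr_ref must be positive")
        total += r.clr_ref * subject.gfr / r.gfr_ref
    return total


# ---------------------------------------------------------------------------
# Dosing and simulation
# ---------------------------------------------------------------------------

Route = Literal["oral", "iv_bolus", "iv_infusion"]


@dataclass(frozen=True)
class DoseEvent:
    route: Route
    amount: float  # mg
    start: float = 0.0  # h
    infusion_duration: float = 0.0  # h, infusions only

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.route == "iv_infusion" and self.infusion_duration <= 0:
            raise ValueError("infusion requires a positive duration")
        if self.start < 0:
            raise ValueError("dose start must be >= 0")


@dataclass
class EngineSettings:
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf  # h
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be positive")


@dataclass
class ConcentrationProfile:
    """Plasma concentration-time course plus bookkeeping for mass balance."""

    time_h: np.ndarray
    conc_mg_l: np.ndarray  # venous plasma, mg/L
    dose_total: float  # mg administered (incl. unabsorbed oral fraction)
    mass_balance_error: float  # max relative error over the grid
    amounts: dict[str, np.ndarray] = field(default_factory=dict)


_STATE = ["depot", "venous", "arterial"] + T.TISSUES + ["elim_hepatic", "elim_renal"]
_IDX = {name: i for i, name in enumerate(_STATE)}
_PARALLEL = [t for t in T.PERFUSED if t not in ("gut", "spleen", "liver")]


def simulate_concentration(
    subject: VirtualSubject,
    drug: DrugModel,
    doses: Sequence[DoseEvent],
    settings: Optional[EngineSettings] = None,
    grid: Optional[np.ndarray] = None,
    kp_overrides: Optional[dict[str, float]] = None,
) -> ConcentrationProfile:
    """Integrate the whole-body model for one subject, drug and regimen.

    `grid` is the output time grid (h); the default is 0-24 h at 0.25 h.
    `kp_overrides` substitutes specific tissue Kp values (used by the
    degenerate closed-form checks); a Kp of exactly 0 makes that tissue a
    pass-through with no drug uptake.
    """
    settings = settings or EngineSettings()
    if grid is None:
        grid = np.arange(0.0, 24.0 + 1e-9, 0.25)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    if any(d.route == "oral" for d in doses) and drug.absorption is None:
        raise ValueError(f"{drug.name} has no absorption block for oral dosing")
    if not doses:
        raise ValueError("at least one dose event required")

    bp = drug.blood_to_plasma
    fu = drug.fu_plasma
    kps = all_kp(drug)
    if kp_overrides:
        kps.update(kp_overrides)
    if kps["liver"] <= 0:
        raise ValueError("liver Kp must be positive")

    vol = subject.tissue_volumes
    flow = subject.tissue_flows
    v_blood = subject.blood_volume
    v_ven = v_blood * T.VENOUS_FRACTION
    v_art = v_blood - v_ven
    q_co = subject.cardiac_output
    q_liv_total = flow["liver"] + flow["gut"] + flow["spleen"]

    clint_u = ivive_hepatic_clint(drug, subject) if drug.route("enzymatic") else 0.0
    cl_renal = renal_cl_scaled(drug, subject) if drug.route("renal") else 0.0
    cl_systemic = sum(r.cl_iv for r in drug.route("systemic"))
    ka = drug.absorption.ka if drug.absorption else 0.0

    par_q = np.array([flow[t] for t in _PARALLEL])
    par_v = np.array([vol[t] for t in _PARALLEL])
    par_kp = np.array([kps[t] for t in _PARALLEL])
    par_idx = np.array([_IDX[t] for t in _PARALLEL])
    par_active = par_kp > 0.0
    # blood-referenced outflow factor: C_out_blood = A/V * BP/Kp
    par_fac = np.where(par_active, bp / np.where(par_active, par_kp, 1.0), 0.0)

    i_dep, i_ven, i_art = _IDX["depot"], _IDX["venous"], _IDX["arterial"]
    i_lung, i_gut, i_spl, i_liv = (
        _IDX["lung"], _IDX["gut"], _IDX["spleen"], _IDX["liver"],
    )
    i_kid, i_eh, i_er = _IDX["kidney"], _IDX["elim_hepatic"], _IDX["elim_renal"]
    lung_active = kps["lung"] > 0

    def rhs(t: float, y: np.ndarray, inf_rate: float) -> np.ndarray:
        dy = np.zeros_like(y)
        c_ven = y[i_ven] / v_ven
        c_art = y[i_art] / v_art

        # lung in series with cardiac output
        if lung_active:
            c_lung_out = y[i_lung] / vol["lung"] * bp / kps["lung"]
            dy[i_lung] = q_co * (c_ven - c_lung_out)
        else:
            c_lung_out = c_ven
        dy[i_art] = q_co * c_lung_out - q_co * c_art

        # parallel non-splanchnic tissues
        c_par_out = np.where(par_active, y[par_idx] / par_v * par_fac, c_art)
        dy[par_idx] = np.where(par_active, par_q * (c_art - c_par_out), 0.0)
        venous_in = float(par_q @ c_par_out)

        # splanchnic loop: gut and spleen drain into the liver
        c_out = {}
        for tis, idx in (("gut", i_gut), ("spleen", i_spl)):
            if kps[tis] > 0:
                c_out[tis] = y[idx] / vol[tis] * bp / kps[tis]
                dy[idx] = flow[tis] * (c_art - c_out[tis])
            else:
                c_out[tis] = c_art
        c_liv_out = y[i_liv] / vol["liver"] * bp / kps["liver"]
        liver_in = (
            flow["liver"] * c_art
            + flow["gut"] * c_out["gut"]
            + flow["spleen"] * c_out["spleen"]
            + ka * y[i_dep]
        )
        hepatic_elim = fu * clint_u * (y[i_liv] / vol["liver"]) / kps["liver"]
        dy[i_liv] = liver_in - q_liv_total * c_liv_out - hepatic_elim
        venous_in += q_liv_total * c_liv_out

        # renal elimination acts on the kidney outflow (plasma-referenced);
        # with a pass-through kidney it is taken from the venous return
        if kps["kidney"] > 0:
            renal_elim = cl_renal * (y[i_kid] / vol["kidney"]) / kps["kidney"]
            dy[i_kid] -= renal_elim
            venous_correction = 0.0
        else:
            renal_elim = cl_renal * c_art / bp
            venous_correction = renal_elim

        systemic_elim = cl_systemic * c_ven / bp
        dy[i_ven] = (
            venous_in - q_co * c_ven + inf_rate - systemic_elim - venous_correction
        )
        dy[i_dep] = -ka * y[i_dep]
        dy[i_eh] = hepatic_elim
        dy[i_er] = renal_elim + systemic_elim
        return dy

    # --- event segmentation -------------------------------------------------
    t_end = float(grid[-1])
    breaks = {0.0, t_end}
    for d in doses:
        breaks.add(d.start)
        if d.route == "iv_infusion":
            breaks.add(min(d.start + d.infusion_duration, t_end))
    times = sorted(b for b in breaks if 0.0 <= b <= t_end)

    y = np.zeros(len(_STATE))
    out = np.full(grid.size, np.nan)
    amounts = {name: np.full(grid.size, np.nan) for name in _STATE}
    administered = np.zeros(grid.size)  # effective dose delivered by time t

    # reported concentration: arterial ("systemic") plasma — the post-lung
    # mixed concentration, the closest analogue of peripheral sampling
    def record(indices: np.ndarray, ys: np.ndarray, seg_admin) -> None:
        for j, gi in enumerate(indices):
            out[gi] = ys[i_art, j] / v_art / bp
            for name, k in _IDX.items():
                amounts[name][gi] = ys[k, j]
            administered[gi] = seg_admin(grid[gi])

    delivered = 0.0  # running effective dose at segment start
    for a, b in zip(times[:-1], times[1:]):
        # apply instantaneous events at segment start
        for d in doses:
            if d.start == a:
                if d.route == "iv_bolus":
                    y[i_ven] += d.amount
                    delivered += d.amount
                elif d.route == "oral":
                    assert drug.absorption is not None
                    y[i_dep] += d.amount * drug.absorption.fa
                    delivered += d.amount * drug.absorption.fa
        inf_rate = sum(
            d.amount / d.infusion_duration
            for d in doses
            if d.route == "iv_infusion"
            and d.start <= a and a < d.start + d.infusion_duration
        )
        d0 = delivered

        def seg_admin(t: float, rate=inf_rate, a0=a, base=d0) -> float:
            return base + rate * (t - a0)

        mask = (grid >= a - 1e-12) & (grid <= b + 1e-12)
        t_eval = grid[mask]
        seg_t = np.unique(np.concatenate(([a], t_eval, [b])))
        sol = solve_ivp(
            rhs, (a, b), y, t_eval=seg_t, args=(inf_rate,),
            method=settings.method, rtol=settings.rtol, atol=settings.atol,
            max_step=settings.max_step,
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed for {drug.name} in [{a}, {b}] h: {sol.message}"
            )
        keep = np.isin(sol.t, t_eval)
        record(np.flatnonzero(mask), sol.y[:, keep], seg_admin)
        y = sol.y[:, -1]
        delivered += inf_rate * (b - a)

    if np.any(out < -1e-6 * max(out.max(), 1e-12)):
        raise RuntimeError("negative concentrations beyond solver tolerance")
    out = np.clip(out, 0.0, None)

    total = np.sum([amounts[n] for n in _STATE], axis=0)
    scale = max(float(np.max(administered)), 1e-12)
    mb_err = float(np.max(np.abs(total - administered)) / scale)

    dose_total = sum(d.amount for d in doses)
    return ConcentrationProfile(
        time_h=grid, conc_mg_l=out, dose_total=dose_total,
        mass_balance_error=mb_err, amounts=amounts,
    )
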