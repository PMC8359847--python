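"""Noncompartmental analysis of concentration-time profiles.

AUC uses the linear-up/log-down trapezoid; the terminal slope λz comes
from a log-linear regression over the last 3-8 post-peak positive
samples, choosing the window with the best adjusted R².  AUC to
infinity adds C_last/λz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class NCAResult:
    auc_0_t: float       # h·(mg/L)
    auc_0_inf: Optional[float]
    cmax: float          # mg/L
    tmax: float          # h
    lambda_z: Optional[float]  # 1/h
    extrapolated_fraction: Optional[float]
    reliable_terminal: bool


def _trapezoid_segment(t0, t1, c0, c1, log_down: bool) -> float:
    dt = t1 - t0
    if log_down and c1 < c0 and c0 > 0 and c1 > 0:
        # log trapezoid on the descending limb
        return dt * (c0 - c1) / np.log(c0 / c1)
    return dt * 0.5 * (c0 + c1)


def nca_auc(
    time_h: np.ndarray, conc: np.ndarray, method: str = "linear-up/log-down"
) -> tuple[float, Optional[float]]:
    """AUC0-t and AUC0-inf; AUC0-inf is None when no λz is estimable.

    `method` selects the trapezoid rule: the default linear-up/log-down
    (exact for exponential decay on clean data) or plain "linear"
    (unbiased under symmetric measurement noise).
    """
    r = nca(time_h, conc, method=method)
    return r.auc_0_t, r.auc_0_inf


def terminal_slope(
    time_h: np.ndarray, conc: np.ndarray, min_points: int = 3, max_points: int = 8
) -> tuple[Optional[float], bool]:
    """λz (1/h) from the best log-linear terminal window; flags reliability.

    Only post-peak positive samples are eligible; a non-negative slope or
    fewer than `min_points` usable samples makes the estimate unreliable.
    """
    t = np.asarray(time_h, float)
    c = np.asarray(conc, float)
    i_peak = int(np.argmax(c))
    tail_t, tail_c = t[i_peak:], c[i_peak:]
    keep = tail_c > 0
    tail_t, tail_c = tail_t[keep], tail_c[keep]
    if tail_t.size < min_points + 1:  # peak itself is excluded from windows
        return None, False
    rising_tail = tail_c.size >= 2 and tail_c[-1] > tail_c[-2]

    best: tuple[float, float] | None = None  # (adj_r2, lambda_z)
    logc = np.log(tail_c)
    for k in range(min_points, min(max_points, tail_t.size - 1) + 1):
        tt, yy = tail_t[-k:], logc[-k:]
        slope, intercept = np.polyfit(tt, yy, 1)
        if slope >= 0:
            continue
        fitted = intercept + slope * tt
        ss_res = float(np.sum((yy - fitted) ** 2))
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        if ss_tot == 0:
            continue
        adj_r2 = 1.0 - (ss_res / ss_tot) * (k - 1) / (k - 2)
        if best is None or adj_r2 > best[0]:
            best = (adj_r2, -slope)
    if best is None:
        return None, False
    # a rising terminal limb makes any extrapolation suspect
    return best[1], not rising_tail


def nca(
    time_h: np.ndarray, conc: np.ndarray, method: str = "linear-up/log-down"
) -> NCAResult:
    if method not in ("linear-up/log-down", "linear"):
        raise ValueError(f"unknown AUC method {method!r}")
    log_down = method == "linear-up/log-down"
    t = np.asarray(time_h, float)
    c = np.asarray(conc, float)
    if t.ndim != 1 or t.size != c.size or t.size < 3:
        raise ValueError("need matching 1-D arrays with >= 3 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("negative concentrations")

    auc_t = sum(
        _trapezoid_segment(t[i], t[i + 1], c[i], c[i + 1], log_down)
        for i in range(t.size - 1)
    )
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])

    lam, reliable = terminal_slope(t, c)
    auc_inf = None
    extrap = None
    if lam is not None and c[-1] > 0:
        auc_inf = auc_t + float(c[-1]) / lam
        extrap = (auc_inf - auc_t) / auc_inf
    return NCAResult(
        auc_0_t=float(auc_t), auc_0_inf=auc_inf, cmax=cmax, tmax=tmax,
        lambda_z=lam, extrapolated_fraction=extrap, reliable_terminal=reliable,
    )


def nca_cmax(time_h: np.ndarray, conc: np.ndarray) -> tuple[float, float]:
    """(Cmax, Tmax) over the sampled grid; ties resolve to the first time."""
    t = np.asarray(time_h, float)
    c = np.asarray(conc, float)
    i = int(np.argmax(c))
    return float(c[i]), float(t[i])
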