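"""Analytic regime classification from dimensional analysis.

The effective system size is the physical length measured in units of the
intrinsic reaction-diffusion length sqrt(d/r):

    ell_eff = L * sqrt(r / d)

Comparing it with the reach of rescue fronts (2*u*tau0, how far a front
travels while local recovery completes) and the front width lam yields the
regime chain: Isolated when ell_eff > 2*u*tau0, Mixing when ell_eff < lam,
Rescue in between.  When 2*u*tau0 < lam the chain degenerates: the Rescue
window is empty and the Isolated/Mixing comparison decides.

Note on units: d carries length^2/time, so the square root in ell_eff is
forced by nondimensionality (the transition curves d* scale as L^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["RegimePrediction", "effective_size", "classify", "transition_curves"]


@dataclass(frozen=True)
class RegimePrediction:
    """Effective size, the predicted regime, and the two transition thresholds."""

    ell_eff: float
    regime: Literal["IR", "RR", "MR"]
    thr_IR_RR: float  # 2 * u * tau0
    thr_RR_MR: float  # lam


def effective_size(L: float, r: float, d: float) -> float:
    """Effective (nondimensional) system size L * sqrt(r/d); inf when d = 0."""
    if L <= 0 or r <= 0 or d < 0:
        raise ValueError("L and r must be positive, d nonnegative")
    if d == 0:
        return math.inf
    return L * math.sqrt(r / d)


def classify(ell_eff: float, u: float, lam: float, tau0: float) -> RegimePrediction:
    """Classify a system by its effective size against the regime thresholds.

    tau0 may be inf (local recovery never completes): the system is then
    never Isolated, since fronts always outrun an infinite local wait.
    """
    if not (u > 0 and lam > 0):
        raise ValueError("u and lam must be positive")
    if not tau0 > 0:
        raise ValueError("tau0 must be positive")
    thr_ir_rr = 2.0 * u * tau0
    if thr_ir_rr >= lam:
        if ell_eff > thr_ir_rr:
            regime = "IR"
        elif ell_eff < lam:
            regime = "MR"
        else:
            regime = "RR"
    else:
        # degenerate ordering: no Rescue window, IR/MR comparison decides
        regime = "IR" if ell_eff > math.sqrt(thr_ir_rr * lam) else "MR"
    return RegimePrediction(ell_eff=ell_eff, regime=regime,
                            thr_IR_RR=thr_ir_rr, thr_RR_MR=lam)


def transition_curves(
    L: Union[float, Sequence[float]],
    r: float,
    u: float,
    lam: float,
    tau0: float,
) -> pd.DataFrame:
    """Critical dispersal values of the two regime transitions.

    Solving L*sqrt(r/d) = 2*u*tau0 and L*sqrt(r/d) = lam for d gives

        d_IR_RR = r * (L / (2*u*tau0))**2      (Isolated -> Rescue)
        d_RR_MR = r * (L / lam)**2             (Rescue -> Mixing)

    so in the (d, L) plane both transitions are straight lines L ~ sqrt(d).
    Returns a DataFrame with columns axis_value, d_IR_RR, d_RR_MR; when
    tau0 = inf the IR-RR threshold is 0 (the system is never Isolated).
    """
    Ls = np.atleast_1d(np.asarray(L, dtype=float))
    with np.errstate(divide="ignore"):
        d_ir_rr = r * (Ls / (2.0 * u * tau0)) ** 2 if math.isfinite(tau0) else np.zeros_like(Ls)
    d_rr_mr = r * (Ls / lam) ** 2
    return pd.DataFrame(
        {"axis_value": Ls, "d_IR_RR": d_ir_rr, "d_RR_MR": d_rr_mr}
    )
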