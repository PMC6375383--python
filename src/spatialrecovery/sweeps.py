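"""Parameter-sweep engines: return-time maps over disturbance space and
regime-contribution maps over (dispersal x {L, gamma, rho}) space.

Sweeps are deterministic given their configuration; results come back as a
:class:`SweepResult` holding a tidy DataFrame (one row per cell) plus full
parameter provenance.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .disturbance import Disturbance
from .metrics import (
    NOT_RECOVERED,
    decompose,
    front_metrics,
    local_timescale,
    return_time as _return_time,
)
from .model import Domain, GrowthModel, ModelParams, StateField, default_lattice, integrate
from .disturbance import apply_disturbance
from .regimes import classify, effective_size

__all__ = ["SweepResult", "return_time_map", "regime_map"]


@dataclass
class SweepResult:
    """Tidy sweep output: named axis grids, per-cell records, provenance."""

    axes: Dict[str, np.ndarray]
    cells: pd.DataFrame
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_expected = int(np.prod([len(v) for v in self.axes.values()]))
        if len(self.cells) != n_expected:
            raise ValueError(
                f"cell count {len(self.cells)} != grid product {n_expected}"
            )

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def _params_meta(base: ModelParams) -> Dict[str, object]:
    return {
        "r": base.r,
        "d": base.d,
        "growth_kind": base.growth.kind,
        "K": base.growth.K,
        "gamma": base.growth.gamma,
        "allee": base.growth.allee,
    }


def return_time_map(
    d: float,
    sigmas: Sequence[float],
    rhos: Sequence[float],
    base: ModelParams,
    domain: Domain,
    threshold: float = 0.99,
    t_max: Optional[float] = None,
) -> SweepResult:
    """Return time over the (sigma, rho) disturbance grid at fixed dispersal d.

    Each cell records the realized extent (after rounding to whole cells),
    the strength s, the return time and its log10.  Cells that never recover
    within the horizon are reported as missing (NaN), not clamped.
    """
    sigmas = np.asarray(list(sigmas), dtype=float)
    rhos = np.asarray(list(rhos), dtype=float)
    params = base.with_d(d)
    K = params.growth.K
    eq = StateField.uniform(domain, K)

    rows = []
    for sg in sigmas:
        for rh in rhos:
            dist = Disturbance(sigma=sg, rho=rh)
            disturbed = apply_disturbance(eq, dist, domain, params.growth)
            try:
                from .metrics import _run_until_recovered

                traj = _run_until_recovered(disturbed, params, domain, threshold, t_max)
                T = _return_time(traj, K, threshold)
            except RuntimeError:
                T = NOT_RECOVERED
            rows.append(
                {
                    "sigma": sg,
                    "rho": rh,
                    "sigma_realized": dist.realized_sigma(domain),
                    "s": sg * rh,
                    "d": d,
                    "return_time": T if math.isfinite(T) else np.nan,
                    "log10_return_time": math.log10(T) if math.isfinite(T) and T > 0 else np.nan,
                }
            )
    return SweepResult(
        axes={"sigma": sigmas, "rho": rhos},
        cells=pd.DataFrame(rows),
        meta={**_params_meta(params), "threshold": threshold},
    )


def regime_map(
    d_grid: Sequence[float],
    y_axis: Literal["L", "gamma", "rho"],
    y_grid: Sequence[float],
    base: ModelParams,
    L: float = 100.0,
    sigma: float = 0.5,
    rho: float = 0.9,
    eps_mix: float = 0.01,
    max_cells: int = 2048,
) -> SweepResult:
    """IR/RR/MR contributions over a (d, y) grid, y in {L, gamma, rho}.

    For every y value the transition thresholds are recomputed from measured
    front metrics and tau0 (they depend on gamma and rho but not on L), and
    each cell carries both the simulated decomposition and the analytic
    regime prediction.
    """
    d_grid = np.asarray(list(d_grid), dtype=float)
    y_grid = np.asarray(list(y_grid), dtype=float)
    if np.any(d_grid <= 0):
        raise ValueError("d grid must be positive (log-spaced)")

    rows = []
    for y in y_grid:
        L_y, sigma_y, rho_y, growth_y = L, sigma, rho, base.growth
        if y_axis == "L":
            L_y = y
        elif y_axis == "gamma":
            growth_y = dataclasses.replace(base.growth, gamma=y)
        elif y_axis == "rho":
            rho_y = y
        else:
            raise ValueError(f"unknown y_axis {y_axis!r}")

        # front metrics at a reference dispersal: u and lam are d-free by
        # construction (nondimensionalized), so one measurement per y serves
        fm = front_metrics(
            dataclasses.replace(base, d=1.0, growth=growth_y), rho=rho_y
        )
        tau0 = local_timescale(growth_y, rho_y).tau0
        dist = Disturbance(sigma=sigma_y, rho=rho_y)

        for d in d_grid:
            params = dataclasses.replace(base, d=d, growth=growth_y)
            domain = default_lattice(L_y, params, max_cells=max_cells)
            dec = decompose(params, domain, dist, eps_mix=eps_mix)
            pred = classify(effective_size(L_y, params.r, d), fm.u, fm.lam, tau0)
            rows.append(
                {
                    "d": d,
                    y_axis: y,
                    "L": L_y,
                    "gamma": growth_y.gamma if growth_y.kind == "power_logistic" else np.nan,
                    "sigma": sigma_y,
                    "rho": rho_y,
                    "return_time": dec.return_time,
                    "mixing_time": dec.mixing_time if math.isfinite(dec.mixing_time) else np.nan,
                    "f_IR": dec.f_IR,
                    "f_RR": dec.f_RR,
                    "f_MR": dec.f_MR,
                    "dominant": dec.dominant,
                    "u": fm.u,
                    "lam": fm.lam,
                    "tau0": tau0 if math.isfinite(tau0) else np.nan,
                    "ell_eff": pred.ell_eff,
                    "predicted_regime": pred.regime,
                    "d_IR_RR": base.r * (L_y / (2 * fm.u * tau0)) ** 2 if math.isfinite(tau0) else 0.0,
                    "d_RR_MR": base.r * (L_y / fm.lam) ** 2,
                }
            )
    return SweepResult(
        axes={"d": d_grid, y_axis: y_grid},
        cells=pd.DataFrame(rows),
        meta={**_params_meta(base), "y_axis": y_axis, "sigma": sigma,
              "rho": rho, "L": L, "eps_mix": eps_mix},
    )
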