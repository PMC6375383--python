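"""Recovery metrics: return time, mixing time, the Isolated/Rescue/Mixing
decomposition, the local (non-spatial) timescale tau0, and front metrics.

The three recovery regimes are quantified operationally:

* Isolated Regime (IR) — recovery that a dispersal-free twin of the system
  would have achieved on its own.
* Mixing Regime (MR) — recovery occurring after the mixing time, once
  dispersal has homogenized the system.
* Rescue Regime (RR) — the remainder: recovery carried by fronts of biomass
  propagating from undisturbed into disturbed regions.

The analytic transition predictions (see :mod:`spatialrecovery.regimes`)
are built from three nondimensional quantities measured here: the front
speed ``u`` (in units of sqrt(r*d)), the front width ``lam`` (in units of
sqrt(d/r)), and the dispersal-free recovery time ``tau0`` (in units of 1/r).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .disturbance import Disturbance, apply_disturbance
from .model import Domain, GrowthModel, ModelParams, StateField, Trajectory, integrate

__all__ = [
    "RecoveryDecomposition",
    "LocalTimescale",
    "FrontMetrics",
    "NOT_RECOVERED",
    "return_time",
    "mixing_time",
    "decompose",
    "local_timescale",
    "front_metrics",
]

#: sentinel for "biomass never crossed the threshold within the horizon"
NOT_RECOVERED = math.inf


@dataclass(frozen=True)
class RecoveryDecomposition:
    """Return time plus the biomass-recovery fractions of the three regimes."""

    return_time: float
    mixing_time: float
    f_IR: float
    f_RR: float
    f_MR: float

    def __post_init__(self) -> None:
        total = self.f_IR + self.f_RR + self.f_MR
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"regime fractions must sum to 1, got {total}")
        for name in ("f_IR", "f_RR", "f_MR"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def dominant(self) -> str:
        """Regime with the largest recovery fraction: 'IR', 'RR' or 'MR'."""
        fracs = {"IR": self.f_IR, "RR": self.f_RR, "MR": self.f_MR}
        return max(fracs, key=fracs.get)


@dataclass(frozen=True)
class LocalTimescale:
    """Dispersal-free recovery time tau0, nondimensionalized by r."""

    tau0: float

    def __post_init__(self) -> None:
        if not self.tau0 > 0:
            raise ValueError(f"tau0 must be positive, got {self.tau0}")


@dataclass(frozen=True)
class FrontMetrics:
    """Nondimensional front speed u (units sqrt(r d)) and width lam (units sqrt(d/r))."""

    u: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.u > 0 and self.lam > 0):
            raise ValueError("front speed and width must be positive")


def _first_crossing(times: np.ndarray, values: np.ndarray, level: float,
                    above: bool = True) -> float:
    """First time ``values`` crosses ``level`` (linearly interpolated)."""
    ok = values >= level if above else values <= level
    if ok[0]:
        return float(times[0])
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return NOT_RECOVERED
    i = idx[0]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(times[i])
    frac = (level - v0) / (v1 - v0)
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))


def return_time(traj: Trajectory, K: float, threshold: float = 0.99) -> float:
    """Time for total biomass to regain ``threshold`` of its equilibrium value.

    The equilibrium biomass is K times the system measure.  Returns
    :data:`NOT_RECOVERED` (inf) if the trajectory never crosses within its
    horizon.  Times are measured from the start of the trajectory.
    """
    target = threshold * K * traj.states.shape[1] * traj.site_measure
    t = _first_crossing(traj.times, traj.total_biomass, target)
    return t - traj.times[0] if t != NOT_RECOVERED else NOT_RECOVERED


def mixing_time(traj: Trajectory, K: float, eps: float = 0.01) -> float:
    """First time the spatial spread max(N) - min(N) falls below eps*K.

    Returns inf if the system never homogenizes within the horizon.
    """
    spread = traj.states.max(axis=1) - traj.states.min(axis=1)
    t = _first_crossing(traj.times, spread, eps * K, above=False)
    return t - traj.times[0] if t != NOT_RECOVERED else NOT_RECOVERED


def _run_until_recovered(
    state0: StateField,
    params: ModelParams,
    domain: Domain,
    threshold: float,
    t_max: Optional[float],
    n_store: int = 1500,
    t_cap: float = 1e7,
) -> Trajectory:
    """Integrate from ``state0``, doubling the horizon until biomass recovers."""
    K = params.growth.K
    t = t_max if t_max is not None else 50.0 / params.r
    while True:
        traj = integrate(state0, params, domain, t_max=t, store_every=t / n_store)
        if return_time(traj, K, threshold) != NOT_RECOVERED:
            return traj
        if t_max is not None or t >= t_cap / params.r:
            raise RuntimeError(
                f"system did not recover to {threshold:.0%} of equilibrium biomass "
                f"by t={t:.3g}; increase t_max"
            )
        t *= 4.0


def decompose(
    params: ModelParams,
    domain: Domain,
    dist: Disturbance,
    eps_mix: float = 0.01,
    threshold: float = 0.99,
    t_max: Optional[float] = None,
) -> RecoveryDecomposition:
    """Attribute the recovered biomass to the Isolated/Rescue/Mixing regimes.

    Runs the full system and a dispersal-free (d = 0) twin from the same
    disturbed state.  With R(t) the recovered biomass of the full run, T its
    return time, t* = min(mixing time, T), and R0(t) the twin's recovery:

    * f_MR = [R(T) - R(t*)] / R(T) — recovery after homogenization,
    * f_IR = min(R0(t*), R(t*)) / R(T) — recovery the twin achieved alone,
    * f_RR = 1 - f_IR - f_MR — front-mediated rescue.

    Fractions are clipped to [0, 1] and renormalized.
    """
    K = params.growth.K
    eq = StateField.uniform(domain, K)
    disturbed = apply_disturbance(eq, dist, domain, params.growth)

    traj = _run_until_recovered(disturbed, params, domain, threshold, t_max)
    T = return_time(traj, K, threshold)
    t_mix = mixing_time(traj, K, eps_mix)
    horizon = float(traj.times[-1] - traj.times[0])

    B_dist = float(traj.total_biomass[0])
    R = lambda t: traj.biomass_at(traj.times[0] + t) - B_dist  # noqa: E731
    R_T = R(T)
    t_star = min(t_mix, T)

    if params.d == 0:
        # the twin is the run itself and mixing cannot be dispersal-driven
        f_IR, f_RR, f_MR = 1.0, 0.0, 0.0
        t_mix = NOT_RECOVERED
    else:
        twin = integrate(
            disturbed, params.with_d(0.0), domain,
            t_max=horizon, store_every=horizon / 1500,
        )
        R0 = lambda t: twin.biomass_at(twin.times[0] + t) - B_dist  # noqa: E731
        f_MR = max(0.0, R_T - R(t_star)) / R_T
        f_IR = min(R0(t_star), R(t_star)) / R_T
        f_RR = 1.0 - f_IR - f_MR
        f_IR, f_RR, f_MR = np.clip([f_IR, f_RR, f_MR], 0.0, 1.0)
        total = f_IR + f_RR + f_MR
        f_IR, f_RR, f_MR = f_IR / total, f_RR / total, f_MR / total

    return RecoveryDecomposition(
        return_time=T, mixing_time=t_mix, f_IR=float(f_IR), f_RR=float(f_RR), f_MR=float(f_MR)
    )


def local_timescale(
    growth: GrowthModel,
    rho: float,
    threshold: float = 0.99,
    tau_cap: float = 1e4,
) -> LocalTimescale:
    """Dispersal-free recovery time from N = (1-rho)K, in units of 1/r.

    Integrates dN/dtau = N F(N) (the r-scaled local dynamics) from the
    post-disturbance density until N = threshold*K; returns tau0 = inf if the
    threshold is not reached by ``tau_cap`` (e.g. rho = 1 with gamma > 0
    starts on the extinction fixed point).
    """
    if not 0 < rho <= 1:
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    K = growth.K
    N0 = (1.0 - rho) * K
    target = threshold * K
    if N0 >= target:
        return LocalTimescale(tau0=np.finfo(float).tiny)
    if growth.reaction(np.array([N0]))[0] <= 0:
        if rho == 1.0:
            warnings.warn(
                "rho = 1 leaves the site on the extinction fixed point; tau0 = inf",
                stacklevel=2,
            )
        return LocalTimescale(math.inf)

    event = lambda t, y: y[0] - target  # noqa: E731
    event.terminal = True
    event.direction = 1
    sol = solve_ivp(
        lambda t, y: growth.reaction(y),
        (0.0, tau_cap),
        [N0],
        events=event,
        rtol=1e-10,
        atol=1e-12 * K,
        max_step=tau_cap / 50,
    )
    if sol.t_events[0].size == 0:
        return LocalTimescale(math.inf)
    return LocalTimescale(float(sol.t_events[0][0]))


def _fit_speed(times: np.ndarray, positions: np.ndarray) -> Tuple[float, float]:
    """Linear fit of front position vs time over the middle 50% of the run."""
    t0, t1 = times[0], times[-1]
    lo, hi = t0 + 0.25 * (t1 - t0), t0 + 0.75 * (t1 - t0)
    sel = (times >= lo) & (times <= hi)
    t, x = times[sel], positions[sel]
    slope, icpt = np.polyfit(t, x, 1)
    resid = x - (slope * t + icpt)
    ss_tot = np.sum((x - x.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(r2)


def _crossing_position(x: np.ndarray, N: np.ndarray, level: float) -> float:
    """Rightmost downward crossing of ``level`` along the profile."""
    below = N < level
    idx = np.flatnonzero(~below[:-1] & below[1:])
    if idx.size == 0:
        return math.nan
    i = idx[-1]
    frac = (N[i] - level) / (N[i] - N[i + 1])
    return float(x[i] + frac * (x[i + 1] - x[i]))


def front_metrics(
    params: ModelParams,
    rho: float = 0.9,
    width_levels: Tuple[float, float] = (0.1, 0.9),
    domain_factor: float = 250.0,
    dx_factor: float = 0.05,
    min_r2: float = 0.99,
) -> FrontMetrics:
    """Measure the nondimensional front speed u and width lam.

    Simulates a step between the equilibrium N = K and the disturbed level
    N = (1-rho)K on a no-flux lattice auto-sized to ``domain_factor`` front
    widths sqrt(d/r), tracks the K/2 level set, fits its speed over the
    middle 50% of the run (u = speed / sqrt(r d)), and measures the width of
    a mid-run steady profile between the ``width_levels`` recovery fractions
    of the jump (lam = width / sqrt(d/r)).

    Raises if no steadily propagating front is detected (fit R^2 < min_r2).
    """
    if params.d <= 0:
        raise ValueError("front propagation requires d > 0")
    K = params.growth.K
    ell = math.sqrt(params.d / params.r)  # intrinsic front length scale
    L_dom = domain_factor * ell
    n = int(round(L_dom / (dx_factor * ell)))
    domain = Domain.lattice(L_dom, n, boundary="no_flux")
    x = domain.positions()

    N0 = np.where(x < 0.2 * L_dom, K, (1.0 - rho) * K)
    state = StateField(N0)
    jump0 = rho * K

    # Run in chunks until the front reaches 80% of the domain, the profile
    # flattens (the disturbed background recovers on its own and overtakes
    # the front), or the time cap expires.  The tracking level is the
    # midpoint between the instantaneous profile extremes, so a slowly
    # recovering background does not strand the level set.
    v_scale = math.sqrt(params.r * params.d)
    chunk = 0.05 * L_dom / v_scale
    times, positions, profiles = [], [], []
    t_cap = 40.0 * L_dom / v_scale
    flattened = False
    while (times[-1] if times else 0.0) < t_cap:
        traj = integrate(state, params, domain, t_max=chunk, store_every=chunk / 20)
        for ti, Ni in zip(traj.times, traj.states):
            lo, hi = Ni.min(), Ni.max()
            if hi - lo < 0.5 * jump0:
                flattened = True
                break
            pos = _crossing_position(x, Ni, 0.5 * (lo + hi))
            if math.isnan(pos):
                flattened = True
                break
            times.append(float(ti))
            positions.append(pos)
            profiles.append(Ni)
        state = traj.final
        if flattened or positions[-1] >= 0.8 * L_dom:
            break
    if len(times) < 8:
        raise RuntimeError("no steady front propagation detected (profile flattened)")

    speed, r2 = _fit_speed(np.asarray(times), np.asarray(positions))
    if r2 < min_r2 or speed <= 0:
        raise RuntimeError(
            f"no steady propagation: speed fit R^2 = {r2:.4f} < {min_r2}"
        )
    u = speed / v_scale

    # width of the steady profile: measured between the width_levels
    # fractions of the instantaneous jump, on a mid-run snapshot
    profile = profiles[int(0.75 * (len(profiles) - 1))]
    lo, hi = profile.min(), profile.max()
    x_low = _crossing_position(x, profile, lo + width_levels[0] * (hi - lo))
    x_high = _crossing_position(x, profile, lo + width_levels[1] * (hi - lo))
    if math.isnan(x_low) or math.isnan(x_high):
        raise RuntimeError("could not locate width levels on the front profile")
    lam = abs(x_low - x_high) / ell
    return FrontMetrics(u=u, lam=lam)
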