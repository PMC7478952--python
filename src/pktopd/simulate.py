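"""Forward simulation of PK/TO/PD trajectories under oral dosing.

Oral doses are applied as instantaneous boluses into the plasma
compartment; between dose times the coupled system is integrated with an
adaptive stiff-capable solver (LSODA) at tight tolerances.  Trajectories
report the post-dose state at dose times (right-continuous).

Besides the final binding-kinetics occupancy model, the two comparison
occupancy models evaluated during model development are available: a
direct-response Emax model (occupancy an instantaneous function of plasma
concentration) and an effect-compartment Emax model (occupancy driven by a
hypothetical compartment equilibrating with plasma at rate ``ke0``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    DOSE_UG_PER_MG,
    InhibitionForm,
    PDParams,
    PKParams,
    TOParams,
    pk_closed_form,
    to_equilibrium,
    tracer_concentration,
)

__all__ = [
    "DoseRegimen",
    "AltTOParams",
    "Trajectory",
    "SolverError",
    "simulate",
    "simulate_qd",
    "simulate_alt_to",
    "hysteresis_curve",
    "HysteresisResult",
    "cycle_extrema",
]

#: Default dense output step for simulated curves, h.
DEFAULT_GRID_STEP = 0.01

#: Default integrator tolerances.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SolverError(RuntimeError):
    """ODE integration failure; ``t_last`` is the last successful time."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last successful time: {t_last:g} h)")
        self.t_last = t_last


@dataclass(frozen=True)
class DoseRegimen:
    """Oral dosing schedule: a fixed dose given at each listed time.

    ``route`` is informational; oral doses enter the plasma compartment as
    instantaneous boluses (apparent oral parameterization).
    """

    dose_mg_kg: float
    times: tuple[float, ...] = (0.0,)
    route: str = "oral-as-bolus"

    def __post_init__(self) -> None:
        if self.dose_mg_kg < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose_mg_kg!r}")
        times = tuple(float(t) for t in self.times)
        if len(times) == 0 or times[0] < 0:
            raise ValueError("times must be non-empty with first >= 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        object.__setattr__(self, "times", times)

    @classmethod
    def once_daily(cls, dose_mg_kg: float, n_days: int) -> "DoseRegimen":
        if n_days < 1:
            raise ValueError("n_days must be >= 1")
        return cls(dose_mg_kg, tuple(24.0 * k for k in range(n_days)))


@dataclass(frozen=True)
class AltTOParams:
    """Parameters of the comparison occupancy models.

    ``direct_emax``: TO(t) = BRmax·Cp/(EC50 + Cp) with no lag.
    ``effect_compartment``: dCe/dt = ke0·(Cp − Ce),
    TO = BRmax·Ce/(EC50 + Ce).
    """

    model: str  # "direct_emax" | "effect_compartment"
    ec50: float
    brmax: float
    bltr: float
    ke0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model not in ("direct_emax", "effect_compartment"):
            raise ValueError(f"unknown TO model {self.model!r}")
        if not self.ec50 > 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50!r}")
        if not (0 < self.brmax <= 1):
            raise ValueError(f"brmax must lie in (0, 1], got {self.brmax!r}")
        if not self.bltr > 0:
            raise ValueError(f"bltr must be > 0, got {self.bltr!r}")
        if self.model == "effect_compartment":
            if self.ke0 is None or not self.ke0 > 0:
                raise ValueError(
                    "effect_compartment model requires ke0 > 0"
                )


@dataclass(frozen=True)
class Trajectory:
    """Simulated time courses of the observables on a common grid.

    ``dserine`` is ``None`` for occupancy-only simulations.  ``to_eq`` is
    the zero-lag (equilibrium/static) occupancy at the instantaneous plasma
    concentration, carried along as the hysteresis reference.
    """

    time: np.ndarray          # h
    cp: np.ndarray            # ng/mL
    to: np.ndarray            # fraction
    tracer: np.ndarray        # ng/g
    dserine: Optional[np.ndarray] = None   # nmol/g
    to_eq: Optional[np.ndarray] = None
    brmax: float = 1.0

    def __post_init__(self) -> None:
        n = self.time.size
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name in ("cp", "to", "tracer", "dserine", "to_eq"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (n,):
                raise ValueError(f"series {name!r} length differs from grid")
        if np.any((self.to < -1e-9) | (self.to > self.brmax + 1e-9)):
            raise ValueError("occupancy left [0, BRmax]")

    def to_frame(self) -> pd.DataFrame:
        """Tidy export (time_h, cp_ng_ml, to_frac, tracer_ng_g, dserine_nmol_g)."""
        return pd.DataFrame(
            {
                "time_h": self.time,
                "cp_ng_ml": self.cp,
                "to_frac": self.to,
                "tracer_ng_g": self.tracer,
                "dserine_nmol_g": (
                    self.dserine if self.dserine is not None
                    else np.full(self.time.size, np.nan)
                ),
            }
        )


def _superposed_cp(regimen: DoseRegimen, pk: PKParams, t: np.ndarray) -> np.ndarray:
    """Closed-form plasma concentration under multiple boluses.

    Plasma kinetics are linear, so the multi-dose curve is the sum of
    shifted single-bolus exponentials (right-continuous at dose times).
    """
    cp = np.zeros_like(t, dtype=float)
    for tau in regimen.times:
        mask = t >= tau
        cp[mask] += pk_closed_form(regimen.dose_mg_kg, pk, t[mask] - tau)
    return cp


def _default_grid(regimen: DoseRegimen, step: float) -> np.ndarray:
    t_end = regimen.times[-1] + 24.0
    return np.round(np.arange(0.0, t_end + step / 2, step), 9)


def simulate(
    regimen: DoseRegimen,
    pk: PKParams,
    to: TOParams,
    pd_params: PDParams,
    form: InhibitionForm = InhibitionForm.SCALED,
    grid: Optional[Sequence[float]] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the full PK/TO/PD system under the given regimen.

    The returned trajectory is evaluated exactly at ``grid`` (default: a
    dense 0.01 h grid covering one day past the last dose).  The tracer
    series is the affine displacement map of the occupancy series and
    ``to_eq`` the equilibrium occupancy at each instantaneous Cp.
    """
    form = InhibitionForm(form)
    grid = (
        _default_grid(regimen, DEFAULT_GRID_STEP)
        if grid is None
        else np.asarray(grid, dtype=float)
    )
    if np.any(np.diff(grid) <= 0) or grid[0] < 0:
        raise ValueError("grid must be strictly increasing and >= 0")
    if grid[0] > regimen.times[0]:
        raise ValueError("grid must start at or before the first dose")

    ke = pk.ke
    kin = pd_params.kin
    if form is InhibitionForm.SCALED:
        imax_eff = pd_params.imax / to.brmax
    else:
        imax_eff = pd_params.imax

    def f(t, y):
        ap, occ, ds = y
        cp = ap / pk.vp
        return (
            -ke * ap,
            to.kon * (to.brmax - occ) * cp - to.koff * occ,
            kin - pd_params.kout * ds * (1.0 - imax_eff * occ),
        )

    y = np.array([0.0, 0.0, pd_params.bl])
    out = np.empty((grid.size, 3))
    out[:] = np.nan
    # pre-dose portion of the grid is flat at the initial state
    pre = grid < regimen.times[0]
    out[pre] = y

    bolus = DOSE_UG_PER_MG * regimen.dose_mg_kg
    seg_ends = list(regimen.times[1:]) + [max(grid[-1], regimen.times[-1])]
    for i_seg, t0 in enumerate(regimen.times):
        y[0] += bolus
        t1 = seg_ends[i_seg]
        last = i_seg == len(regimen.times) - 1
        sel = (grid >= t0) & ((grid <= t1) if last else (grid < t1))
        if t1 > t0:
            # evaluate at the grid points of this segment plus both segment
            # endpoints, so the next bolus starts from the exact end state
            t_eval = np.union1d(grid[sel], [t0, t1])
            sol = solve_ivp(
                f, (t0, t1), y, method="LSODA", t_eval=t_eval,
                rtol=rtol, atol=atol,
            )
            if not sol.success:
                t_last = float(sol.t[-1]) if sol.t.size else t0
                raise SolverError(sol.message, t_last=t_last)
            idx = np.searchsorted(sol.t, grid[sel])
            out[sel] = sol.y.T[idx]
            y = sol.y[:, -1].copy()
        elif np.any(sel):
            out[sel] = y

    ap_series, to_series, pd_series = out.T
    to_series = np.clip(to_series, 0.0, to.brmax)
    cp_series = ap_series / pk.vp
    return Trajectory(
        time=grid,
        cp=cp_series,
        to=to_series,
        tracer=tracer_concentration(to_series, to.bltr),
        dserine=pd_series,
        to_eq=to_equilibrium(cp_series, to),
        brmax=to.brmax,
    )


def simulate_qd(
    dose_mg_kg: float,
    n_days: int,
    pk: PKParams,
    to: TOParams,
    pd_params: PDParams,
    form: InhibitionForm = InhibitionForm.SCALED,
    grid_step: float = DEFAULT_GRID_STEP,
) -> Trajectory:
    """Once-daily multiple-dose simulation over ``n_days`` days."""
    regimen = DoseRegimen.once_daily(dose_mg_kg, n_days)
    grid = np.round(
        np.arange(0.0, 24.0 * n_days + grid_step / 2, grid_step), 9
    )
    return simulate(regimen, pk, to, pd_params, form, grid=grid)


def cycle_extrema(traj: Trajectory, period: float = 24.0) -> pd.DataFrame:
    """Per-dosing-cycle trough/peak summary of each simulated series.

    Cycle ``k`` covers ``[k·period, (k+1)·period)``; the trough of a series
    is its minimum over the cycle (attained just before the next dose for
    decaying series).
    """
    n_cycles = int(np.ceil((traj.time[-1] + 1e-9) / period))
    rows = []
    for k in range(n_cycles):
        sel = (traj.time >= k * period) & (traj.time < (k + 1) * period)
        if k == n_cycles - 1:
            sel |= traj.time == traj.time[-1]
        if not np.any(sel):
            continue
        row = {"cycle": k + 1, "t_start_h": k * period}
        for name, series in (
            ("cp", traj.cp), ("to", traj.to), ("dserine", traj.dserine),
        ):
            if series is None:
                continue
            row[f"{name}_trough"] = float(np.min(series[sel]))
            row[f"{name}_peak"] = float(np.max(series[sel]))
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_alt_to(
    regimen: DoseRegimen,
    pk: PKParams,
    alt: AltTOParams,
    grid: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Simulate the occupancy/tracer observables of a comparison TO model.

    Both comparison models admit closed forms given the closed-form plasma
    curve: the direct model is an algebraic map of Cp, and the effect
    compartment is a linear ODE whose bolus response superposes.
    """
    grid = (
        _default_grid(regimen, DEFAULT_GRID_STEP)
        if grid is None
        else np.asarray(grid, dtype=float)
    )
    cp = _superposed_cp(regimen, pk, grid)
    if alt.model == "direct_emax":
        driver = cp
    else:
        ke = pk.ke
        ke0 = float(alt.ke0)
        driver = np.zeros_like(grid)
        c0 = DOSE_UG_PER_MG * regimen.dose_mg_kg / pk.vp
        for tau in regimen.times:
            dt = grid - tau
            mask = dt >= 0
            dtm = dt[mask]
            if abs(ke0 - ke) < 1e-12 * max(ke0, ke):
                ce = c0 * ke * dtm * np.exp(-ke * dtm)
            else:
                ce = c0 * ke0 / (ke0 - ke) * (
                    np.exp(-ke * dtm) - np.exp(-ke0 * dtm)
                )
            driver[mask] += ce
    occ = alt.brmax * driver / (alt.ec50 + driver)
    return Trajectory(
        time=grid,
        cp=cp,
        to=occ,
        tracer=tracer_concentration(occ, alt.bltr),
        dserine=None,
        to_eq=alt.brmax * cp / (alt.ec50 + cp),
        brmax=alt.brmax,
    )


@dataclass(frozen=True)
class HysteresisResult:
    """Concentration–occupancy hysteresis loop of a single-bolus trajectory.

    ``pairs`` are the time-ordered (Cp, TO) points.  ``signed_area`` is the
    shoelace area of the closed loop formed by the observed path and the
    zero-lag reference path (the equilibrium occupancy at the same
    instantaneous Cp), oriented so that the physiological case — occupancy
    lagging concentration, hence sitting above the reference on the
    declining limb — is positive and labelled ``"anticlockwise"``.
    ``"degenerate"`` marks a path that coincides with its reference (no
    kinetic lag, as for a direct-response model); ``"clockwise"`` the
    opposite loop sense (effect leading concentration).
    """

    pairs: np.ndarray
    signed_area: float
    orientation: str


def hysteresis_curve(traj: Trajectory) -> HysteresisResult:
    """Quantify the kinetic lag between plasma concentration and occupancy.

    After a bolus the plasma concentration declines monotonically, so the
    observed (Cp, TO) path alone never self-intersects; the hysteresis
    loop is the area swept between that path and the zero-lag reference
    curve ``TO_eq(Cp)`` carried by the trajectory.  A model with no lag
    retraces its reference exactly (zero area, ``degenerate``); slow
    binding kinetics leave occupancy below equilibrium while plasma levels
    are high and above it as they fall, sweeping a loop whose signed area
    is positive (``anticlockwise``).  The area shrinks to zero as binding
    kinetics become fast relative to plasma elimination.
    """
    if traj.time.size < 3:
        raise ValueError("hysteresis loop requires at least 3 points")
    if traj.to_eq is None:
        raise ValueError("trajectory carries no equilibrium reference (to_eq)")
    x = traj.cp
    y = traj.to
    pairs = np.column_stack([x, y])
    gap = traj.to_eq - y
    scale = max(float(np.max(traj.to_eq)), 1e-300)
    if float(np.max(np.abs(gap))) <= 1e-9 * scale:
        return HysteresisResult(pairs=pairs, signed_area=0.0,
                                orientation="degenerate")
    # shoelace area of [observed path forward, reference path backward];
    # Cp decreases along the path, so this trapezoid sum is positive when
    # occupancy trails its equilibrium (anticlockwise loop)
    area = -float(np.trapezoid(gap, x=x))
    orientation = "anticlockwise" if area > 0 else "clockwise"
    return HysteresisResult(pairs=pairs, signed_area=area,
                            orientation=orientation)
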