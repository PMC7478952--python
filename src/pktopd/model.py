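"""Core multilayer PK/TO/PD model: parameters, ODE right-hand sides and
closed-form limits.

The model links three layers observed in the mouse studies of the DAAO
(D-amino acid oxidase) inhibitor programme:

* **PK** — one-compartment plasma kinetics with first-order elimination.
  Oral dosing is treated as an instantaneous bolus into the plasma
  compartment (no absorption phase was resolvable at the first sampling
  time), so clearance and volume are *apparent oral* parameters.
* **TO** — target occupancy of the enzyme in cerebellum, driven by plasma
  concentration through second-order association (``Kon``) and first-order
  dissociation (``Koff``) binding kinetics, saturating at a maximum binding
  ratio ``BRmax`` (1 − BRmax is the non-displaceable tracer fraction).
  Occupancy is observed indirectly as displacement of a tracer ligand:
  ``tracer = BLtr · (1 − TO)``.
* **PD** — cerebellar D-serine governed by an indirect-response (turnover)
  model in which occupancy inhibits the first-order elimination of
  D-serine; the zero-order production rate is tied to the drug-free
  baseline, ``Kin = BL · Kout``.

Canonical internal units are hours, μg/kg (plasma amount per body weight),
ng/mL (plasma concentration), ng/g (brain tracer) and nmol/g (D-serine).
With the apparent volume in L/kg, ``Cp = Ap / Vp`` comes out in ng/mL with
no hidden conversion factors, which makes the printed unit of ``Kon``
(mL/ng/h) dimensionally consistent.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParams",
    "TOParams",
    "PDParams",
    "ErrorModel",
    "InhibitionForm",
    "BindingConstants",
    "ModelState",
    "MOUSE_PK",
    "MOUSE_TO",
    "MOUSE_PD",
    "MOUSE_ERROR",
    "MOUSE_FP",
    "IN_VITRO_IC50",
    "DOSE_UG_PER_MG",
    "rhs",
    "plasma_concentration",
    "tracer_concentration",
    "in_vivo_kd",
    "kin_from_baseline",
    "pk_closed_form",
    "to_equilibrium",
    "pd_steady_state",
    "propagate_occupancy",
    "propagate_dserine",
]

#: μg per mg — oral doses are quoted in mg/kg, internal amounts in μg/kg.
DOSE_UG_PER_MG = 1000.0

#: Free (unbound) fraction of the drug in mouse plasma.
MOUSE_FP = 0.077

#: In vitro half-maximal inhibitory concentration of the enzyme, ng/mL.
IN_VITRO_IC50 = 1.8


class InhibitionForm(str, enum.Enum):
    """Variant of the turnover inhibition term.

    The indirect-response equation is written so that D-serine rests at its
    baseline when occupancy is zero.  Two bracketing variants of how the
    maximum binding ratio enters are exposed:

    * ``SCALED`` (default): ``dPD/dt = Kin − Kout·PD·(1 − Imax·TO/BRmax)``
      — the fractional inhibition reaches exactly ``Imax`` at full
      attainable occupancy ``TO = BRmax`` (standard turnover model with
      inhibition of elimination).
    * ``LITERAL_UNSCALED``: ``dPD/dt = Kin − Kout·PD·(1 − Imax·TO)`` —
      inhibition ``Imax·TO`` without rescaling by ``BRmax``.

    For ``BRmax`` close to 1 the two differ by at most ~1.5%.
    """

    SCALED = "scaled"
    LITERAL_UNSCALED = "literal_unscaled"


def _check_positive(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if not (np.isfinite(value) and value > 0):
            raise ValueError(
                f"{type(obj).__name__}.{name} must be a positive finite "
                f"number, got {value!r}"
            )


@dataclass(frozen=True)
class PKParams:
    """Apparent oral one-compartment plasma PK parameters.

    Attributes
    ----------
    clp : float
        Oral clearance CL/F, L/h/kg.
    vp : float
        Apparent volume of distribution V/F, L/kg.
    """

    clp: float
    vp: float

    def __post_init__(self) -> None:
        _check_positive(self, "clp", "vp")

    @property
    def ke(self) -> float:
        """First-order elimination rate constant CLp/Vp, 1/h."""
        return self.clp / self.vp


@dataclass(frozen=True)
class TOParams:
    """Binding-kinetics target-occupancy parameters.

    Attributes
    ----------
    kon : float
        Second-order association rate constant, mL/ng/h.
    koff : float
        First-order dissociation rate constant, 1/h.
    brmax : float
        Maximum binding ratio (maximum displaceable tracer fraction),
        dimensionless in (0, 1].
    bltr : float
        Baseline specifically-bound tracer concentration in the target
        region (cerebellum), ng/g.
    """

    kon: float
    koff: float
    brmax: float
    bltr: float

    def __post_init__(self) -> None:
        _check_positive(self, "kon", "koff", "brmax", "bltr")
        if self.brmax > 1.0:
            raise ValueError(
                f"TOParams.brmax must lie in (0, 1], got {self.brmax!r}"
            )


@dataclass(frozen=True)
class PDParams:
    """Indirect-response (turnover) parameters for cerebellar D-serine.

    Attributes
    ----------
    bl : float
        Baseline D-serine concentration, nmol/g.
    kout : float
        First-order elimination rate constant of D-serine, 1/h.
    imax : float
        Maximum fractional inhibition of elimination, in (0, 1].
    """

    bl: float
    kout: float
    imax: float

    def __post_init__(self) -> None:
        _check_positive(self, "bl", "kout", "imax")
        if self.imax > 1.0:
            raise ValueError(
                f"PDParams.imax must lie in (0, 1], got {self.imax!r}"
            )

    @property
    def kin(self) -> float:
        """Zero-order D-serine production rate Kin = BL·Kout, nmol/g/h."""
        return self.bl * self.kout


@dataclass(frozen=True)
class ErrorModel:
    """Proportional residual-error standard deviations per readout.

    Each observation is modelled as ``value = prediction · (1 + ε)`` with
    ``ε ~ N(0, σ²)``; the σ are coefficients of variation (fractions).
    Zero σ are permitted (noise-free generation); fitted σ are positive.
    """

    sigma_pk: float
    sigma_to: float
    sigma_pd: float

    def __post_init__(self) -> None:
        for name in ("sigma_pk", "sigma_to", "sigma_pd"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0):
                raise ValueError(
                    f"ErrorModel.{name} must be >= 0, got {value!r}"
                )


@dataclass(frozen=True)
class ModelState:
    """Instantaneous state of the three-layer system.

    Attributes
    ----------
    ap : float
        Drug amount in the plasma compartment, μg/kg.
    to : float
        Target occupancy, dimensionless fraction.
    pd : float
        D-serine concentration, nmol/g.
    """

    ap: float
    to: float
    pd: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ap) and self.ap >= 0):
            raise ValueError(f"ModelState.ap must be >= 0, got {self.ap!r}")
        if not (np.isfinite(self.to) and 0 <= self.to <= 1):
            raise ValueError(
                f"ModelState.to must lie in [0, 1], got {self.to!r}"
            )
        if not (np.isfinite(self.pd) and self.pd > 0):
            raise ValueError(f"ModelState.pd must be > 0, got {self.pd!r}")


@dataclass(frozen=True)
class BindingConstants:
    """Derived equilibrium constants of the fitted model.

    ``in_vivo_kd`` is the free-concentration equilibrium dissociation
    constant ``Koff/Kon · fp`` and ``kin`` the D-serine production rate
    ``BL·Kout``.
    """

    fp: float
    in_vivo_kd: float
    kin: float

    def __post_init__(self) -> None:
        _check_positive(self, "fp", "in_vivo_kd", "kin")
        if self.fp > 1.0:
            raise ValueError(f"fp must lie in (0, 1], got {self.fp!r}")

    @classmethod
    def from_params(
        cls, to: TOParams, pd: PDParams, fp: float = MOUSE_FP
    ) -> "BindingConstants":
        return cls(fp=fp, in_vivo_kd=in_vivo_kd(to, fp), kin=pd.kin)


# Final mouse parameter estimates of the published analysis; used as the
# default ground truth of the synthetic-study generator.
MOUSE_PK = PKParams(clp=5.14, vp=35.7)
MOUSE_TO = TOParams(kon=0.0372, koff=0.113, brmax=0.987, bltr=21.6)
MOUSE_PD = PDParams(bl=3.48, kout=1.32, imax=0.877)
MOUSE_ERROR = ErrorModel(sigma_pk=0.540, sigma_to=0.416, sigma_pd=0.344)


# ---------------------------------------------------------------------------
# Observable maps and derived quantities
# ---------------------------------------------------------------------------

def plasma_concentration(ap, vp: float):
    """Plasma concentration Cp = Ap/Vp in ng/mL.

    ``ap`` is the plasma amount in μg/kg and ``vp`` the apparent volume in
    L/kg; μg/kg ÷ L/kg ≡ ng/mL exactly.  Accepts scalars or arrays.
    """
    if not vp > 0:
        raise ValueError(f"vp must be > 0, got {vp!r}")
    ap = np.asarray(ap, dtype=float)
    if np.any(ap < 0):
        raise ValueError("ap must be >= 0")
    out = ap / vp
    return float(out) if out.ndim == 0 else out


def tracer_concentration(to, bltr: float):
    """Specifically-bound tracer concentration BLtr·(1 − TO), ng/g.

    Linear displacement map of occupancy: monotone decreasing in TO, equal
    to the baseline ``bltr`` at zero occupancy and 0 at full displacement.
    """
    if not bltr > 0:
        raise ValueError(f"bltr must be > 0, got {bltr!r}")
    to = np.asarray(to, dtype=float)
    if np.any((to < 0) | (to > 1)):
        raise ValueError("to must lie in [0, 1]")
    out = bltr * (1.0 - to)
    return float(out) if out.ndim == 0 else out


def in_vivo_kd(to: TOParams, fp: float = MOUSE_FP) -> float:
    """In vivo equilibrium dissociation constant Koff/Kon·fp, ng/mL.

    The kinetic ratio ``Koff/Kon`` is a dissociation constant on the total
    plasma-concentration scale; multiplying by the plasma free fraction
    ``fp`` expresses it on the free-concentration scale, the quantity
    comparable to an in vitro potency.
    """
    if not (0 < fp <= 1):
        raise ValueError(f"fp must lie in (0, 1], got {fp!r}")
    return to.koff / to.kon * fp


def kin_from_baseline(pd: PDParams) -> float:
    """Zero-order production rate Kin = BL·Kout, nmol/g/h.

    Chosen so that the drug-free steady state of the turnover equation is
    exactly the baseline ``BL``.
    """
    return pd.bl * pd.kout


def pk_closed_form(dose_mg_kg: float, pk: PKParams, t):
    """Analytic plasma concentration after a single oral-as-bolus dose.

    ``Cp(t) = (1000·dose/Vp)·exp(−(CLp/Vp)·t)`` in ng/mL, for ``dose`` in
    mg/kg and ``t`` in hours.  Serves as the independent oracle for the ODE
    integrator.
    """
    if dose_mg_kg < 0:
        raise ValueError(f"dose must be >= 0, got {dose_mg_kg!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    cp0 = DOSE_UG_PER_MG * dose_mg_kg / pk.vp
    out = cp0 * np.exp(-pk.ke * t)
    return float(out) if out.ndim == 0 else out


def to_equilibrium(cp, to: TOParams):
    """Equilibrium occupancy at constant plasma concentration.

    Setting dTO/dt = 0 gives ``TO_ss = BRmax·Cp/(Cp + Koff/Kon)`` — a
    hyperbolic (Emax-type) curve with half-saturation at the total-scale
    dissociation constant ``Koff/Kon`` and plateau ``BRmax``.  This is also
    the static concentration–occupancy map of the direct-response
    comparison model when ``EC50 = Koff/Kon``.
    """
    cp = np.asarray(cp, dtype=float)
    if np.any(cp < 0):
        raise ValueError("cp must be >= 0")
    kd_total = to.koff / to.kon
    out = to.brmax * cp / (cp + kd_total)
    return float(out) if out.ndim == 0 else out


def pd_steady_state(
    to_frac: float, pd: PDParams, form: InhibitionForm = InhibitionForm.SCALED,
    brmax: float = MOUSE_TO.brmax,
) -> float:
    """Steady-state D-serine concentration at a held occupancy, nmol/g.

    ``scaled`` variant: ``BL / (1 − Imax·TO/BRmax)``;
    ``literal_unscaled``: ``BL / (1 − Imax·TO)``.  Both equal ``BL`` at
    zero occupancy.
    """
    if not 0 <= to_frac <= 1:
        raise ValueError(f"to_frac must lie in [0, 1], got {to_frac!r}")
    form = InhibitionForm(form)
    if form is InhibitionForm.SCALED:
        inhibition = pd.imax * to_frac / brmax
    else:
        inhibition = pd.imax * to_frac
    denom = 1.0 - inhibition
    if denom <= 0:
        raise ValueError(
            "elimination fully inhibited (Imax·TO >= 1): steady state "
            "does not exist"
        )
    return pd.bl / denom


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

def rhs(
    state: ModelState,
    pk: PKParams,
    to: TOParams,
    pd: PDParams,
    form: InhibitionForm = InhibitionForm.SCALED,
) -> tuple[float, float, float]:
    """Time derivatives (dAp/dt, dTO/dt, dPD/dt) of the coupled system.

    dAp/dt = −(CLp/Vp)·Ap
    dTO/dt = Kon·(BRmax − TO)·Cp − Koff·TO        with Cp = Ap/Vp
    dPD/dt = Kin − Kout·PD·(1 − Imax·TO/BRmax)    (scaled variant)

    Units: per hour throughout; ``Kon·Cp`` has units 1/h because Cp is in
    ng/mL and Kon in mL/ng/h.
    """
    if not isinstance(state, ModelState):
        state = ModelState(*state)
    cp = plasma_concentration(state.ap, pk.vp)
    dap = -pk.ke * state.ap
    dto = to.kon * (to.brmax - state.to) * cp - to.koff * state.to
    form = InhibitionForm(form)
    if form is InhibitionForm.SCALED:
        frac = 1.0 - pd.imax * state.to / to.brmax
    else:
        frac = 1.0 - pd.imax * state.to
    dpd = pd.kin - pd.kout * state.pd * frac
    return (dap, dto, dpd)


# ---------------------------------------------------------------------------
# Fast fixed-step semi-analytic propagators
#
# Given the closed-form plasma concentration, the TO and PD equations are
# scalar *linear* ODEs with slowly varying coefficients.  Over a short step
# with the driving concentration frozen at its midpoint value each has the
# exact update  x_{n+1} = x_inf + (x_n − x_inf)·exp(−λ·Δt).  This
# exponential-midpoint scheme is second-order accurate, unconditionally
# stable and orders of magnitude faster than an adaptive solver — it is the
# workhorse inside the estimation objective, where the model is evaluated
# thousands of times.  The adaptive integrator in `simulate` provides the
# independent high-accuracy reference path.
# ---------------------------------------------------------------------------

def propagate_occupancy(
    doses_mg_kg: np.ndarray,
    t_grid: np.ndarray,
    pk: PKParams,
    kon: float,
    koff: float,
    brmax: float,
) -> np.ndarray:
    """Occupancy TO(t) after single boluses at t = 0, one column per dose.

    Parameters
    ----------
    doses_mg_kg : array of doses (mg/kg)
    t_grid : strictly increasing times starting at 0, h; the step should be
        small (≲0.05 h) since it is also the integration step.

    Returns
    -------
    ndarray of shape (len(t_grid), len(doses)); TO(0) = 0.
    """
    doses = np.asarray(doses_mg_kg, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing from 0")
    cp0 = DOSE_UG_PER_MG * doses / pk.vp
    t_mid = 0.5 * (t[:-1] + t[1:])
    dt = np.diff(t)
    # (n_steps, n_doses) midpoint plasma concentrations
    cp_mid = cp0[None, :] * np.exp(-pk.ke * t_mid[:, None])
    lam = kon * cp_mid + koff
    to_inf = kon * brmax * cp_mid / lam
    decay = np.exp(-lam * dt[:, None])
    out = np.empty((t.size, doses.size))
    out[0] = 0.0
    cur = out[0]
    for i in range(t.size - 1):
        cur = to_inf[i] + (cur - to_inf[i]) * decay[i]
        out[i + 1] = cur
    return out


def propagate_dserine(
    to_series: np.ndarray,
    t_grid: np.ndarray,
    pd: PDParams,
    brmax: float,
    form: InhibitionForm = InhibitionForm.SCALED,
) -> np.ndarray:
    """D-serine PD(t) driven by a precomputed occupancy series.

    ``to_series`` has shape (len(t_grid), n_doses) as produced by
    :func:`propagate_occupancy`; the return value has the same shape and
    starts at the baseline ``pd.bl``.
    """
    t = np.asarray(t_grid, dtype=float)
    to_series = np.asarray(to_series, dtype=float)
    if to_series.shape[0] != t.size:
        raise ValueError("to_series and t_grid lengths differ")
    form = InhibitionForm(form)
    to_mid = 0.5 * (to_series[:-1] + to_series[1:])
    if form is InhibitionForm.SCALED:
        frac = 1.0 - pd.imax * to_mid / brmax
    else:
        frac = 1.0 - pd.imax * to_mid
    frac = np.maximum(frac, 1e-12)
    lam = pd.kout * frac
    pd_inf = pd.kin / lam
    decay = np.exp(-lam * np.diff(t)[:, None])
    out = np.empty_like(to_series)
    out[0] = pd.bl
    cur = out[0]
    for i in range(t.size - 1):
        cur = pd_inf[i] + (cur - pd_inf[i]) * decay[i]
        out[i + 1] = cur
    return out


def _grid_with_times(t_max: float, dt: float, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Uniform grid [0, t_max] of step <= dt augmented with ``times``.

    Returns (grid, indices of ``times`` in the grid).
    """
    base = np.linspace(0.0, t_max, max(int(math.ceil(t_max / dt)), 1) + 1)
    grid = np.union1d(np.round(base, 9), np.round(np.asarray(times, float), 9))
    if grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
    idx = np.searchsorted(grid, np.round(np.asarray(times, float), 9))
    return grid, idx
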