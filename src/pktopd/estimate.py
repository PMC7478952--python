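"""Sequential naive-pooled maximum-likelihood estimation.

All observations are pooled as if from a single subject — the appropriate
likelihood for a destructive-sampling design in which every animal
contributes one time point, so no inter-individual random effects are
identifiable.  Residuals are proportional for every readout
(``y = f·(1+ε)``, ε ~ N(0, σ²)), giving the extended-least-squares
objective

    OFV = Σ_i [ (y_i − f_i)² / (σ²·f_i²) + ln(σ²·f_i²) ]

(−2·log-likelihood up to the additive constant ``n·ln 2π``).  σ is profiled
out analytically during optimization (its conditional ML estimate is the
mean squared relative residual), which removes one search dimension.

The three stages are fitted sequentially: plasma PK first, then occupancy
with PK fixed, then D-serine turnover with PK and occupancy fixed.  Tracer
preprocessing follows the study convention: specific binding is the
target-region (cerebellum) minus reference-region (frontal cortex) tracer
concentration per animal, and the occupancy baseline is the grand mean of
the vehicle group pooled over all time points, fixed thereafter.

Parameters are searched on log scale (positivity) except the bounded
fractions BRmax and Imax, searched on logit scale.  Each stage runs a
multi-start Nelder–Mead (starts spread ±3-fold around the initial values)
followed by a quasi-Newton polish; standard errors come from the inverse
central-difference Hessian of OFV/2 at the optimum, with
RSE% = 100·SE/estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import (
    DOSE_UG_PER_MG,
    InhibitionForm,
    MOUSE_FP,
    PDParams,
    PKParams,
    TOParams,
    BindingConstants,
    _grid_with_times,
    pk_closed_form,
    propagate_dserine,
    propagate_occupancy,
)

__all__ = [
    "READOUT_PLASMA",
    "READOUT_TRACER_TARGET",
    "READOUT_TRACER_REFERENCE",
    "READOUT_TRACER_SPECIFIC",
    "READOUT_DSERINE",
    "OBSERVATION_COLUMNS",
    "DEFAULT_LLOQ",
    "FitResult",
    "SequentialFit",
    "validate_table",
    "specific_binding",
    "vehicle_baseline",
    "exclude_blq",
    "neg2ll_proportional",
    "fit_pk",
    "fit_to",
    "fit_pd",
    "fit_sequential",
    "compare_models",
]

READOUT_PLASMA = "plasma_drug"
READOUT_TRACER_TARGET = "tracer_target"
READOUT_TRACER_REFERENCE = "tracer_reference"
READOUT_TRACER_SPECIFIC = "tracer_specific"
READOUT_DSERINE = "dserine"

_READOUTS = (
    READOUT_PLASMA,
    READOUT_TRACER_TARGET,
    READOUT_TRACER_REFERENCE,
    READOUT_TRACER_SPECIFIC,
    READOUT_DSERINE,
)

OBSERVATION_COLUMNS = (
    "subject_id", "group", "dose_mg_kg", "time_h", "readout", "value", "blq",
)

#: Lower limits of quantification per readout, in each readout's unit
#: (plasma ng/mL; tracer ng/g; D-serine nmol/g, converted from the 0.5 ng/g
#: assay calibration minimum via the molar mass of serine, 105.09 g/mol).
DEFAULT_LLOQ = {
    READOUT_PLASMA: 2.0,
    READOUT_TRACER_TARGET: 0.1,
    READOUT_TRACER_REFERENCE: 0.1,
    READOUT_DSERINE: 0.5 / 105.09,
}

#: Spread of the multi-start perturbations on transformed scale (±3-fold).
_START_SPREAD = math.log(3.0)

#: Integration step (h) of the fixed-step propagators inside objectives.
_FIT_DT = 0.05


# ---------------------------------------------------------------------------
# Observation-table plumbing
# ---------------------------------------------------------------------------

def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format observation table contract."""
    missing = [c for c in OBSERVATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    if len(table) and (table["time_h"] < 0).any():
        raise ValueError("observation times must be >= 0")
    bad = set(table["readout"]) - set(_READOUTS)
    if bad:
        raise ValueError(f"unknown readouts: {sorted(bad)}")
    return table


def specific_binding(table: pd.DataFrame) -> pd.DataFrame:
    """Append per-animal specific-binding records (target − reference).

    Every animal with a target-region tracer record must have a matching
    reference-region record; the per-animal difference is added as a
    ``tracer_specific`` row.  A specific-binding record is flagged BLQ when
    either region was (per-region flags are applied before subtraction).
    Negative differences (possible under noise) are retained as-is.
    """
    validate_table(table)
    tgt = table[table["readout"] == READOUT_TRACER_TARGET].set_index("subject_id")
    ref = table[table["readout"] == READOUT_TRACER_REFERENCE].set_index("subject_id")
    unpaired = sorted(set(tgt.index).symmetric_difference(ref.index))
    if unpaired:
        raise ValueError(
            "unpaired target/reference tracer records for animals: "
            f"{unpaired}"
        )
    if tgt.index.has_duplicates or ref.index.has_duplicates:
        raise ValueError("multiple tracer records for one animal and region")
    ref = ref.loc[tgt.index]
    spec = tgt.copy()
    spec["readout"] = READOUT_TRACER_SPECIFIC
    spec["value"] = tgt["value"] - ref["value"]
    spec["blq"] = tgt["blq"] | ref["blq"]
    out = pd.concat(
        [table[table["readout"] != READOUT_TRACER_SPECIFIC], spec.reset_index()],
        ignore_index=True,
    )
    return out[list(table.columns)]


def vehicle_baseline(table: pd.DataFrame) -> float:
    """Fixed tracer baseline: grand mean of the vehicle specific binding.

    All vehicle-group time points are pooled into one arithmetic mean
    (BLQ records excluded); the TO stage fixes BLtr to this value.
    """
    validate_table(table)
    if READOUT_TRACER_SPECIFIC not in set(table["readout"]):
        table = specific_binding(table)
    sel = (
        (table["readout"] == READOUT_TRACER_SPECIFIC)
        & (table["dose_mg_kg"] == 0)
        & (~table["blq"])
    )
    values = table.loc[sel, "value"]
    if values.empty:
        raise ValueError(
            "no quantifiable vehicle-group specific-binding records "
            "(missing vehicle group, or all records BLQ): cannot fix the "
            "tracer baseline"
        )
    return float(values.mean())


def exclude_blq(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop below-LLOQ records; return the kept table and counts per readout."""
    validate_table(table)
    flagged = table[table["blq"]]
    counts = flagged.groupby("readout").size().to_dict()
    return table[~table["blq"]].reset_index(drop=True), counts


def neg2ll_proportional(obs, pred, sigma: float) -> float:
    """−2·log-likelihood (up to ``n·ln 2π``) of a proportional-error model."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred shapes differ")
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma!r}")
    if np.any(pred <= 0):
        raise ValueError("model predictions must be positive for all observations")
    var = sigma**2 * pred**2
    return float(np.sum((obs - pred) ** 2 / var + np.log(var)))


def _profiled_ofv(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """OFV with σ profiled at its conditional ML value; returns (OFV, σ̂)."""
    if np.any(pred <= 0) or not np.all(np.isfinite(pred)):
        return np.inf, np.nan
    r2 = ((obs - pred) / pred) ** 2
    s2 = max(float(np.mean(r2)), 1e-30)
    n = obs.size
    ofv = n * math.log(s2) + 2.0 * float(np.sum(np.log(pred))) + n
    return ofv, math.sqrt(s2)


# ---------------------------------------------------------------------------
# Parameter transforms and the multi-start optimizer
# ---------------------------------------------------------------------------

def _to_x(values: Sequence[float], kinds: Sequence[str]) -> np.ndarray:
    out = []
    for v, k in zip(values, kinds):
        if k == "log":
            out.append(math.log(v))
        else:  # logit
            v = min(max(v, 1e-12), 1 - 1e-12)
            out.append(math.log(v / (1 - v)))
    return np.array(out)


def _from_x(x: np.ndarray, kinds: Sequence[str]) -> np.ndarray:
    out = []
    for v, k in zip(x, kinds):
        if k == "log":
            out.append(math.exp(v))
        else:
            out.append(1.0 / (1.0 + math.exp(-v)))
    return np.array(out)


@dataclass
class _OptResult:
    x: np.ndarray
    ofv: float
    converged: bool
    n_evals: int


def _multistart(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_starts: int,
    seed: int,
) -> _OptResult:
    """Multi-start Nelder–Mead with quasi-Newton polish.

    The first start is the initial vector itself; the remainder perturb
    every coordinate uniformly within ±ln 3 on the transformed scale.
    The lowest OFV wins; ties (within 1e-8) go to the candidate closest to
    the initial vector.
    """
    rng = np.random.default_rng(seed)
    starts = [x0] + [
        x0 + rng.uniform(-_START_SPREAD, _START_SPREAD, size=x0.size)
        for _ in range(max(n_starts - 1, 0))
    ]
    best: Optional[_OptResult] = None
    best_dist = np.inf
    n_evals = 0
    for start in starts:
        nm = minimize(
            objective, start, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000,
                     "maxfev": 5000},
        )
        polish = minimize(objective, nm.x, method="BFGS",
                          options={"gtol": 1e-8, "maxiter": 200})
        cand = polish if polish.fun <= nm.fun else nm
        n_evals += nm.nfev + polish.nfev
        dist = float(np.linalg.norm(cand.x - x0))
        better = best is None or cand.fun < best.ofv - 1e-8 or (
            abs(cand.fun - best.ofv) <= 1e-8 and dist < best_dist
        )
        if better:
            best = _OptResult(
                x=np.asarray(cand.x), ofv=float(cand.fun),
                converged=bool(nm.success or polish.success),
                n_evals=n_evals,
            )
            best_dist = dist
    assert best is not None
    best.n_evals = n_evals
    return best


def _hessian_se(
    ofv_natural: Callable[[np.ndarray], float], theta: np.ndarray
) -> np.ndarray:
    """Asymptotic SEs from the central-difference Hessian of OFV/2."""
    p = theta.size
    h = 1e-4 * np.maximum(np.abs(theta), 1e-8)
    hess = np.empty((p, p))
    f0 = ofv_natural(theta)

    def f(t):
        try:
            return ofv_natural(t)
        except (ValueError, FloatingPointError):
            return np.nan

    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                val = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                val = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    hess /= 2.0  # Hessian of OFV/2 = observed information
    try:
        cov = np.linalg.pinv(hess)
        var = np.diag(cov).copy()
        var[var < 0] = np.nan
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Stage estimates with asymptotic uncertainty and fit diagnostics."""

    stage: str
    model: str
    estimates: dict[str, float]
    fixed: dict[str, float]
    se: dict[str, float]
    rse_percent: dict[str, float]
    ofv: float
    n_obs: int
    n_blq_excluded: int
    converged: bool
    boundary_params: list[str] = field(default_factory=list)
    n_starts: int = 5

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "model": self.model,
            "estimates": self.estimates,
            "fixed": self.fixed,
            "se": self.se,
            "rse_percent": self.rse_percent,
            "ofv": self.ofv,
            "n_obs": self.n_obs,
            "n_blq_excluded": self.n_blq_excluded,
            "converged": self.converged,
            "boundary_params": self.boundary_params,
            "n_starts": self.n_starts,
        }


def _finish_fit(
    stage: str,
    model: str,
    names: list[str],
    kinds: list[str],
    opt: _OptResult,
    sigma_name: str,
    predict_natural: Callable[[np.ndarray], np.ndarray],
    obs: np.ndarray,
    fixed: dict[str, float],
    n_blq: int,
    n_starts: int,
) -> FitResult:
    theta_struct = _from_x(opt.x, kinds)
    pred = predict_natural(theta_struct)
    ofv, sigma_hat = _profiled_ofv(obs, pred)

    full_names = names + [sigma_name]
    theta_full = np.append(theta_struct, sigma_hat)

    def ofv_nat(t):
        return neg2ll_proportional(obs, predict_natural(t[:-1]), t[-1])

    if sigma_hat > 1e-8:
        se = _hessian_se(ofv_nat, theta_full)
    else:  # noise-free data: the information matrix is degenerate
        se = np.full(theta_full.size, np.nan)
    estimates = dict(zip(full_names, theta_full.tolist()))
    se_d = dict(zip(full_names, se.tolist()))
    rse = {
        k: (100.0 * se_d[k] / estimates[k] if estimates[k] else np.nan)
        for k in full_names
    }
    boundary = [
        n for n, k in zip(names, kinds)
        if k == "logit" and estimates[n] > 0.999
    ]
    return FitResult(
        stage=stage, model=model, estimates=estimates, fixed=fixed,
        se=se_d, rse_percent=rse, ofv=ofv, n_obs=obs.size,
        n_blq_excluded=n_blq, converged=opt.converged,
        boundary_params=boundary, n_starts=n_starts,
    )


# ---------------------------------------------------------------------------
# Stage fits
# ---------------------------------------------------------------------------

def fit_pk(
    table: pd.DataFrame,
    init: PKParams | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit oral clearance and apparent volume to plasma concentrations."""
    validate_table(table)
    sub = table[(table["readout"] == READOUT_PLASMA) & (table["dose_mg_kg"] > 0)]
    n_blq = int(sub["blq"].sum())
    sub = sub[~sub["blq"]]
    if len(sub) < 3:
        raise ValueError("PK fit needs at least 3 quantifiable plasma records")
    obs = sub["value"].to_numpy(float)
    dose = sub["dose_mg_kg"].to_numpy(float)
    t = sub["time_h"].to_numpy(float)
    init = init or PKParams(clp=2.0, vp=20.0)

    names, kinds = ["clp", "vp"], ["log", "log"]

    def predict(theta):
        clp, vp = theta
        return DOSE_UG_PER_MG * dose / vp * np.exp(-(clp / vp) * t)

    def objective(x):
        return _profiled_ofv(obs, predict(_from_x(x, kinds)))[0]

    opt = _multistart(objective, _to_x([init.clp, init.vp], kinds),
                      n_starts, seed)
    return _finish_fit("pk", "one_compartment_bolus", names, kinds, opt,
                       "sigma_pk", predict, obs, {}, n_blq, n_starts)


def _tracer_subset(table: pd.DataFrame, retain_negative: bool):
    if READOUT_TRACER_SPECIFIC not in set(table["readout"]):
        table = specific_binding(table)
    sub = table[
        (table["readout"] == READOUT_TRACER_SPECIFIC)
        & (table["dose_mg_kg"] > 0)
    ]
    n_blq = int(sub["blq"].sum())
    sub = sub[~sub["blq"]]
    if not retain_negative:
        sub = sub[sub["value"] > 0]
    if sub.empty:
        raise ValueError(
            "no quantifiable specific-binding records in treated groups: "
            "all tracer observations are BLQ or missing — cannot fit the "
            "occupancy stage"
        )
    return sub, n_blq


def fit_to(
    table: pd.DataFrame,
    pk: PKParams,
    bltr: float,
    init: TOParams | None = None,
    model: str = "binding_kinetics",
    fix_brmax: float | None = None,
    n_starts: int = 5,
    seed: int = 0,
    retain_negative: bool = True,
) -> FitResult:
    """Fit an occupancy model to specific tracer binding, PK fixed.

    ``model`` selects the structure: the mechanistic ``binding_kinetics``
    model (Kon, Koff, BRmax), the zero-lag ``direct_emax`` model (EC50,
    BRmax) or the ``effect_compartment`` model (EC50, ke0, BRmax).
    ``fix_brmax`` fixes the maximum binding ratio instead of estimating it
    (used for the nested comparison against full displacement, BRmax = 1).
    The observable is ``BLtr·(1 − TO)`` with BLtr fixed at the vehicle
    grand mean.
    """
    validate_table(table)
    if not bltr > 0:
        raise ValueError(f"bltr must be > 0, got {bltr!r}")
    sub, n_blq = _tracer_subset(table, retain_negative)
    obs = sub["value"].to_numpy(float)
    doses = np.unique(sub["dose_mg_kg"].to_numpy(float))
    times = np.unique(sub["time_h"].to_numpy(float))
    dose_idx = np.searchsorted(doses, sub["dose_mg_kg"].to_numpy(float))
    grid, t_pos = _grid_with_times(times.max(), _FIT_DT, times)
    time_idx = t_pos[np.searchsorted(times, sub["time_h"].to_numpy(float))]

    init = init or TOParams(kon=0.01, koff=0.5, brmax=0.9, bltr=bltr)
    fixed: dict[str, float] = {"bltr": bltr}

    if model == "binding_kinetics":
        if fix_brmax is None:
            names = ["kon", "koff", "brmax"]
            kinds = ["log", "log", "logit"]
            x0 = [init.kon, init.koff, init.brmax]
        else:
            if not (0 < fix_brmax <= 1):
                raise ValueError("fix_brmax must lie in (0, 1]")
            names, kinds = ["kon", "koff"], ["log", "log"]
            x0 = [init.kon, init.koff]
            fixed["brmax"] = fix_brmax

        def predict(theta):
            kon, koff = theta[0], theta[1]
            brmax = theta[2] if fix_brmax is None else fix_brmax
            occ = propagate_occupancy(doses, grid, pk, kon, koff, brmax)
            return bltr * (1.0 - occ[time_idx, dose_idx])

    elif model == "direct_emax":
        names, kinds = ["ec50", "brmax"], ["log", "logit"]
        x0 = [init.koff / init.kon, init.brmax]
        cp_obs = pk_closed_form(1.0, pk, sub["time_h"].to_numpy(float)) \
            * sub["dose_mg_kg"].to_numpy(float)

        def predict(theta):
            ec50, brmax = theta
            occ = brmax * cp_obs / (ec50 + cp_obs)
            return bltr * (1.0 - occ)

    elif model == "effect_compartment":
        names = ["ec50", "ke0", "brmax"]
        kinds = ["log", "log", "logit"]
        x0 = [init.koff / init.kon, 0.5, init.brmax]
        t_obs = sub["time_h"].to_numpy(float)
        dose_obs = sub["dose_mg_kg"].to_numpy(float)
        ke = pk.ke
        c0_unit = DOSE_UG_PER_MG / pk.vp  # per mg/kg of dose

        def predict(theta):
            ec50, ke0, brmax = theta
            if abs(ke0 - ke) < 1e-12 * max(ke0, ke):
                ce = c0_unit * dose_obs * ke * t_obs * np.exp(-ke * t_obs)
            else:
                ce = (
                    c0_unit * dose_obs * ke0 / (ke0 - ke)
                    * (np.exp(-ke * t_obs) - np.exp(-ke0 * t_obs))
                )
            occ = brmax * ce / (ec50 + ce)
            return bltr * (1.0 - occ)

    else:
        raise ValueError(f"unknown occupancy model {model!r}")

    def objective(x):
        return _profiled_ofv(obs, predict(_from_x(x, kinds)))[0]

    opt = _multistart(objective, _to_x(x0, kinds), n_starts, seed)
    return _finish_fit("to", model, names, kinds, opt, "sigma_to",
                       predict, obs, fixed, n_blq, n_starts)


def fit_pd(
    table: pd.DataFrame,
    pk: PKParams,
    to: TOParams,
    init: PDParams | None = None,
    form: InhibitionForm = InhibitionForm.SCALED,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit the D-serine turnover parameters with PK and TO fixed.

    The occupancy time course is fully determined by the fixed upstream
    stages, so it is precomputed once; each objective evaluation only
    propagates the turnover equation.
    """
    validate_table(table)
    form = InhibitionForm(form)
    sub = table[table["readout"] == READOUT_DSERINE]
    n_blq = int(sub["blq"].sum())
    sub = sub[~sub["blq"]]
    if len(sub) < 3:
        raise ValueError("PD fit needs at least 3 quantifiable D-serine records")
    obs = sub["value"].to_numpy(float)
    doses = np.unique(sub["dose_mg_kg"].to_numpy(float))
    times = np.unique(sub["time_h"].to_numpy(float))
    dose_idx = np.searchsorted(doses, sub["dose_mg_kg"].to_numpy(float))
    grid, t_pos = _grid_with_times(times.max(), _FIT_DT, times)
    time_idx = t_pos[np.searchsorted(times, sub["time_h"].to_numpy(float))]

    occ_series = propagate_occupancy(doses, grid, pk, to.kon, to.koff, to.brmax)

    init = init or PDParams(bl=float(np.median(obs)), kout=0.5, imax=0.8)
    names, kinds = ["bl", "kout", "imax"], ["log", "log", "logit"]

    def predict(theta):
        ds = propagate_dserine(
            occ_series, grid, PDParams(bl=theta[0], kout=theta[1],
                                       imax=min(theta[2], 1.0 - 1e-12)),
            brmax=to.brmax, form=form,
        )
        return ds[time_idx, dose_idx]

    def objective(x):
        return _profiled_ofv(obs, predict(_from_x(x, kinds)))[0]

    x0 = [init.bl, init.kout, init.imax]
    opt = _multistart(objective, _to_x(x0, kinds), n_starts, seed)
    return _finish_fit("pd", f"indirect_response_{form.value}", names, kinds,
                       opt, "sigma_pd", predict, obs, {}, n_blq, n_starts)


# ---------------------------------------------------------------------------
# Sequential pipeline and model comparison
# ---------------------------------------------------------------------------

@dataclass
class SequentialFit:
    """Results of the full PK → TO → PD sequential analysis."""

    bltr: float
    pk: FitResult
    to: FitResult
    pd: FitResult
    derived: BindingConstants
    blq_counts: dict[str, int]

    def pk_params(self) -> PKParams:
        return PKParams(clp=self.pk.estimates["clp"], vp=self.pk.estimates["vp"])

    def to_params(self) -> TOParams:
        e = self.to.estimates
        return TOParams(kon=e["kon"], koff=e["koff"],
                        brmax=e.get("brmax", self.to.fixed.get("brmax", 1.0)),
                        bltr=self.bltr)

    def pd_params(self) -> PDParams:
        e = self.pd.estimates
        return PDParams(bl=e["bl"], kout=e["kout"], imax=e["imax"])

    def to_dict(self) -> dict:
        return {
            "bltr": self.bltr,
            "stages": {
                "pk": self.pk.to_dict(),
                "to": self.to.to_dict(),
                "pd": self.pd.to_dict(),
            },
            "derived": {
                "in_vivo_kd_ng_ml": self.derived.in_vivo_kd,
                "kin_nmol_g_h": self.derived.kin,
                "fp": self.derived.fp,
                "nondisplaceable_fraction_percent":
                    100.0 * (1.0 - self.to_params().brmax),
            },
            "blq_counts": self.blq_counts,
        }


def fit_sequential(
    table: pd.DataFrame,
    form: InhibitionForm = InhibitionForm.SCALED,
    fp: float = MOUSE_FP,
    n_starts: int = 5,
    seed: int = 0,
    pk_init: PKParams | None = None,
    to_init: TOParams | None = None,
    pd_init: PDParams | None = None,
) -> SequentialFit:
    """Run the full sequential analysis on one observation table.

    Order of operations: specific-binding preprocessing, vehicle baseline,
    BLQ exclusion bookkeeping, then PK → TO → PD fits with each stage's
    estimates fixed downstream.  Derived constants (in vivo Kd, Kin) are
    computed from the final estimates.
    """
    table = specific_binding(table)
    bltr = vehicle_baseline(table)
    _, blq_counts = exclude_blq(table)
    pk_fit = fit_pk(table, init=pk_init, n_starts=n_starts, seed=seed)
    pk = PKParams(clp=pk_fit.estimates["clp"], vp=pk_fit.estimates["vp"])
    to_fit = fit_to(table, pk, bltr, init=to_init, n_starts=n_starts,
                    seed=seed + 1)
    to = TOParams(kon=to_fit.estimates["kon"], koff=to_fit.estimates["koff"],
                  brmax=to_fit.estimates["brmax"], bltr=bltr)
    pd_fit = fit_pd(table, pk, to, init=pd_init, form=form,
                    n_starts=n_starts, seed=seed + 2)
    pd_params = PDParams(bl=pd_fit.estimates["bl"],
                         kout=pd_fit.estimates["kout"],
                         imax=pd_fit.estimates["imax"])
    derived = BindingConstants.from_params(to, pd_params, fp=fp)
    return SequentialFit(bltr=bltr, pk=pk_fit, to=to_fit, pd=pd_fit,
                         derived=derived, blq_counts=blq_counts)


def compare_models(
    table: pd.DataFrame,
    pk: PKParams,
    bltr: float,
    candidates: Sequence[str] = (
        "direct_emax", "effect_compartment", "binding_kinetics",
    ),
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit competing occupancy models on the identical tracer subset.

    Returns a report ranked by OFV (lower is better) with pairwise ΔOFV
    against the best candidate, plus the per-candidate fit results.  The
    printed objective-function differences of the original analysis depend
    on the original animal data; only the comparison machinery is
    reproducible.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    fits: dict[str, FitResult] = {}
    n_obs = None
    fitted = []
    for cand in candidates:
        fit = fits.get(cand) or fit_to(table, pk, bltr, model=cand,
                                       n_starts=n_starts, seed=seed)
        if n_obs is None:
            n_obs = fit.n_obs
        elif fit.n_obs != n_obs:
            raise ValueError(
                "candidates were fitted on different observation subsets"
            )
        fits[cand] = fit
        fitted.append(fit)
    report = pd.DataFrame(
        {
            "model": list(candidates),
            "n_params": [len(f.estimates) for f in fitted],
            "ofv": [f.ofv for f in fitted],
        }
    ).sort_values("ofv", kind="stable", ignore_index=True)
    report["delta_ofv"] = report["ofv"] - report["ofv"].iloc[0]
    report["rank"] = np.arange(1, len(report) + 1)
    return report, fits
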