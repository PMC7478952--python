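# Methods

## Model structure and assumptions

The pipeline links three observation layers with a deterministic ODE
model and a proportional observation-error model.

**Plasma PK.** One compartment with first-order elimination.  Oral doses
enter the plasma compartment as instantaneous boluses: no absorption
phase is resolvable when the first sample is taken at 2 h, so `CLp` and
`Vp` are *apparent oral* parameters (bioavailability is absorbed into
them) and no absorption rate constant exists.  Plasma concentration
`Cp = Ap/Vp` drives target binding directly, which assumes fast
blood–brain equilibration and an unbound brain-to-plasma ratio near 1 —
reasonable for a compound that is not a P-gp/BCRP substrate and shows
rapid brain penetration.

**Target occupancy.** Second-order association / first-order dissociation
binding kinetics to the cerebellar enzyme:
`dTO/dt = Kon·(BRmax − TO)·Cp − Koff·TO`.  `BRmax < 1` caps attainable
displacement; `1 − BRmax` is the non-displaceable tracer fraction.
Occupancy is observed through tracer displacement,
`tracer = BLtr·(1 − TO)`, where the specific binding is the target-region
(cerebellum) minus reference-region (frontal cortex) tracer concentration
per animal and `BLtr` is fixed at the grand mean of the vehicle group
pooled over all times.  The kinetic ratio `Koff/Kon` is a dissociation
constant on the total-plasma scale; multiplying by the plasma free
fraction `fp` gives the free-concentration in vivo Kd.

**Pharmacodynamics.** Indirect-response (turnover) model in which
occupancy inhibits D-serine elimination.  The production rate is tied to
the drug-free baseline, `Kin = BL·Kout`, so `PD = BL` is the unperturbed
steady state.  Two variants of the inhibition term are exposed because
the printed form of the turnover equation omits the state variable and
must be normalised one way or the other:

* `scaled` (default): `dPD/dt = Kin − Kout·PD·(1 − Imax·TO/BRmax)` —
  fractional inhibition reaches exactly `Imax` at the maximum attainable
  occupancy `TO = BRmax`;
* `literal_unscaled`: `dPD/dt = Kin − Kout·PD·(1 − Imax·TO)`.

With `BRmax = 0.987` the two differ by ≤ ~1.5%; both are selectable in
configuration and the choice is reported with every fit.

**Comparison occupancy models.**  The zero-lag direct model
`TO = BRmax·Cp/(EC50 + Cp)` and the effect-compartment model
`dCe/dt = ke0·(Cp − Ce)`, `TO = BRmax·Ce/(EC50 + Ce)` are implemented in
their canonical Emax forms.  Both admit closed forms given the
closed-form plasma curve (the effect compartment is a linear ODE, so its
bolus response superposes).

## Parameters

| symbol | unit | meaning | default (mouse) |
|---|---|---|---|
| CLp | L/h/kg | apparent oral clearance | 5.14 |
| Vp | L/kg | apparent volume of distribution | 35.7 |
| Kon | mL/ng/h | association rate constant | 0.0372 |
| Koff | 1/h | dissociation rate constant | 0.113 |
| BRmax | – | maximum binding ratio | 0.987 |
| BLtr | ng/g | baseline specific tracer binding | 21.6 (fixed) |
| BL | nmol/g | baseline D-serine | 3.48 |
| Kout | 1/h | D-serine elimination rate | 1.32 |
| Imax | – | maximum inhibition of elimination | 0.877 |
| fp | – | mouse plasma free fraction | 0.077 |
| σ_pk, σ_to, σ_pd | CV | proportional residual SDs | 0.540, 0.416, 0.344 |

Internal canonical units are h, μg/kg (amounts), ng/mL (plasma), ng/g
(tracer) and nmol/g (D-serine); doses convert mg/kg → μg/kg (×1000) at
the dosing boundary.  With `Vp` in L/kg, `Ap/Vp` is in ng/mL with no
hidden factors, making the printed unit of `Kon` dimensionally exact.

## Estimation

All observations are pooled (naive-pooled likelihood): destructive
sampling gives one observation per animal, so inter-individual random
effects are not identifiable and none are estimated.  The
proportional-error −2·log-likelihood (up to `n·ln 2π`) is

    OFV = Σ_i [ (y_i − f_i)² / (σ²·f_i²) + ln(σ²·f_i²) ].

σ is profiled analytically (its conditional ML value is the mean squared
relative residual), removing one search dimension; the reported σ and
OFV are the exact joint ML values.  Records below the limit of
quantification are excluded before fitting (defaults: plasma 2.0 ng/mL,
tracer 0.1 ng/g per region, D-serine 0.5 ng/g ≈ 4.8·10⁻³ nmol/g via the
molar mass of serine, 105.09 g/mol; all overridable).  Specific-binding
records are flagged BLQ when either region was; negative differences with
positive predictions are retained in the likelihood (the
prediction-scaled variance is well defined), with a toggle to drop them.

Stages run sequentially — PK alone, then TO with PK fixed, then PD with
PK and TO fixed — matching the original analysis and keeping each stage
low-dimensional.  Parameters are searched on log scale, except the
bounded fractions `BRmax` and `Imax` on logit scale, which enforces
positivity/boundedness without constrained optimization.  Each stage uses
multi-start Nelder–Mead (default 5 starts; the first at the initial
values, the rest perturbed uniformly within ±ln 3 per coordinate)
followed by a BFGS polish; the lowest OFV wins, ties (within 1e-8)
resolved toward the start closest to the initialization.  A logit-scaled
estimate above 0.999 is reported as a boundary hit.

Standard errors come from the inverse central-difference Hessian of
OFV/2 at the optimum over the natural parameters including σ
(RSE% = 100·SE/estimate); on noise-free data the information matrix is
degenerate and SEs are reported as NaN.  Model comparison refits each
candidate occupancy model on the identical observation subset and ranks
by OFV; nested candidates (e.g. `BRmax` fixed at 1) use the same
machinery.

## Numerics

* **Trajectory integration** (`simulate`): LSODA with rtol 1e-8 /
  atol 1e-10, dose boluses handled by state reinitialization at dose
  times (no events), dense default output step 0.01 h.  The plasma ODE
  agrees with the analytic bolus solution to better than 1e-6 relative.
* **Fitting objectives** use a fixed-step exponential-midpoint
  propagator: given closed-form `Cp(t)`, the TO and PD equations are
  scalar linear ODEs with slowly varying coefficients, so over each step
  (0.05 h, observation times inserted exactly into the grid) the exact
  constant-coefficient update is applied with midpoint coefficients.
  The scheme is unconditionally stable, second-order (~1e-4 relative at
  this step size — an order below the optimizer tolerances it serves)
  and orders of magnitude faster than an adaptive solver, which matters
  when the model is evaluated thousands of times per fit.  The adaptive
  integrator and an independent fixed-step RK4 reimplementation in the
  test suite provide the cross-checks.
* **Degenerate inputs**: zero dose yields exactly flat baselines; the
  profiled σ² is floored at 1e-30 so noise-free data remain finite; a
  fully inhibited turnover (`Imax·TO → 1`) is rejected in the
  steady-state formula and floored in the propagator.
* **Hysteresis loop**: after a bolus the plasma concentration declines
  monotonically, so the observed (Cp, TO) path alone never
  self-intersects and a plain closed-polyline area would be dominated by
  the arbitrary closure chord — any zero-lag model would still enclose
  the area between its static curve and that chord.  The loop is
  therefore computed between the observed path and the zero-lag
  reference `TO_eq(Cp)` carried by every trajectory, via the shoelace
  (trapezoid) sum, oriented so that occupancy trailing concentration —
  the physiological lag — gives a positive, "anticlockwise" area.  A
  path coinciding with its reference is flagged degenerate (zero area);
  the area vanishes continuously as binding becomes fast relative to
  plasma elimination.

## Synthetic-study generator

The generator reproduces the statistical structure of the mouse study:
oral doses 0.3/1/3/10 mg/kg; occupancy-arm sampling at 2, 4, 6, 8, 10,
24 h with n = 4 animals per dose and time, each contributing plasma plus
target- and reference-region tracer; a PD arm at 2, 6, 10, 24 h with
n = 7 contributing D-serine; and a vehicle group on the occupancy grid
(448 records in total).  Noise is multiplicative normal per readout at
the fitted residual magnitudes; draws that land non-positive are
re-flagged BLQ rather than resampled, preserving the error distribution.
Each readout has its own RNG stream spawned from the master seed, so
extending one arm never perturbs another, and identical seed + design +
truth reproduce the table byte-for-byte.

The reference region carries only non-specific binding, modelled as a
constant 5% of `BLtr` (the study gives no reference-region model; only
the difference enters the fit, so this is a nuisance choice, and it is
overridable).  A target-region value is composed as the animal's specific
binding with proportional noise plus that same animal's reference value,
so the target-minus-reference difference carries exactly the proportional
error assumed by the likelihood.  An optional variance-inflation factor
for the vehicle group emulates the larger baseline variability seen in
practice; the multiplicative noise is zero-mean, so the grand-mean
baseline stays unbiased.

What the generator does **not** emulate: circadian or inter-study drift
in baselines, correlation of residuals within an animal across readouts,
assay-specific heteroscedasticity beyond the proportional model, and the
20-min tracer-to-sacrifice interval (the tracer is treated as an
instantaneous occupancy probe).  Passing recovery tests therefore show
that the estimator is correct and well calibrated *under the stated error
model and design* — not that real data are free of structural
misspecification.

## Translation to humans

`Kon` is rescaled by the free-fraction ratio (preserving the free
in vivo Kd exactly), `Kout` by the mouse/human plasma D-serine half-life
ratio 1.2 h / 3.3 h; `Koff`, `BRmax` and `Imax` carry over.  Human plasma
PK parameters must be supplied (allometric prediction is out of scope —
the source species parameters needed to reproduce it are not available),
and the human D-serine baseline defaults to the mouse value with an
override.  The steady-state occupancy–response relationship is invariant
to the `Kout` scaling; only the response kinetics change.  The scan-time
report proposes exactly two PET scans: the occupancy peak (after the
plasma peak, by the binding lag) and a late scan at ≥ 24 h.

## Validation problem sizes

The recovery study in the test suite and the structural checks use 20
replicate synthetic studies at the full design (448 records each), fitted
sequentially with 2 optimizer starts per stage; zero-noise round trips
use the same design.  These sizes give stable medians (observed median
recovery errors are under 10% for all nine parameters) while keeping the
whole suite fast; the estimator itself defaults to 5 starts.

## Known limitations

* One-compartment PK ignores the absorption and distribution phases; the
  original analysis found a two-compartment input changed the
  occupancy-stage results negligibly, but early-time plasma predictions
  (< 2 h) are not meaningful here.
* The naive-pooled likelihood treats all residual variation as
  observational; true inter-animal variability inflates the estimated σ
  rather than being separated from it.
* Asymptotic (Hessian-based) RSEs are first-order approximations; they
  degrade near parameter bounds (`Imax`, `BRmax` → 1).
* The exact equations of the original direct-response and
  effect-compartment comparison models are not published; the canonical
  Emax forms implemented here are the standard referents of those names,
  and only the comparison machinery — not published objective-function
  differences — is validated.
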