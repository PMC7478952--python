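# pktopd

Mechanistic multilayer **PK / target-occupancy / pharmacodynamics**
modelling of a D-amino acid oxidase (DAAO) inhibitor in mice — simulation,
naive-pooled maximum-likelihood estimation, synthetic-study generation and
mouse-to-human translation.

## The scientific problem

DAAO degrades D-serine, a co-agonist of the NMDA receptor; inhibiting DAAO
raises cerebellar D-serine, a mechanism of interest for schizophrenia.
Linking an oral dose quantitatively to that response requires three
layers: plasma drug exposure (PK), enzyme target occupancy in cerebellum
(TO, measured as displacement of a tracer ligand), and the D-serine
response (PD).  The occupancy time course lags plasma concentration —
occupancy peaks hours after the plasma peak and an anticlockwise
hysteresis loop appears in the concentration–occupancy plane — which a
zero-lag (direct-response) model cannot describe.  Slow target binding
kinetics can.

This package implements that three-layer model as a reusable pipeline for
modellers in DMPK / quantitative pharmacology.  Because the underlying
animal data are not public, a first-class synthetic-study generator
reproduces the study's design (destructive sampling, group sizes, sampling
grids, proportional noise, quantification limits), so every stage of the
workflow is testable end to end.

## The model

State variables: plasma drug amount `Ap` (μg/kg), target occupancy `TO`
(fraction), cerebellar D-serine `PD` (nmol/g).  With `Cp = Ap/Vp` (ng/mL):

    dAp/dt = −(CLp/Vp) · Ap                         (oral dose as bolus)
    dTO/dt = Kon · (BRmax − TO) · Cp − Koff · TO    (binding kinetics)
    dPD/dt = Kin − Kout · PD · (1 − Imax·TO/BRmax)  (turnover, inhibition
                                                     of elimination)

with observables and derived constants

    tracer   = BLtr · (1 − TO)          (specific binding, cerebellum −
                                         frontal cortex)
    Kin      = BL · Kout                (holds PD at baseline when TO = 0)
    in vivo Kd = (Koff/Kon) · fp        (free-concentration scale)

Estimation is sequential (PK → TO → PD, upstream estimates fixed) by
naive-pooled maximum likelihood with proportional residual error — the
faithful likelihood for a design in which every animal is sampled once.
Comparison occupancy models (direct Emax, effect compartment) and an
objective-function model-comparison report are included, as is the
mouse-to-human parameter translation used to plan PET occupancy scans.

## Worked example

```python
import numpy as np
import pktopd as p
from pktopd.io import table_summary

# one synthetic study at the real design and noise magnitudes
table, meta = p.generate_study(p.StudyDesign(seed=1), p.MOUSE_PK,
                               p.MOUSE_TO, p.MOUSE_PD, p.MOUSE_ERROR)
fit = p.fit_sequential(table, seed=1)
print(table_summary(fit))

traj = p.simulate(p.DoseRegimen(0.3), fit.pk_params(), fit.to_params(),
                  fit.pd_params())
i_cp, i_to = np.argmax(traj.cp), np.argmax(traj.to)
print(f"plasma peak {traj.cp[i_cp]:.2f} ng/mL at {traj.time[i_cp]:g} h; "
      f"occupancy peak {traj.to[i_to]:.3f} at {traj.time[i_to]:g} h")
print(f"hysteresis: {p.hysteresis_curve(traj).orientation}")
```

prints (seed 1):

```
Category Parameter       Unit     Definition                                 Value   RSE (%)
PK       CLp             L/h/kg   oral clearance                             4.861       4.8
PK       Vp              L/kg     apparent volume of distribution            32.61      7.02
PK       residual error  %        proportional residual error                41.64      9.35
TO       Kon             mL/ng/h  association rate constant                0.03098        11
TO       Koff            1/h      dissociation rate constant               0.09946      13.1
TO       BRmax           -        maximum binding ratio                     0.9844     0.388
TO       BLtr            ng/g     baseline concentration of tracer           20.73       Fix
TO       residual error  %        proportional residual error                39.52      8.32
PD       BL              nmol/g   baseline concentration of D-serine         3.635      5.43
PD       Kout            1/h      elimination rate constant                  1.223      13.5
PD       Imax            -        maximum inhibitory effect                 0.8656      2.65
PD       residual error  %        proportional residual error                32.38      7.35

Derived quantities:
  in vivo Kd (Koff/Kon x fp)      : 0.2472 ng/mL
  non-displaceable tracer fraction: 1.56 %
  Kin (BL x Kout)                 : 4.446 nmol/g/h

plasma peak 9.20 ng/mL at 0 h; occupancy peak 0.509 at 6.62 h
hysteresis: anticlockwise
```

The single noisy study recovers the generating parameters (CLp 5.14,
Kon 0.0372, Imax 0.877, …) to roughly their reported relative standard
errors; occupancy peaks ~6 h after the instantaneous plasma peak, the
signature kinetic lag of slow target binding.

The same workflow is available from the shell:

```
pktopd generate -o run/          # synthetic dataset + truth sidecar
pktopd fit -d run/observations.csv -o run/
pktopd simulate --qd --days 7 -o run/
pktopd compare -d run/observations.csv -o run/
pktopd translate -c config.yaml -o run/
```

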