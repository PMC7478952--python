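"""Mouse-to-human scaling of the occupancy and turnover parameters.

Two species differences are carried across:

* Plasma protein binding — the association rate constant acts on *total*
  plasma concentration, so it is rescaled by the ratio of free fractions,
  ``Kon_human = Kon_mouse · fp_human / fp_mouse``.  This preserves the
  free-concentration dissociation constant ``Koff/Kon·fp`` exactly.
* D-serine turnover — the cerebellar elimination rate is scaled by the
  ratio of plasma D-serine half-lives between species,
  ``Kout_human = Kout_mouse · t½_mouse / t½_human`` (defaults 1.2 h in
  mouse vs 3.3 h in patients).

``Koff``, ``BRmax`` and ``Imax`` are treated as system/drug properties and
carried over.  Human plasma PK parameters are required inputs (predicted
externally, e.g. by allometry); no allometric exponents are invented here.
The human D-serine baseline defaults to the mouse value and can be
overridden.

The human-regimen simulation is used to reason about PET scan scheduling:
occupancy peaks after the plasma peak under binding kinetics, so one scan
is proposed at the occupancy peak and a second at 24 h or later to capture
the occupancy tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    InhibitionForm,
    MOUSE_FP,
    PDParams,
    PKParams,
    TOParams,
)
from .simulate import DoseRegimen, Trajectory, simulate

__all__ = [
    "TranslationInputs",
    "translate_params",
    "simulate_human",
    "suggest_scan_times",
]

#: Plasma D-serine elimination half-lives, h.
T_HALF_DSERINE_MOUSE = 1.2
T_HALF_DSERINE_HUMAN = 3.3


@dataclass(frozen=True)
class TranslationInputs:
    """Species-difference inputs for the mouse-to-human mapping."""

    fp_human: float
    fp_mouse: float = MOUSE_FP
    t_half_dserine_mouse: float = T_HALF_DSERINE_MOUSE
    t_half_dserine_human: float = T_HALF_DSERINE_HUMAN
    #: Human D-serine baseline, nmol/g; None carries over the mouse value.
    bl_human: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("fp_human", "fp_mouse",
                     "t_half_dserine_mouse", "t_half_dserine_human"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        if self.fp_human > 1 or self.fp_mouse > 1:
            raise ValueError("free fractions must lie in (0, 1]")
        if self.bl_human is not None and not self.bl_human > 0:
            raise ValueError("bl_human must be > 0 when given")


def translate_params(
    to_mouse: TOParams,
    pd_mouse: PDParams,
    tr: TranslationInputs,
) -> tuple[TOParams, PDParams]:
    """Map mouse TO/PD parameters to their human counterparts.

    The mapping preserves the free-concentration dissociation constant
    (``in_vivo_kd(human, fp_human) == in_vivo_kd(mouse, fp_mouse)``) and
    rescales the D-serine turnover rate by the half-life ratio; the
    steady-state concentration–response is unchanged since it depends only
    on occupancy, Imax and the baseline.
    """
    kon_human = to_mouse.kon * tr.fp_human / tr.fp_mouse
    kout_human = pd_mouse.kout * (
        tr.t_half_dserine_mouse / tr.t_half_dserine_human
    )
    to_human = TOParams(kon=kon_human, koff=to_mouse.koff,
                        brmax=to_mouse.brmax, bltr=to_mouse.bltr)
    pd_human = PDParams(
        bl=tr.bl_human if tr.bl_human is not None else pd_mouse.bl,
        kout=kout_human, imax=pd_mouse.imax,
    )
    return to_human, pd_human


def simulate_human(
    regimen: DoseRegimen,
    pk_human: PKParams,
    to_human: TOParams,
    pd_human: PDParams,
    form: InhibitionForm = InhibitionForm.SCALED,
    grid: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Forward-simulate the translated model under a human regimen."""
    return simulate(regimen, pk_human, to_human, pd_human, form, grid=grid)


def suggest_scan_times(traj: Trajectory) -> tuple[float, float]:
    """Propose two PET scan times from a simulated human trajectory.

    The first scan targets the occupancy peak (a little after the plasma
    peak, given the binding lag); the second probes the slow occupancy
    tail at 24 h after the first dose, or at the occupancy peak itself if
    that falls even later.  The simulation must extend to at least 24 h.
    """
    if traj.time[-1] < 24.0:
        raise ValueError("simulate at least 24 h to schedule the late scan")
    t_peak = float(traj.time[int(np.argmax(traj.to))])
    return t_peak, max(24.0, t_peak)
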