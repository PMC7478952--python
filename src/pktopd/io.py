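"""Configuration schema, dataset/result I/O and reproducibility metadata.

One long-format CSV dialect is used for observations (columns
``subject_id, group, dose_mg_kg, time_h, readout, value, blq``) — three
heterogeneous observables with different units make an explicit readout
column clearer than a wide layout.  Parameters travel as JSON with a
species tag; fit results as structured JSON; trajectories as tidy CSV.
Every artifact directory receives a resolved copy of the run
configuration plus provenance (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .estimate import DEFAULT_LLOQ, OBSERVATION_COLUMNS, validate_table
from .model import (
    ErrorModel,
    InhibitionForm,
    MOUSE_ERROR,
    MOUSE_FP,
    MOUSE_PD,
    MOUSE_PK,
    MOUSE_TO,
    PDParams,
    PKParams,
    TOParams,
)
from .synth import StudyDesign

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "provenance",
    "read_observations",
    "write_observations",
    "write_json",
    "write_params",
    "read_params",
    "table_summary",
]

try:
    PACKAGE_VERSION = _pkg_version("pktopd")
except PackageNotFoundError:  # pragma: no cover - editable quirk
    PACKAGE_VERSION = "unknown"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignConfig(_Strict):
    doses: list[float] = [0.3, 1.0, 3.0, 10.0]
    to_times: list[float] = [2.0, 4.0, 6.0, 8.0, 10.0, 24.0]
    pd_times: list[float] = [2.0, 6.0, 10.0, 24.0]
    n_to: int = 4
    n_pd: int = 7
    vehicle: bool = True
    n_vehicle: int = 4
    ref_fraction: float = 0.05
    vehicle_sigma_inflation: float = 1.0


class ParamsConfig(_Strict):
    """Model parameters; defaults are the published mouse estimates."""

    clp: float = MOUSE_PK.clp
    vp: float = MOUSE_PK.vp
    kon: float = MOUSE_TO.kon
    koff: float = MOUSE_TO.koff
    brmax: float = MOUSE_TO.brmax
    bltr: float = MOUSE_TO.bltr
    bl: float = MOUSE_PD.bl
    kout: float = MOUSE_PD.kout
    imax: float = MOUSE_PD.imax
    sigma_pk: float = MOUSE_ERROR.sigma_pk
    sigma_to: float = MOUSE_ERROR.sigma_to
    sigma_pd: float = MOUSE_ERROR.sigma_pd
    fp: float = MOUSE_FP

    def pk(self) -> PKParams:
        return PKParams(clp=self.clp, vp=self.vp)

    def to(self) -> TOParams:
        return TOParams(kon=self.kon, koff=self.koff, brmax=self.brmax,
                        bltr=self.bltr)

    def pd(self) -> PDParams:
        return PDParams(bl=self.bl, kout=self.kout, imax=self.imax)

    def error(self) -> ErrorModel:
        return ErrorModel(sigma_pk=self.sigma_pk, sigma_to=self.sigma_to,
                          sigma_pd=self.sigma_pd)


class FitConfig(_Strict):
    n_starts: int = 5


class SimulateConfig(_Strict):
    doses: list[float] = [0.3, 1.0, 3.0, 10.0]
    qd: bool = False
    days: int = 7
    grid_step: float = 0.01


class TranslationConfig(_Strict):
    fp_human: float = MOUSE_FP
    fp_mouse: float = MOUSE_FP
    t_half_dserine_mouse: float = 1.2
    t_half_dserine_human: float = 3.3
    bl_human: Optional[float] = None
    clp_human: Optional[float] = None
    vp_human: Optional[float] = None
    dose_mg_kg: float = 1.0


class RunConfig(_Strict):
    """Resolved run configuration; unknown keys are rejected."""

    seed: int = 1
    form: str = InhibitionForm.SCALED.value
    outdir: str = "pktopd_out"
    lloq: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_LLOQ))
    design: DesignConfig = Field(default_factory=DesignConfig)
    params: ParamsConfig = Field(default_factory=ParamsConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    translation: TranslationConfig = Field(default_factory=TranslationConfig)

    def study_design(self) -> StudyDesign:
        d = self.design
        return StudyDesign(
            doses=tuple(d.doses), to_times=tuple(d.to_times),
            pd_times=tuple(d.pd_times), n_to=d.n_to, n_pd=d.n_pd,
            vehicle=d.vehicle, n_vehicle=d.n_vehicle,
            lloq=dict(self.lloq), ref_fraction=d.ref_fraction,
            vehicle_sigma_inflation=d.vehicle_sigma_inflation,
            seed=self.seed,
        )

    def inhibition_form(self) -> InhibitionForm:
        return InhibitionForm(self.form)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def provenance(cfg: RunConfig) -> dict:
    return {
        "config_sha256": config_hash(cfg),
        "seed": cfg.seed,
        "package_version": PACKAGE_VERSION,
    }


def write_run_metadata(cfg: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json(cfg.model_dump(), outdir / "resolved_config.json")
    write_json(provenance(cfg), outdir / "provenance.json")


# ---------------------------------------------------------------------------
# Datasets, parameters, results
# ---------------------------------------------------------------------------

def write_observations(table: pd.DataFrame, path: str | Path) -> None:
    validate_table(table)
    table.to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"malformed observation CSV {path}: missing columns {missing}"
        )
    table["blq"] = table["blq"].astype(bool)
    return validate_table(table)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_params(
    path: str | Path,
    pk: PKParams,
    to: TOParams,
    pd_params: PDParams,
    species: str = "mouse",
) -> None:
    write_json(
        {
            "species": species,
            "pk": {"clp": pk.clp, "vp": pk.vp},
            "to": {"kon": to.kon, "koff": to.koff, "brmax": to.brmax,
                   "bltr": to.bltr},
            "pd": {"bl": pd_params.bl, "kout": pd_params.kout,
                   "imax": pd_params.imax},
        },
        path,
    )


def read_params(path: str | Path) -> tuple[PKParams, TOParams, PDParams, str]:
    data = json.loads(Path(path).read_text())
    return (
        PKParams(**data["pk"]),
        TOParams(**data["to"]),
        PDParams(**data["pd"]),
        data.get("species", "mouse"),
    )


_SUMMARY_ROWS = (
    ("PK", "clp", "CLp", "L/h/kg", "oral clearance"),
    ("PK", "vp", "Vp", "L/kg", "apparent volume of distribution"),
    ("PK", "sigma_pk", "residual error", "%", "proportional residual error"),
    ("TO", "kon", "Kon", "mL/ng/h", "association rate constant"),
    ("TO", "koff", "Koff", "1/h", "dissociation rate constant"),
    ("TO", "brmax", "BRmax", "-", "maximum binding ratio"),
    ("TO", "bltr", "BLtr", "ng/g", "baseline concentration of tracer"),
    ("TO", "sigma_to", "residual error", "%", "proportional residual error"),
    ("PD", "bl", "BL", "nmol/g", "baseline concentration of D-serine"),
    ("PD", "kout", "Kout", "1/h", "elimination rate constant"),
    ("PD", "imax", "Imax", "-", "maximum inhibitory effect"),
    ("PD", "sigma_pd", "residual error", "%", "proportional residual error"),
)


def table_summary(seq_fit) -> str:
    """Human-readable parameter summary of a sequential fit.

    One row per parameter with category, unit, definition, estimate and
    RSE%; residual errors are shown as percent CV and the fixed tracer
    baseline is marked "Fix".  A derived block reports the in vivo Kd,
    non-displaceable tracer fraction and Kin.
    """
    stages = {"pk": seq_fit.pk, "to": seq_fit.to, "pd": seq_fit.pd}
    lines = [
        f"{'Category':<9}{'Parameter':<16}{'Unit':<9}"
        f"{'Definition':<38}{'Value':>10}  {'RSE (%)':>8}"
    ]
    for cat, key, label, unit, definition in _SUMMARY_ROWS:
        fit = stages[{"PK": "pk", "TO": "to", "PD": "pd"}[cat]]
        if key == "bltr":
            value, rse = seq_fit.bltr, "Fix"
        elif key in fit.estimates:
            value = fit.estimates[key]
            pct = fit.rse_percent.get(key)
            rse = f"{pct:.3g}" if pct is not None and pct == pct else "-"
        else:
            value, rse = fit.fixed.get(key, float("nan")), "Fix"
        if key.startswith("sigma"):
            value = 100.0 * value
        lines.append(
            f"{cat:<9}{label:<16}{unit:<9}{definition:<38}"
            f"{value:>10.4g}  {rse:>8}"
        )
    d = seq_fit.to_dict()["derived"]
    lines += [
        "",
        "Derived quantities:",
        f"  in vivo Kd (Koff/Kon x fp)      : {d['in_vivo_kd_ng_ml']:.4g} ng/mL",
        f"  non-displaceable tracer fraction: "
        f"{d['nondisplaceable_fraction_percent']:.3g} %",
        f"  Kin (BL x Kout)                 : {d['kin_nmol_g_h']:.4g} nmol/g/h",
    ]
    return "\n".join(lines)
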