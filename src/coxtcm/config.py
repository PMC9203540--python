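"""Validated run configurations, bundled fixtures and file I/O.

Configs are JSON or YAML mappings validated with pydantic (unknown keys
rejected) and convertible to the domain parameter objects.  Two fixtures
ship with the package: ``mouse150`` (the PK-driven xenograft
parameterization) and ``spheroid`` (the constant-concentration lapatinib
parameterization).  Every file the package writes embeds the config hash
on a leading comment line for provenance.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .estimation import ObservationSeries
from .pk_model import DoseEvent, DoseSchedule, PKParams
from .tcm_dynamics import GrowthParams, MortalityParams, TCMParams

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "bundled_config",
    "config_hash",
    "write_table",
    "read_observations",
    "write_observations",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GrowthConfig(_Strict):
    variant: Literal["simeoni", "logistic"]
    lambda0: float = Field(gt=0)
    lambda1: Optional[float] = None
    phi: Optional[float] = None
    umax: Optional[float] = None
    saturation: Literal["total", "proliferating"] = "total"

    def to_domain(self) -> GrowthParams:
        return GrowthParams(
            variant=self.variant, lambda0=self.lambda0, lambda1=self.lambda1,
            phi=self.phi, umax=self.umax, saturation=self.saturation,
        )


class MortalityConfig(_Strict):
    eta: float = Field(ge=0)

    def to_domain(self) -> MortalityParams:
        return MortalityParams(eta=self.eta)


class TCMConfig(_Strict):
    n: int = Field(ge=1)
    k1: float = Field(gt=0)
    p: float = Field(default=1.0, ge=0, le=1)

    def to_domain(self) -> TCMParams:
        return TCMParams(n=self.n, k1=self.k1, p=self.p)


class PKConfig(_Strict):
    k01: float = Field(ge=0)
    k21: float = Field(ge=0)
    k12: float = Field(ge=0)
    V: float = Field(gt=0)

    def to_domain(self) -> PKParams:
        return PKParams(k01=self.k01, k21=self.k21, k12=self.k12, V=self.V)


class DoseEventConfig(_Strict):
    time: float = Field(ge=0)
    amount: float = Field(ge=0)
    route: Literal["bolus", "infusion"] = "bolus"


class ScheduleConfig(_Strict):
    events: list[DoseEventConfig]
    horizon: float = Field(gt=0)

    def to_domain(self) -> DoseSchedule:
        return DoseSchedule(
            events=tuple(DoseEvent(e.time, e.amount, e.route) for e in self.events),
            horizon=self.horizon,
        )


class SolverConfig(_Strict):
    method: str = "LSODA"
    rtol: float = Field(default=1e-8, gt=0)
    atol: float = Field(default=1e-10, gt=0)


class RunConfig(_Strict):
    """Complete description of a simulation/fit scenario."""

    name: str = "run"
    model: Literal["erlang", "coxian"] = "coxian"
    growth: GrowthConfig
    mortality: MortalityConfig
    tcm: TCMConfig
    pk: Optional[PKConfig] = None
    schedule: Optional[ScheduleConfig] = None
    concentrations: Optional[list[float]] = None
    sample_times: Optional[list[float]] = None
    w0: float = Field(gt=0)
    time_unit: Literal["day", "hour"] = "day"
    solver: SolverConfig = SolverConfig()
    seed: int = 0

    @model_validator(mode="after")
    def _check_drive(self) -> "RunConfig":
        if self.schedule is not None and self.pk is None:
            raise ValueError("a dose schedule requires PK parameters")
        return self

    def to_domain(self) -> dict:
        """Domain parameter objects keyed by role."""
        out = {
            "model": self.model,
            "growth": self.growth.to_domain(),
            "mortality": self.mortality.to_domain(),
            "tcm": self.tcm.to_domain(),
            "w0": self.w0,
        }
        if self.pk is not None:
            out["pk"] = self.pk.to_domain()
        if self.schedule is not None:
            out["schedule"] = self.schedule.to_domain()
        if self.concentrations is not None:
            out["concentrations"] = list(self.concentrations)
        if self.sample_times is not None:
            out["sample_times"] = list(self.sample_times)
        return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    data = (
        yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    )
    if not isinstance(data, dict):
        raise ValueError(f"config {path} does not contain a mapping")
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.model_dump(exclude_none=True)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def bundled_config(name: Literal["mouse150", "spheroid"]) -> RunConfig:
    """Load a fixture shipped with the package."""
    ref = resources.files("coxtcm").joinpath(f"fixtures/{name}.json")
    return RunConfig.model_validate(json.loads(ref.read_text()))


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical JSON dump (provenance tag for outputs)."""
    payload = json.dumps(config.model_dump(exclude_none=True), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance_line(config: RunConfig | None, seed: int | None = None) -> str:
    parts = [f"# coxtcm {__version__}"]
    if config is not None:
        parts.append(f"config_sha256={config_hash(config)}")
        parts.append(f"time_unit={config.time_unit}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """CSV with a leading provenance comment line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_line(config, seed) + "\n")
        frame.to_csv(fh, index=False)


def read_observations(path: str | Path) -> list[ObservationSeries]:
    """Read observation CSV (columns: time, value [, label, concentration])."""
    frame = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in frame.columns}
    if "time" not in cols or "value" not in cols:
        raise ValueError(f"{path}: observation CSV needs 'time' and 'value' columns")
    label_col = cols.get("label")
    conc_col = cols.get("concentration")
    out = []
    groups = frame.groupby(label_col, sort=False) if label_col else [("", frame)]
    for label, g in groups:
        conc = float(g[conc_col].iloc[0]) if conc_col else None
        out.append(
            ObservationSeries(
                times=g[cols["time"]].to_numpy(float),
                values=g[cols["value"]].to_numpy(float),
                label=str(label),
                concentration=conc,
            )
        )
    return out


def write_observations(
    series: list[ObservationSeries],
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    rows = []
    for s in series:
        for t, v in zip(s.times, s.values):
            row = {"time": t, "value": v, "label": s.label}
            if s.concentration is not None:
                row["concentration"] = s.concentration
            rows.append(row)
    write_table(pd.DataFrame(rows), path, config, seed)
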