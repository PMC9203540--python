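"""Synthetic datasets mirroring the two study designs.

Two designs are emulated so the whole pipeline is testable without any
measurement files:

* **Xenograft** — tumor implanted at day 0 with w0 = 0.0121 g, ten daily
  boluses of 4.5e7 from day 13, tumor weight sampled (by default) at ten
  uniformly spaced days over 13..40 (the source series' sampling days are
  not published, so the uniform design is a synthetic choice).
* **Spheroid** — constant drug concentration per group (0 = control), the
  design's eight sampling hours 0, 1, 2, 3, 6, 24, 48, 72, optionally 30
  replicates per group.

The default measurement noise is multiplicative lognormal with sigma =
0.05 (proportional error is the usual model for tumor burden readouts);
generation is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .estimation import ObservationSeries
from .pk_model import BolusConcentration, DoseSchedule, PKParams, daily_bolus_schedule
from .tcm_dynamics import GrowthParams, MortalityParams, TCMParams, simulate_tcm

__all__ = [
    "NoiseModel",
    "generate_xenograft_dataset",
    "generate_spheroid_dataset",
    "aggregate_replicates",
    "SPHEROID_SAMPLE_HOURS",
]

SPHEROID_SAMPLE_HOURS = (0.0, 1.0, 2.0, 3.0, 6.0, 24.0, 48.0, 72.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    ``proportional`` multiplies by exp(sigma * Z) (median-unbiased
    lognormal); ``additive`` adds sigma * Z truncated at zero; ``none``
    returns the model values untouched.
    """

    kind: Literal["none", "additive", "proportional"] = "proportional"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive", "proportional"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "none" or self.sigma == 0:
            return values.copy()
        z = rng.standard_normal(values.shape)
        if self.kind == "proportional":
            return values * np.exp(self.sigma * z)
        return np.clip(values + self.sigma * z, 0.0, None)


def generate_xenograft_dataset(
    growth: GrowthParams,
    mortality: MortalityParams,
    tcm: TCMParams,
    pk: PKParams,
    schedule: DoseSchedule | None = None,
    *,
    model: Literal["erlang", "coxian"] = "coxian",
    w0: float = 0.0121,
    sample_times: Sequence[float] | None = None,
    noise: NoiseModel = NoiseModel(),
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> tuple[ObservationSeries, dict]:
    """Simulate the multi-bolus xenograft design and sample tumor weight.

    Returns the observation series and a manifest dict recording the truth
    parameters and seed (for recovery tests).
    """
    if schedule is None:
        schedule = daily_bolus_schedule(start=13.0, n_doses=10, amount=4.5e7, horizon=40.0)
    times = (
        np.linspace(13.0, 40.0, 10) if sample_times is None
        else np.asarray(sample_times, dtype=float)
    )
    if times.max() > schedule.horizon:
        raise ValueError("sampling beyond the schedule horizon")
    conc = BolusConcentration(pk, schedule)
    grid = np.unique(np.concatenate(([0.0], times)))
    traj = simulate_tcm(model, growth, mortality, tcm, conc, w0, grid, rtol=rtol, atol=atol)
    clean = np.interp(times, traj.t, traj.w)
    rng = np.random.default_rng(noise.seed)
    values = noise.apply(clean, rng)
    series = ObservationSeries(times=times, values=values, label="xenograft")
    manifest = {
        "design": "xenograft",
        "model": model,
        "truth": {
            "growth": dataclasses.asdict(growth),
            "mortality": dataclasses.asdict(mortality),
            "tcm": dataclasses.asdict(tcm),
            "pk": dataclasses.asdict(pk),
            "w0": w0,
        },
        "noise": dataclasses.asdict(noise),
        "sample_times": times.tolist(),
    }
    return series, manifest


def generate_spheroid_dataset(
    growth: GrowthParams,
    mortality: MortalityParams,
    tcm: TCMParams,
    concentrations: Sequence[float] = (0.0, 5.0, 10.0),
    *,
    model: Literal["erlang", "coxian"] = "coxian",
    w0: float = 0.002,
    sample_times: Sequence[float] = SPHEROID_SAMPLE_HOURS,
    replicates: int = 1,
    noise: NoiseModel = NoiseModel(),
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> tuple[list[ObservationSeries], dict]:
    """Constant-concentration spheroid groups sampled at the design hours.

    One series per group when ``replicates == 1``; otherwise one series per
    replicate, labelled ``"<group>/repNN"``.  Group concentration 0 is the
    untreated control.
    """
    if growth.variant != "logistic":
        raise ValueError("spheroid design uses logistic growth")
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be nonnegative")
    times = np.asarray(sample_times, dtype=float)
    rng = np.random.default_rng(noise.seed)
    out: list[ObservationSeries] = []
    for c in concentrations:
        grid = np.unique(np.concatenate(([0.0], times)))
        traj = simulate_tcm(
            model, growth, mortality, tcm, float(c), w0, grid, rtol=rtol, atol=atol
        )
        clean = np.interp(times, traj.t, traj.w)
        label = "control" if c == 0 else f"{c:g}uM"
        if replicates == 1:
            out.append(
                ObservationSeries(
                    times=times, values=noise.apply(clean, rng),
                    label=label, concentration=float(c),
                )
            )
        else:
            for r in range(replicates):
                out.append(
                    ObservationSeries(
                        times=times, values=noise.apply(clean, rng),
                        label=f"{label}/rep{r:02d}", concentration=float(c),
                    )
                )
    manifest = {
        "design": "spheroid",
        "model": model,
        "truth": {
            "growth": dataclasses.asdict(growth),
            "mortality": dataclasses.asdict(mortality),
            "tcm": dataclasses.asdict(tcm),
            "w0": w0,
        },
        "concentrations": [float(c) for c in concentrations],
        "replicates": replicates,
        "noise": dataclasses.asdict(noise),
        "sample_times": times.tolist(),
    }
    return out, manifest


def aggregate_replicates(series: Sequence[ObservationSeries]) -> ObservationSeries:
    """Replicate mean with per-time standard deviation as dispersion."""
    if not series:
        raise ValueError("no replicates to aggregate")
    times = series[0].times
    for s in series[1:]:
        if not np.array_equal(s.times, times):
            raise ValueError("replicates must share sampling times")
    mat = np.vstack([s.values for s in series])
    label = series[0].label.split("/")[0]
    return ObservationSeries(
        times=times,
        values=mat.mean(axis=0),
        label=label,
        concentration=series[0].concentration,
        dispersion=mat.std(axis=0, ddof=1) if len(series) > 1 else None,
    )
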