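"""Perturbed tumor growth with transit-compartment delay.

The model splits the tumor into proliferating mass ``u`` and a cascade of
damaged-cell compartments ``y_1..y_n``.  Drug exposure moves mass from
``u`` into the cascade at rate ``k_out(C, u) = eta * C * u``; the cascade
then drains according to the chosen delay kernel:

* Erlang chain (classical Simeoni-type model)::

      du/dt   = k_in(u, w) - k_out(C, u)
      dy1/dt  = k_out(C, u) - k1 y1
      dyi/dt  = k1 (y_{i-1} - y_i),              i >= 2

* Coxian chain (continuation probability ``p``; ``p = 1`` recovers the
  Erlang chain exactly)::

      dyi/dt  = p k1 y_{i-1} - k1 y_i,           i >= 2

  so a fraction ``(1 - p)`` of each transition exits (sudden death)
  instead of continuing down the cascade.

Growth laws: the Simeoni dual-regime rate

    k_in(u, w) = lambda0 u / (1 + ((lambda0/lambda1) w)^phi)^(1/phi)

(exponential below the threshold w_th = lambda1/lambda0, linear above),
or logistic growth ``lambda0 (1 - w/umax) u``.

The module also provides the distributed-delay master equation

    dy/dt = k_out(C, u) - (k_out * f)(t)

solved by trapezoidal convolution on a fine uniform grid; the linear chain
trick makes this equivalent to the Erlang ODE chain, which is exploited as
an independent oracle in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .phase_type import CoxianSpec, ErlangSpec, PhaseTypeSpec, _as_phase_type

__all__ = [
    "GrowthParams",
    "MortalityParams",
    "TCMParams",
    "TumorState",
    "TrajectoryResult",
    "SimulationError",
    "growth_rate",
    "mortality_rate",
    "erlang_tcm_rhs",
    "coxian_tcm_rhs",
    "simulate_tcm",
    "convolution_oracle",
]

NEGATIVITY_TOL = 1e-9


@dataclass(frozen=True)
class GrowthParams:
    """Growth law and its constants.

    Simeoni: lambda0 (time^-1), lambda1 (mass time^-1), phi (sharpness).
    Logistic: lambda0 (time^-1), umax (carrying capacity).  ``saturation``
    selects whether the logistic bracket uses total mass w (default, as in
    the comparison study) or proliferating mass u only.
    """

    variant: Literal["simeoni", "logistic"]
    lambda0: float
    lambda1: float | None = None
    phi: float | None = None
    umax: float | None = None
    saturation: Literal["total", "proliferating"] = "total"

    def __post_init__(self) -> None:
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be positive")
        if self.variant == "simeoni":
            if self.lambda1 is None or not self.lambda1 > 0:
                raise ValueError("simeoni growth requires lambda1 > 0")
            if self.phi is None or not self.phi >= 1:
                raise ValueError("simeoni growth requires phi >= 1")
        elif self.variant == "logistic":
            if self.umax is None or not self.umax > 0:
                raise ValueError("logistic growth requires umax > 0")
        else:
            raise ValueError(f"unknown growth variant {self.variant!r}")

    @property
    def w_th(self) -> float:
        """Simeoni exponential-to-linear threshold lambda1/lambda0."""
        if self.variant != "simeoni":
            raise AttributeError("w_th is defined for the simeoni variant only")
        return self.lambda1 / self.lambda0


@dataclass(frozen=True)
class MortalityParams:
    """Drug potency eta (concentration^-1 time^-1) in k_out = eta C u."""

    eta: float

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")


@dataclass(frozen=True)
class TCMParams:
    """Cascade size n, transit rate k1 and mean continuation probability p."""

    n: int
    k1: float
    p: float = 1.0

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError("n must be an integer >= 1")
        if not self.k1 > 0:
            raise ValueError("k1 must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class TumorState:
    u: float
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", np.atleast_1d(np.asarray(self.y, dtype=float)))

    @property
    def w(self) -> float:
        return float(self.u + self.y.sum())

    def as_vector(self) -> np.ndarray:
        return np.concatenate(([self.u], self.y))


@dataclass(frozen=True)
class TrajectoryResult:
    """Dense simulation output: grid, states, concentration, provenance."""

    t: np.ndarray
    u: np.ndarray
    y: np.ndarray  # shape (len(t), n)
    C: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name in ("u", "y", "C"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in trajectory component {name}")

    @property
    def w(self) -> np.ndarray:
        return self.u + self.y.sum(axis=1)

    @property
    def total_damaged(self) -> np.ndarray:
        return self.y.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.t, "u": self.u}
        for i in range(self.y.shape[1]):
            cols[f"y{i + 1}"] = self.y[:, i]
        cols["w"] = self.w
        cols["C"] = self.C
        return pd.DataFrame(cols)


class SimulationError(RuntimeError):
    """Integration failure; ``t_last`` is the last successfully reached time."""

    def __init__(self, message: str, t_last: float) -> None:
        super().__init__(message)
        self.t_last = t_last


def _growth_rate(u: float, w: float, params: GrowthParams) -> float:
    # formula-level evaluation, tolerant of tiny solver under/overshoot
    if params.variant == "logistic":
        x = w if params.saturation == "total" else u
        return params.lambda0 * (1.0 - x / params.umax) * u
    # Simeoni in log domain: (1 + r^phi)^(1/phi) with r = (lambda0/lambda1) w
    r = (params.lambda0 / params.lambda1) * w
    if r <= 0.0:
        return params.lambda0 * u
    denom = math.exp(np.logaddexp(0.0, params.phi * math.log(r)) / params.phi)
    return params.lambda0 * u / denom


def growth_rate(u: float, w: float, params: GrowthParams) -> float:
    """Growth inflow k_in(u, w); raises on negative state."""
    if u < 0 or w < 0:
        raise ValueError("u and w must be nonnegative")
    return _growth_rate(u, w, params)


def mortality_rate(C: float, u: float, params: MortalityParams) -> float:
    """Drug-driven kill rate k_out(C, u) = eta * C * u."""
    if C < 0 or u < 0:
        raise ValueError("C and u must be nonnegative")
    return params.eta * C * u


def _state_vector(state) -> np.ndarray:
    if isinstance(state, TumorState):
        return state.as_vector()
    return np.asarray(state, dtype=float)


def erlang_tcm_rhs(
    state,
    C: float,
    growth: GrowthParams,
    mortality: MortalityParams,
    tcm: TCMParams,
) -> np.ndarray:
    """Right-hand side of the Erlang chain; returns d/dt of (u, y1..yn)."""
    v = _state_vector(state)
    if v.size != tcm.n + 1:
        raise ValueError(f"state has {v.size - 1} cascade compartments, expected {tcm.n}")
    u, y = v[0], v[1:]
    w = v.sum()
    k_out = mortality.eta * C * u
    d = np.empty_like(v)
    d[0] = _growth_rate(u, w, growth) - k_out
    d[1] = k_out - tcm.k1 * y[0]
    if tcm.n > 1:
        d[2:] = tcm.k1 * (y[:-1] - y[1:])
    return d


def coxian_tcm_rhs(
    state,
    C: float,
    growth: GrowthParams,
    mortality: MortalityParams,
    tcm: TCMParams,
) -> np.ndarray:
    """Coxian chain: downstream transitions carry probability p; the
    complementary (1-p) k1 flux exits the system (sudden death)."""
    if not 0.0 <= tcm.p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    v = _state_vector(state)
    if v.size != tcm.n + 1:
        raise ValueError(f"state has {v.size - 1} cascade compartments, expected {tcm.n}")
    u, y = v[0], v[1:]
    w = v.sum()
    k_out = mortality.eta * C * u
    d = np.empty_like(v)
    d[0] = _growth_rate(u, w, growth) - k_out
    d[1] = k_out - tcm.k1 * y[0]
    if tcm.n > 1:
        d[2:] = tcm.p * tcm.k1 * y[:-1] - tcm.k1 * y[1:]
    return d


_RHS = {"erlang": erlang_tcm_rhs, "coxian": coxian_tcm_rhs}


def _concentration_callable(concentration) -> tuple[Callable, tuple[float, ...]]:
    if callable(concentration):
        return concentration, tuple(getattr(concentration, "event_times", ()))
    c = float(concentration)
    if c < 0:
        raise ValueError("constant concentration must be nonnegative")
    return (lambda t: c), ()


def simulate_tcm(
    model: Literal["erlang", "coxian"],
    growth: GrowthParams,
    mortality: MortalityParams,
    tcm: TCMParams,
    concentration,
    w0: float,
    grid: Sequence[float],
    *,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    negativity_tol: float = NEGATIVITY_TOL,
) -> TrajectoryResult:
    """Integrate a TCM from the undamaged initial state u = w0, y = 0.

    ``concentration`` is a scalar (constant infusion) or a callable C(t),
    optionally exposing ``event_times`` (dose discontinuities) at which the
    integration is restarted.  Components dipping below ``-negativity_tol``
    raise :class:`SimulationError` rather than being clipped.
    """
    if model not in _RHS:
        raise ValueError(f"unknown model {model!r}")
    if w0 < 0:
        raise ValueError("w0 must be nonnegative")
    rhs_fn = _RHS[model]
    conc, event_times = _concentration_callable(concentration)
    grid = np.asarray(grid, dtype=float)
    t0, t1 = float(grid[0]), float(grid[-1])
    boundaries = sorted({t0, t1, *(te for te in event_times if t0 < te < t1)})

    def rhs(t, v):
        return rhs_fn(v, conc(t), growth, mortality, tcm)

    v = np.concatenate(([w0], np.zeros(tcm.n)))
    out = np.empty((grid.size, tcm.n + 1))
    for a, b in zip(boundaries, boundaries[1:]):
        mask = (grid >= a) & ((grid < b) if b < t1 else (grid <= b))
        sol = solve_ivp(rhs, (a, b), v, method=method, rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            raise SimulationError(f"solver failed on [{a}, {b}]: {sol.message}", t_last=sol.t[-1])
        if mask.any():
            out[mask] = sol.sol(grid[mask]).T
        v = sol.y[:, -1]
        low = min(v.min(), out[mask].min() if mask.any() else 0.0)
        if low < -negativity_tol:
            raise SimulationError(
                f"state undershot below -{negativity_tol:g} (min {low:.3e}) on [{a}, {b}]",
                t_last=b,
            )

    c_grid = np.asarray([conc(t) for t in grid], dtype=float)
    return TrajectoryResult(
        t=grid,
        u=out[:, 0],
        y=out[:, 1:],
        C=c_grid,
        metadata={
            "model": model,
            "growth": growth,
            "mortality": mortality,
            "tcm": tcm,
            "w0": w0,
            "method": method,
            "rtol": rtol,
            "atol": atol,
        },
    )


def _kernel_density_on_grid(kernel, h: float, m: int) -> np.ndarray:
    """f at grid offsets 0, h, ..., m h via one step-matrix recursion."""
    ph: PhaseTypeSpec = _as_phase_type(kernel)
    M = expm(ph.S * h)
    v = ph.alpha.copy()
    f = np.empty(m + 1)
    for j in range(m + 1):
        f[j] = v @ ph.S0
        v = v @ M
    return f


def convolution_oracle(
    growth: GrowthParams,
    mortality: MortalityParams,
    kernel,
    concentration,
    w0: float,
    grid: Sequence[float],
    *,
    refine_check: bool = False,
):
    """Solve the distributed-delay master equation on a uniform grid.

    dy/dt = k_out(C, u) - integral_0^t k_out(C(t-a), u(t-a)) f(a) da, with
    du/dt = k_in - k_out co-integrated by Heun's method and the convolution
    evaluated by the composite trapezoidal rule.  Dose discontinuities must
    fall on grid nodes; k_out being linear in C, node values at a jump use
    the two-sided mean concentration so the quadrature retains second-order
    accuracy.

    Returns ``(t, u, y)``; with ``refine_check=True`` also returns the
    Richardson half-step estimate of the y-error (a warning-level
    self-check for grid adequacy).
    """
    kernel = _as_phase_type(kernel)
    conc, event_times = _concentration_callable(concentration)
    t = np.asarray(grid, dtype=float)
    h = t[1] - t[0]
    if not np.allclose(np.diff(t), h, rtol=1e-8):
        raise ValueError("convolution oracle requires a uniform grid")
    for te in event_times:
        if t[0] < te < t[-1]:
            k = round((te - t[0]) / h)
            if abs(t[0] + k * h - te) > 1e-9 * max(1.0, abs(te)):
                raise ValueError(f"dose event at t={te} does not fall on a grid node")

    m = t.size - 1
    f = _kernel_density_on_grid(kernel, h, m)
    eps = 1e-12 * max(h, 1.0)
    jump_nodes = {round((te - t[0]) / h) for te in event_times if t[0] < te < t[-1]}

    def c_sided(j: int) -> tuple[float, float]:
        tj = t[j]
        if j in jump_nodes:
            return conc(tj - eps), conc(tj + eps)
        c = conc(tj)
        return c, c

    c_left = np.empty(m + 1)
    c_right = np.empty(m + 1)
    for j in range(m + 1):
        c_left[j], c_right[j] = c_sided(j)
    c_mean = 0.5 * (c_left + c_right)

    eta = mortality.eta

    def run(tarr, c_l, c_r, c_m, fdens, u0):
        nsteps = tarr.size - 1
        uu = np.empty(nsteps + 1)
        yy = np.empty(nsteps + 1)
        gm = np.empty(nsteps + 1)
        uu[0] = u0
        yy[0] = 0.0
        gm[0] = eta * c_m[0] * u0
        step = tarr[1] - tarr[0]
        frev = fdens  # f at offsets
        for j in range(nsteps):
            uj, yj = uu[j], yy[j]
            # convolution at t_j (trapezoid over a in [0, t_j])
            if j == 0:
                conv_j = 0.0
            else:
                seg = gm[j::-1] * frev[: j + 1]
                conv_j = step * (seg.sum() - 0.5 * (seg[0] + seg[-1]))
            g_j_right = eta * c_r[j] * uj  # step start uses the post-dose value
            du_j = _growth_rate(uj, uj + yj, growth) - g_j_right
            dy_j = g_j_right - conv_j
            # predictor
            up = uj + step * du_j
            yp = yj + step * dy_j
            g_next_left = eta * c_l[j + 1] * up
            gm_next = eta * c_m[j + 1] * up
            seg = np.concatenate(([gm_next], gm[j::-1])) * frev[: j + 2]
            conv_next = step * (seg.sum() - 0.5 * (seg[0] + seg[-1]))
            du_n = _growth_rate(up, up + yp, growth) - g_next_left
            dy_n = g_next_left - conv_next
            # corrector
            uu[j + 1] = uj + 0.5 * step * (du_j + du_n)
            yy[j + 1] = yj + 0.5 * step * (dy_j + dy_n)
            gm[j + 1] = eta * c_m[j + 1] * uu[j + 1]
        return uu, yy

    u, y = run(t, c_left, c_right, c_mean, f, float(w0))

    if not refine_check:
        return t, u, y

    t2 = np.linspace(t[0], t[-1], 2 * m + 1)
    f2 = _kernel_density_on_grid(kernel, h / 2, 2 * m)
    jump2 = {2 * j for j in jump_nodes}
    cl2 = np.empty(2 * m + 1)
    cr2 = np.empty(2 * m + 1)
    for j in range(2 * m + 1):
        if j in jump2:
            cl2[j], cr2[j] = conc(t2[j] - eps), conc(t2[j] + eps)
        else:
            cl2[j] = cr2[j] = conc(t2[j])
    cm2 = 0.5 * (cl2 + cr2)
    u2, y2 = run(t2, cl2, cr2, cm2, f2, float(w0))
    err = float(np.max(np.abs(y2[::2] - y)))
    return t, u, y, err
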