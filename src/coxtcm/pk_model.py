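"""Two-compartment pharmacokinetics driving the tumor models.

State: drug amounts ``q1`` (plasma/central) and ``q2`` (peripheral) with

    dq1/dt = -(k01 + k21) q1 + k12 q2 + v(t)
    dq2/dt = k21 q1 - k12 q2
    C(t)   = q1(t) / V

``v(t)`` carries bolus injections (instantaneous jumps in q1) or piecewise
constant infusion rates.  Elimination (k01) acts on the central compartment
only, so between dose events total drug q1 + q2 is non-increasing.
Amounts, volume and concentration are kept on the mouse-150 dataset's
reported scale (ng kg^-1, ml, ng ml^-1) without unit conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PKParams",
    "DoseEvent",
    "DoseSchedule",
    "PKProfile",
    "pk_simulate",
    "pk_matrix_exponential_solution",
    "BolusConcentration",
    "ConstantConcentration",
    "constant_infusion_concentration",
    "daily_bolus_schedule",
]


@dataclass(frozen=True)
class PKParams:
    """Rate constants (time^-1) and central volume (ml)."""

    k01: float
    k21: float
    k12: float
    V: float

    def __post_init__(self) -> None:
        for name in ("k01", "k21", "k12"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.V > 0:
            raise ValueError("V must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """System matrix A with dq/dt = A q between dose events."""
        return np.array(
            [
                [-(self.k01 + self.k21), self.k12],
                [self.k21, -self.k12],
            ]
        )


@dataclass(frozen=True)
class DoseEvent:
    time: float
    amount: float
    route: Literal["bolus", "infusion"] = "bolus"

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("dose amount must be nonnegative")
        if self.route not in ("bolus", "infusion"):
            raise ValueError(f"unknown route {self.route!r}")


@dataclass(frozen=True)
class DoseSchedule:
    """Event list; an infusion event holds its rate until the next event."""

    events: tuple[DoseEvent, ...]
    horizon: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(t < 0 or t > self.horizon for t in times):
            raise ValueError("event times must lie within [0, horizon]")

    @property
    def event_times(self) -> tuple[float, ...]:
        return tuple(e.time for e in self.events)

    @property
    def bolus_only(self) -> bool:
        return all(e.route == "bolus" for e in self.events)


def daily_bolus_schedule(
    start: float, n_doses: int, amount: float, horizon: float
) -> DoseSchedule:
    """``n_doses`` equal boluses at days start, start+1, ..."""
    events = tuple(DoseEvent(start + i, amount) for i in range(n_doses))
    return DoseSchedule(events=events, horizon=horizon)


@dataclass(frozen=True)
class PKProfile:
    """Dense concentration profile on a time grid."""

    t: np.ndarray
    q1: np.ndarray
    q2: np.ndarray
    C: np.ndarray


def _check_grid(schedule: DoseSchedule, grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < 0 or grid.max() > schedule.horizon):
        raise ValueError("grid must lie within [0, horizon]")
    return grid


def pk_simulate(
    params: PKParams,
    schedule: DoseSchedule,
    grid: Sequence[float],
    *,
    bolus_mode: Literal["add", "reset"] = "add",
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> PKProfile:
    """Integrate the two-compartment system piecewise between dose events.

    At each bolus the central amount jumps by the dose (``bolus_mode="add"``,
    the standard superposition convention) or is reset to the dose amount
    (``bolus_mode="reset"``).  Integration restarts at every event so the
    solver never steps across a discontinuity.
    """
    grid = _check_grid(schedule, grid)
    A = params.matrix
    boundaries = sorted({0.0, schedule.horizon, *schedule.event_times})
    events_at = {e.time: e for e in schedule.events}
    q = np.zeros(2)
    rate = 0.0
    out_q = np.zeros((grid.size, 2))

    for t0, t1 in zip(boundaries, boundaries[1:]):
        ev = events_at.get(t0)
        if ev is not None:
            if ev.route == "bolus":
                q = q.copy()
                q[0] = q[0] + ev.amount if bolus_mode == "add" else ev.amount
            else:
                rate = ev.amount
        mask = (grid >= t0) & (grid < t1) if t1 < schedule.horizon else (
            (grid >= t0) & (grid <= t1)
        )
        t_eval = grid[mask]
        rhs_rate = rate

        def rhs(t, y, _r=rhs_rate):
            return A @ y + np.array([_r, 0.0])

        sol = solve_ivp(
            rhs,
            (t0, t1),
            q,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"PK integration failed on [{t0}, {t1}]: {sol.message}")
        if t_eval.size:
            out_q[mask] = sol.sol(t_eval).T
        q = sol.y[:, -1]

    return PKProfile(t=grid, q1=out_q[:, 0], q2=out_q[:, 1], C=out_q[:, 0] / params.V)


class BolusConcentration:
    """Exact C(t) for a bolus-only schedule via the matrix exponential.

    Precomputes the eigendecomposition of the 2x2 system matrix and the
    post-dose states at every event, so evaluation at arbitrary t is O(1)
    per past-event lookup.  Serves both as the independent PK oracle and as
    the fast concentration callable driving tumor simulations.
    """

    def __init__(
        self,
        params: PKParams,
        schedule: DoseSchedule,
        *,
        bolus_mode: Literal["add", "reset"] = "add",
    ) -> None:
        if not schedule.bolus_only:
            raise ValueError("matrix-exponential solution supports bolus events only")
        self.params = params
        self.schedule = schedule
        A = params.matrix
        lam, W = np.linalg.eig(A)
        self._lam = lam.real
        self._W = W.real
        self._Winv = np.linalg.inv(W).real
        # post-dose states at each event time
        self._times = np.array(schedule.event_times)
        states = []
        q = np.zeros(2)
        prev_t = None
        for ev in schedule.events:
            if prev_t is not None:
                q = self._propagate(q, ev.time - prev_t)
            q = q.copy()
            q[0] = q[0] + ev.amount if bolus_mode == "add" else ev.amount
            states.append(q)
            prev_t = ev.time
        self._states = np.array(states) if states else np.zeros((0, 2))

    def _propagate(self, q: np.ndarray, dt: float) -> np.ndarray:
        coeff = self._Winv @ q
        return self._W @ (np.exp(self._lam * dt) * coeff)

    @property
    def event_times(self) -> tuple[float, ...]:
        return self.schedule.event_times

    def amounts(self, t) -> np.ndarray:
        """q(t) with the convention that C(t_in) is the post-dose value."""
        arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros((arr.size, 2))
        if self._times.size:
            idx = np.searchsorted(self._times, arr, side="right") - 1
            for i, (ti, j) in enumerate(zip(arr, idx)):
                if j >= 0:
                    out[i] = self._propagate(self._states[j], ti - self._times[j])
        return out

    def __call__(self, t):
        q = self.amounts(t)
        c = q[:, 0] / self.params.V
        return float(c[0]) if np.ndim(t) == 0 else c

    @property
    def eigenvalues(self) -> np.ndarray:
        """Disposition eigenvalues; the slow one sets the terminal log-slope."""
        return np.sort(self._lam)


def pk_matrix_exponential_solution(
    params: PKParams,
    schedule: DoseSchedule,
    grid: Sequence[float],
    *,
    bolus_mode: Literal["add", "reset"] = "add",
) -> PKProfile:
    """Exact bolus-superposition solution on a grid (independent PK oracle)."""
    grid = _check_grid(schedule, grid)
    sol = BolusConcentration(params, schedule, bolus_mode=bolus_mode)
    q = sol.amounts(grid)
    return PKProfile(t=grid, q1=q[:, 0], q2=q[:, 1], C=q[:, 0] / params.V)


class ConstantConcentration:
    """Constant infusion steady state C(t) = Cbar."""

    def __init__(self, Cbar: float) -> None:
        if Cbar < 0:
            raise ValueError("Cbar must be nonnegative")
        self.Cbar = float(Cbar)

    event_times: tuple[float, ...] = ()

    def __call__(self, t):
        if np.ndim(t) == 0:
            return self.Cbar
        return np.full(np.shape(t), self.Cbar)


def constant_infusion_concentration(params: PKParams, Cbar: float) -> ConstantConcentration:
    """Steady constant-concentration profile used by the equilibrium analysis."""
    return ConstantConcentration(Cbar)
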