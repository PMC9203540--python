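"""Phase-type distributions for transit-compartment delay kernels.

A phase-type distribution is the absorption-time law of a finite
continuous-time Markov chain with one absorbing state.  It is specified by
an initial probability row vector ``alpha`` over the transient phases, a
sub-generator matrix ``S`` (negative diagonal, nonnegative off-diagonal)
and the exit-rate vector ``S0 = -S @ 1``.  Its density is
``f(t) = alpha @ expm(S t) @ S0`` and its CDF ``F(t) = 1 - alpha @ expm(S t) @ 1``.

Two members of the family matter for transit-compartment tumor models:

* **Erlang(n, k1)** — the residence-time law of a chain of ``n`` identical
  compartments with common transit rate ``k1`` (total mean residence time
  ``n / k1``).  This is the kernel behind the classical Simeoni-type model.
* **Coxian(n, k, p)** — a chain where a cell in phase ``i`` either continues
  to phase ``i + 1`` with probability ``p_i`` or exits (dies) immediately.
  It generalizes the Erlang law (all ``p_i = 1``) and models sudden death
  at any age within the damaged-cell cascade.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "ErlangSpec",
    "CoxianSpec",
    "PhaseTypeSpec",
    "erlang_density",
    "erlang_phase_type",
    "coxian_generator",
    "phase_density",
    "phase_cdf",
    "phase_moments",
    "sample_absorption_times",
    "spec_to_json",
    "spec_from_json",
]

_ALPHA_TOL = 1e-12


@dataclass(frozen=True)
class ErlangSpec:
    """Erlang delay kernel: ``n`` phases with common rate ``k1`` (time^-1)."""

    n: int
    k1: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be an integer >= 1, got {self.n!r}")
        if not self.k1 > 0:
            raise ValueError(f"k1 must be positive, got {self.k1!r}")

    @property
    def mean(self) -> float:
        """Total mean residence time n / k1."""
        return self.n / self.k1


@dataclass(frozen=True)
class CoxianSpec:
    """Coxian kernel: phase rates ``k_i`` and continuation probabilities ``p_i``.

    ``p_n`` must be 0 (the last phase always exits).  If all ``p_i = 1`` for
    ``i < n`` and the ``k_i`` are equal, the distribution reduces to
    Erlang(n, k1).
    """

    n: int
    k: tuple[float, ...]
    p: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", tuple(float(v) for v in self.k))
        object.__setattr__(self, "p", tuple(float(v) for v in self.p))
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be an integer >= 1, got {self.n!r}")
        if len(self.k) != self.n or len(self.p) != self.n:
            raise ValueError("k and p must both have length n")
        if any(not v > 0 for v in self.k):
            raise ValueError("all phase rates k_i must be positive")
        if any(not (0.0 <= v <= 1.0) for v in self.p):
            raise ValueError("continuation probabilities p_i must lie in [0, 1]")
        if self.p[-1] != 0.0:
            raise ValueError("p_n must be 0 (the last phase always exits)")

    @classmethod
    def mean_reduced(cls, n: int, k1: float, p: float) -> "CoxianSpec":
        """Mean-parameter Coxian: all rates k1, all continuation probs p (p_n=0)."""
        probs = tuple([float(p)] * (n - 1) + [0.0])
        return cls(n=n, k=tuple([float(k1)] * n), p=probs)


@dataclass(frozen=True)
class PhaseTypeSpec:
    """General phase-type representation (alpha, S, S0)."""

    alpha: np.ndarray
    S: np.ndarray
    S0: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        S = np.atleast_2d(np.asarray(self.S, dtype=float))
        n = alpha.size
        if S.shape != (n, n):
            raise ValueError(f"S must be {n}x{n} to match alpha, got {S.shape}")
        S0 = -S @ np.ones(n) if self.S0 is None else np.asarray(self.S0, dtype=float)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "S0", S0)
        if np.any(np.diag(S) >= 0):
            raise ValueError("diagonal of S must be strictly negative")
        off = S - np.diag(np.diag(S))
        if np.any(off < 0):
            raise ValueError("off-diagonal entries of S must be nonnegative")
        if not np.allclose(S0, -S @ np.ones(n), rtol=0, atol=1e-10):
            raise ValueError("S0 must equal -S @ 1")
        if np.any(S0 < -1e-12):
            raise ValueError("exit rates S0 must be nonnegative")
        if np.any(alpha < -_ALPHA_TOL) or np.any(alpha > 1 + _ALPHA_TOL):
            raise ValueError("alpha entries must lie in [0, 1]")
        if abs(alpha.sum() - 1.0) > _ALPHA_TOL:
            raise ValueError("alpha must sum to 1")

    @property
    def n(self) -> int:
        return self.alpha.size


def erlang_density(a, spec: ErlangSpec):
    """Erlang density f_n(a) = k1 (k1 a)^{n-1} e^{-k1 a} / (n-1)!.

    Evaluated through the gamma density with integer shape ``n`` and scale
    ``1/k1``.  Scalar or array ``a``; negative ages raise.
    """
    arr = np.asarray(a, dtype=float)
    if np.any(arr < 0):
        raise ValueError("age a must be nonnegative")
    out = _gamma_dist.pdf(arr, spec.n, scale=1.0 / spec.k1)
    return float(out) if np.isscalar(a) or arr.ndim == 0 else out


def erlang_phase_type(spec: ErlangSpec) -> PhaseTypeSpec:
    """Phase-type form of Erlang(n, k1): diagonal -k1, superdiagonal k1."""
    n, k1 = spec.n, spec.k1
    S = -k1 * np.eye(n) + k1 * np.eye(n, k=1)
    alpha = np.zeros(n)
    alpha[0] = 1.0
    return PhaseTypeSpec(alpha=alpha, S=S)


def coxian_generator(spec: CoxianSpec) -> PhaseTypeSpec:
    """Build the Coxian sub-generator.

    alpha = (1, 0, ..., 0); S has diagonal ``-k_i`` and superdiagonal
    ``p_i k_i``; the implied exit rates are ``(1 - p_i) k_i`` for ``i < n``
    and ``k_n`` for the last phase.
    """
    n = spec.n
    k = np.asarray(spec.k)
    p = np.asarray(spec.p)
    S = -np.diag(k)
    if n > 1:
        S += np.diag(p[:-1] * k[:-1], k=1)
    alpha = np.zeros(n)
    alpha[0] = 1.0
    return PhaseTypeSpec(alpha=alpha, S=S)


def _as_phase_type(spec) -> PhaseTypeSpec:
    if isinstance(spec, PhaseTypeSpec):
        return spec
    if isinstance(spec, ErlangSpec):
        return erlang_phase_type(spec)
    if isinstance(spec, CoxianSpec):
        return coxian_generator(spec)
    raise TypeError(f"cannot interpret {type(spec).__name__} as a phase-type spec")


def phase_density(spec, t):
    """Density f(t) = alpha @ expm(S t) @ S0 for scalar or array t >= 0."""
    ph = _as_phase_type(spec)
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(arr < 0):
        raise ValueError("t must be nonnegative")
    out = np.empty(arr.shape)
    for i, ti in enumerate(arr.flat):
        M = expm(ph.S * ti)
        if not np.all(np.isfinite(M)):
            raise FloatingPointError(
                f"matrix exponential not finite at t={ti} (spectral scale "
                f"{np.abs(np.diag(ph.S)).max():.3g})"
            )
        out.flat[i] = ph.alpha @ M @ ph.S0
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def phase_cdf(spec, t):
    """CDF F(t) = 1 - alpha @ expm(S t) @ 1."""
    ph = _as_phase_type(spec)
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(arr < 0):
        raise ValueError("t must be nonnegative")
    ones = np.ones(ph.n)
    out = np.empty(arr.shape)
    for i, ti in enumerate(arr.flat):
        out.flat[i] = 1.0 - ph.alpha @ expm(ph.S * ti) @ ones
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def phase_moments(spec) -> float:
    """Mean residence time -alpha @ S^{-1} @ 1 (equals n/k1 for Erlang)."""
    ph = _as_phase_type(spec)
    try:
        x = np.linalg.solve(ph.S, np.ones(ph.n))
    except np.linalg.LinAlgError as err:
        raise ValueError("sub-generator S is singular; mean undefined") from err
    return float(-ph.alpha @ x)


def sample_absorption_times(spec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo absorption times of the underlying Markov chain.

    Vectorized jump-chain simulation: in phase i the holding time is
    Exponential(-S_ii); the chain then exits with probability S0_i/(-S_ii)
    or jumps to phase j with probability S_ij/(-S_ii).
    """
    ph = _as_phase_type(spec)
    n = ph.n
    rates = -np.diag(ph.S)
    jump = ph.S - np.diag(np.diag(ph.S))
    # per-phase categorical over (exit, j=0..n-1)
    probs = np.column_stack([ph.S0 / rates, jump / rates[:, None]])
    cum = np.cumsum(probs, axis=1)
    state = rng.choice(n, size=size, p=ph.alpha)
    times = np.zeros(size)
    active = np.arange(size)
    max_jumps = 1000 * n
    for _ in range(max_jumps):
        if active.size == 0:
            return times
        s = state[active]
        times[active] += rng.exponential(1.0 / rates[s])
        u = rng.random(active.size)
        nxt = (u[:, None] > cum[s]).sum(axis=1)  # 0 => absorbed, else phase nxt-1
        absorbed = nxt == 0
        state[active[~absorbed]] = nxt[~absorbed] - 1
        active = active[~absorbed]
    raise RuntimeError("absorption not reached within jump budget")


def spec_to_json(spec) -> str:
    """Serialize an Erlang or Coxian spec to a JSON config object."""
    if isinstance(spec, ErlangSpec):
        return json.dumps({"n": spec.n, "k1": spec.k1})
    if isinstance(spec, CoxianSpec):
        return json.dumps({"n": spec.n, "k": list(spec.k), "p": list(spec.p)})
    raise TypeError("only ErlangSpec and CoxianSpec are JSON-serializable")


def spec_from_json(text: str):
    """Inverse of :func:`spec_to_json`; dispatches on the keys present."""
    obj = json.loads(text)
    if "k1" in obj:
        return ErlangSpec(n=int(obj["n"]), k1=float(obj["k1"]))
    return CoxianSpec(n=int(obj["n"]), k=tuple(obj["k"]), p=tuple(obj["p"]))
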