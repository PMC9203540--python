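"""Equilibria and stability under constant drug infusion.

With a steady concentration C̄ the long-run fate of the tumor is decided by
the threshold concentration lambda0/eta: above it the only equilibrium is
extinction (u = y_i = 0) and it is asymptotically stable; below it a
nonzero equilibrium appears with

    ybar_i = (eta C̄ ubar / k1) p^(i-1),   i = 1..n,
    wbar   = ubar (1 + (eta C̄ / k1) g(p, n)),   g(p, n) = sum_{i<n} p^i,

while ubar follows from the growth law's steady state k_in(u, w) = eta C̄ u:

* Simeoni (finite phi, solved exactly in the log domain):
      wbar = (lambda1/lambda0) ((lambda0/(eta C̄))^phi - 1)^(1/phi)
  The familiar large-phi form wbar = lambda1/(eta C̄) is reported alongside
  (it degrades badly near the threshold).
* Logistic (bracket on total mass w, the default):
      wbar = umax (1 - eta C̄ / lambda0)
  With the bracket on u only: ubar = umax (1 - eta C̄ / lambda0) directly.

Stability is classified from the eigenvalues of a numerically differenced
Jacobian of the full (n+1)-state system at the equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .tcm_dynamics import (
    GrowthParams,
    MortalityParams,
    TCMParams,
    coxian_tcm_rhs,
)

__all__ = [
    "EquilibriumResult",
    "StabilityVerdict",
    "geometric_factor",
    "equilibria_simeoni",
    "equilibria_logistic",
    "stability_classify",
]

_THRESHOLD_RTOL = 1e-12


@dataclass(frozen=True)
class EquilibriumResult:
    regime: Literal["zero-only", "zero-plus-nonzero", "continuum"]
    threshold: float  # lambda0 / eta
    Cbar: float
    ubar: float
    ybar: np.ndarray
    wbar: float
    reported_forms: dict = field(default_factory=dict)

    @property
    def nonzero(self) -> bool:
        return self.regime == "zero-plus-nonzero"


@dataclass(frozen=True)
class StabilityVerdict:
    stable: bool
    marginal: bool
    eigenvalues: np.ndarray
    max_real_part: float


def geometric_factor(p: float, n: int) -> float:
    """sum_{i=0}^{n-1} p^i, with the exact limit n at p = 1 (no division)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if p == 1.0:
        return float(n)
    return (1.0 - p**n) / (1.0 - p)


def _regime(Cbar: float, threshold: float) -> str:
    if math.isclose(Cbar, threshold, rel_tol=_THRESHOLD_RTOL):
        return "continuum"
    return "zero-only" if Cbar > threshold else "zero-plus-nonzero"


def _chain_equilibrium(wbar: float, Cbar: float, mortality, tcm) -> tuple[float, np.ndarray]:
    """Split steady total mass into (ubar, ybar_i) via the cascade balance."""
    g = geometric_factor(tcm.p, tcm.n)
    load = mortality.eta * Cbar / tcm.k1
    ubar = wbar / (1.0 + load * g)
    ybar = load * ubar * tcm.p ** np.arange(tcm.n)
    return ubar, ybar


def equilibria_simeoni(
    growth: GrowthParams,
    mortality: MortalityParams,
    tcm: TCMParams,
    Cbar: float,
) -> EquilibriumResult:
    """Equilibria of the Simeoni-growth TCM under constant infusion."""
    if growth.variant != "simeoni":
        raise ValueError("equilibria_simeoni requires simeoni growth")
    if Cbar < 0:
        raise ValueError("Cbar must be nonnegative")
    threshold = growth.lambda0 / mortality.eta
    regime = _regime(Cbar, threshold)
    if regime != "zero-plus-nonzero":
        return EquilibriumResult(
            regime=regime, threshold=threshold, Cbar=Cbar,
            ubar=0.0, ybar=np.zeros(tcm.n), wbar=0.0,
        )
    if Cbar == 0.0:
        raise ValueError(
            "unperturbed Simeoni growth is unbounded; no finite nonzero "
            "equilibrium at Cbar = 0"
        )
    # exact finite-phi steady state of k_in(u, w) = eta Cbar u, log domain:
    # wbar = (lambda1/lambda0) * expm1(phi * log(lambda0/(eta Cbar)))^(1/phi)
    ratio = growth.lambda0 / (mortality.eta * Cbar)  # > 1 here
    wbar = (growth.lambda1 / growth.lambda0) * math.exp(
        math.log(math.expm1(growth.phi * math.log(ratio))) / growth.phi
    )
    ubar, ybar = _chain_equilibrium(wbar, Cbar, mortality, tcm)
    # classical large-phi closed forms, reported for comparison
    g = geometric_factor(tcm.p, tcm.n)
    ec = mortality.eta * Cbar
    ubar_large_phi_form = growth.lambda1 / (ec + ec**2 / tcm.k1 * g)
    return EquilibriumResult(
        regime=regime, threshold=threshold, Cbar=Cbar,
        ubar=ubar, ybar=ybar, wbar=wbar,
        reported_forms={
            "ubar_large_phi": ubar_large_phi_form,
            "wbar_large_phi": growth.lambda1 / ec,
        },
    )


def equilibria_logistic(
    growth: GrowthParams,
    mortality: MortalityParams,
    tcm: TCMParams,
    Cbar: float,
) -> EquilibriumResult:
    """Equilibria of the logistic-growth TCM under constant infusion.

    Computed by direct steady-state solution of the ODE system; the
    alternative closed forms in circulation for ybar_n and wbar (which drop
    the p^(n-1) factor) are reported in ``reported_forms`` for comparison
    only — they are not consistent with the cascade balance.
    """
    if growth.variant != "logistic":
        raise ValueError("equilibria_logistic requires logistic growth")
    if Cbar < 0:
        raise ValueError("Cbar must be nonnegative")
    threshold = growth.lambda0 / mortality.eta
    regime = _regime(Cbar, threshold)
    if regime != "zero-plus-nonzero":
        # at Cbar exactly on threshold the logistic model still has only zero
        regime = "zero-only"
        return EquilibriumResult(
            regime=regime, threshold=threshold, Cbar=Cbar,
            ubar=0.0, ybar=np.zeros(tcm.n), wbar=0.0,
        )
    depletion = 1.0 - mortality.eta * Cbar / growth.lambda0
    if growth.saturation == "total":
        wbar = growth.umax * depletion
        ubar, ybar = _chain_equilibrium(wbar, Cbar, mortality, tcm)
    else:
        ubar = growth.umax * depletion
        load = mortality.eta * Cbar / tcm.k1
        ybar = load * ubar * tcm.p ** np.arange(tcm.n)
        wbar = ubar + ybar.sum()
    load = mortality.eta * Cbar / tcm.k1
    ubar_cor = growth.umax * depletion
    g_cor = geometric_factor(tcm.p, tcm.n - 1) if tcm.n > 1 else 0.0
    return EquilibriumResult(
        regime=regime, threshold=threshold, Cbar=Cbar,
        ubar=ubar, ybar=ybar, wbar=wbar,
        reported_forms={
            "ubar_alt": ubar_cor,
            "ybar_n_alt": load * ubar_cor,
            "wbar_alt": (1.0 + load * (1.0 + g_cor)) * ubar_cor,
        },
    )


def _jacobian(fun, x0: np.ndarray, scale: float) -> np.ndarray:
    n = x0.size
    J = np.empty((n, n))
    h = 1e-7 * max(scale, 1e-6)
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (fun(x0 + e) - fun(x0 - e)) / (2 * h)
    return J


def stability_classify(
    equilibrium: EquilibriumResult,
    growth: GrowthParams,
    mortality: MortalityParams,
    tcm: TCMParams,
    Cbar: float,
    *,
    which: Literal["zero", "nonzero"] = "nonzero",
    tol: float = 1e-10,
) -> StabilityVerdict:
    """Local spectral stability of an equilibrium of the constant-C system."""
    if equilibrium.regime == "continuum":
        raise ValueError(
            "continuum of equilibria at Cbar = lambda0/eta: spectral "
            "classification refused (a zero eigenvalue is structural)"
        )
    if which == "zero":
        x0 = np.zeros(tcm.n + 1)
        scale = 1e-4
    else:
        if not equilibrium.nonzero:
            raise ValueError("no nonzero equilibrium in this regime")
        x0 = np.concatenate(([equilibrium.ubar], equilibrium.ybar))
        scale = equilibrium.wbar

    def fun(v):
        return coxian_tcm_rhs(v, Cbar, growth, mortality, tcm)

    J = _jacobian(fun, x0, scale)
    eig = np.linalg.eigvals(J)
    max_re = float(eig.real.max())
    return StabilityVerdict(
        stable=max_re < -tol,
        marginal=abs(max_re) <= tol,
        eigenvalues=eig,
        max_real_part=max_re,
    )
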