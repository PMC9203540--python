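# Methods

## Model

The package implements perturbed tumor growth with a distributed delay
between drug insult and cell loss.  Proliferating mass `u` grows by
`k_in(u, w)` and is converted to damaged mass at the drug-driven rate
`k_out(C, u) = η C u`.  Damaged cells die with an age-at-death density
`f`, giving the master equation

    du/dt = k_in(u, w) − k_out(C, u)
    dy/dt = k_out(C, u) − (k_out * f)(t),        w = u + y.

This follows from an age-structured (McKendrick–von Foerster) description
of the damaged cohort with age-only mortality hazard μ(a): the survivor
function is S(a) = exp(−∫₀^a μ(α) dα) and f = −dS/da.  (The source
analysis prints the exponent of S without the −∫₀^a; the corrected
survivor function is used throughout, as the derivation requires.)

Two phase-type choices of `f` give closed ODE systems:

* **Erlang(n, k1)** (the classical Simeoni-type cascade): by the linear
  chain trick the convolution equals the outflow `k1 y_n` of a chain
  `dy_1/dt = k_out − k1 y_1`, `dy_i/dt = k1(y_{i−1} − y_i)`.
* **Coxian** with continuation probabilities `p_i` and rates `k_i`.  Under
  the equal-instant-death assumption `(1−p_i)k_i` constant — implemented
  through the mean parameters `p = mean(p_i)`, `k1 = mean(k_i)` — the chain
  becomes `dy_i/dt = p k1 y_{i−1} − k1 y_i`.  Each transition loses the
  fraction `1 − p` to immediate death, so the total-mass budget is
  `d(u+Σy)/dt = k_in − (1−p) k1 Σ_{i<n} y_i − k1 y_n`.  At `p = 1` the
  Coxian system is identical to the Erlang system, which the tests assert
  both symbolically (random states, 1e−14) and on full trajectories
  (≤ 1e−8 pointwise).

Phase-type machinery (`phase_type` module) represents both kernels as
(α, S, S⁰) triples with density `α·exp(St)·S⁰`, CDF `1 − α·exp(St)·1` and
mean `−α·S⁻¹·1`; the matrix exponential is scipy's scaling-and-squaring.
No closed-form Coxian density is attempted.  Hypoexponential degenerations
(all `p_i = 1`, unequal `k_i`) are constructible but fall outside the
mean-reduction assumption above.

## Growth laws

* Simeoni: `k_in = λ0 u / (1 + ((λ0/λ1) w)^φ)^{1/φ}` — exponential at rate
  λ0 below `w_th = λ1/λ0`, asymptotically linear `λ1 u / w` above.  With
  φ = 20 the bracket overflows double precision for large w, so the
  denominator is evaluated in the log domain via `logaddexp`.
* Logistic: `k_in = λ0 (1 − w/u_max) u` with the **total** mass w in the
  bracket (the form used in the model-comparison analysis).  The variant
  with `u` in the bracket (as written in the equilibrium corollary) is
  available through `GrowthParams(saturation="proliferating")`; the two
  differ and both are kept because the source equations are not mutually
  consistent — the text form is the default.

## Pharmacokinetics

Two compartments, elimination `k01` from plasma only, distribution
`k21/k12`, `C = q1/V`.  A bolus **adds** its amount to `q1` (standard
superposition); the alternative reading "reset q1 to the dose" is exposed
as `bolus_mode="reset"`.  Integration restarts at every dose event so the
solver never steps over a discontinuity.  `BolusConcentration` evaluates
the exact matrix-exponential solution through the eigendecomposition of
the 2×2 system matrix; it serves both as the fast concentration callable
driving tumor simulations and as the independent oracle against the ODE
route (`pk_simulate`), with agreement ≤ 1e−8 relative required.  Units are
the source study's own (amounts ng·kg⁻¹, V in ml, C in ng·ml⁻¹); no unit
auditing is attempted, because the printed dimensional chain does not
close.

### A note on the drug-potency scale

With the xenograft constants as printed (η = 0.7816, peak C ≈ 4.4e4), the
per-dose kill integral ∫ηC dt ≈ 2.1e4, i.e. the proliferating compartment
is annihilated within minutes of the first dose and the subsequent
dynamics are carried entirely by the damaged-cell cascade (which is what
makes `p` strongly identifiable from post-dose data).  This makes the `u`
equation severely stiff, so the default integrator is LSODA
(stiffness-switching) rather than an explicit Runge–Kutta pair; the
method, rtol (1e−8) and atol (1e−10; 1e−12 in the bundled xenograft
scenarios, where the deep decay of `u` otherwise leaves little headroom to
the −1e−9 negativity guard) are all exposed.  States below −1e−9 raise a
hard error rather than being clipped.

The constant-infusion analysis quotes a threshold concentration
λ0/η = 4032.3, which is inconsistent with η = 0.7816; the equilibrium
scenario therefore uses η = λ0/4032.3 ≈ 6.2e−5, treating the infusion
figures as a self-consistent parameterization.  The same potency scale is
used for the convolution-oracle comparison: at the printed η the kill term
is a quasi-impulse that no fixed-grid quadrature can resolve, while at the
threshold scale the integrand is smooth and the oracle check is a genuine
second-order-accurate comparison.

## Convolution oracle

`convolution_oracle` solves the master equation directly: Heun (explicit
trapezoidal) co-integration of `u` and `y` on a uniform grid, with the
convolution evaluated by the composite trapezoidal rule and the kernel
density precomputed by one step-matrix recursion `v ← v·exp(Sh)`.  Dose
discontinuities must fall on grid nodes; because `k_out` is linear in C,
node values at a jump use the two-sided mean concentration, preserving
second-order accuracy (the acceptance run shows the error dropping ~4×
per grid halving).  A Richardson half-step self-check is available via
`refine_check=True`.  With a near-degenerate kernel (Erlang n ≫ 1 at
fixed mean T) the loss term converges to the lagged kill `k_out(t−T)`,
i.e. the delay-differential limit, which is verified qualitatively.

## Equilibria and stability

Under constant `C̄` the cascade balance gives `ȳ_i = (η C̄ ū/k1) p^{i−1}`
and `w̄ = ū (1 + (η C̄/k1) g(p, n))` with `g(p, n) = Σ_{i<n} p^i`
(evaluated with an explicit `p = 1` branch, no division by `1 − p`).  The
growth-law steady state closes the system:

* Simeoni: solved **exactly at finite φ**,
  `w̄ = (λ1/λ0)((λ0/(ηC̄))^φ − 1)^{1/φ}` (log-domain).  The familiar
  large-φ form `w̄ = λ1/(ηC̄)` is reported alongside; near the threshold
  it is badly wrong (at C̄ within 0.01% of threshold: 1.26 vs 1.84), which
  is why simulation comparisons are run at C̄ = 0.5× and 2× threshold,
  where the forms agree to ~1e−7.
* Logistic (total-mass form): `w̄ = u_max (1 − ηC̄/λ0)`.  The printed
  corollary forms for `ȳ_n` and `w̄` are internally inconsistent with the
  chain steady state (the `p^{n−1}` factor is missing), so the module
  computes equilibria from the direct steady-state solution and only
  *reports* the printed forms for comparison.

Because `g(p, n)` is strictly increasing in p while `w̄` is p-free, `ū` is
strictly decreasing in p below threshold — the provable core of the
"equilibrium decreases with p" observation.  Note the observation is about
the plotted equilibrium level; the *total* `w̄` is p-independent in this
large-φ regime, so no w-level monotonicity is asserted.

Stability is classified from the eigenvalues of a central-difference
Jacobian of the full (n+1)-state system (tolerance 1e−10 on real parts);
the continuum regime at `C̄ = λ0/η` (relative tolerance 1e−12 on the
comparison) refuses classification since a structural zero eigenvalue is
present.  Global statements are probed, not proved: the acceptance run
checks the analytic regime against t = 2000 simulations from the bundled
initial sizes for n ∈ {2,3,4}, p ∈ {0, 0.5, 1} in both growth variants.

## Estimation

Bounded trust-region least squares (scipy `trf`) on stacked natural-scale
unweighted residuals; `gtol` is tightened to 1e−15 because spheroid-scale
residuals (~1e−3 mm³) otherwise trigger premature gradient-based
termination.  Multi-start uses a seeded Latin hypercube over the bounds
(5 starts by default).  Goodness of fit is the range-normalized RMSE with
the range taken from the observed series.  Fitting `p` and `k1` jointly
from a single series emits a warning (the delay parameters trade off); the
staged protocol is the recommended path.

Staged spheroid workflow: (1) λ0, u_max from the control series; (2)
k1, η from the treated series with an Erlang cascade (n = 4); (3) p with a
Coxian cascade (n = 5), everything else fixed; (4) a joint refinement of
all free parameters from the staged solution.  Stage 2 is intentionally
model-mismatched when the data-generating process is Coxian, so the staged
values are consistent starts rather than final estimates; the refinement
(which can only decrease the loss) is what attains truth recovery to
≤ 1e−3 relative on noise-free data.

## Synthetic data

The xenograft generator reproduces the in-vivo design: implant at day 0
with w0 = 0.0121 g, ten daily boluses of 4.5e7 from day 13, ten samples of
w(t).  The actual sampling days of the source series are not published;
the default places them uniformly over days 13–40 (synthetic design).  The
spheroid generator reproduces the in-vitro design: constant concentration
per group (0 = control, 5, 10 µM), samples at 0, 1, 2, 3, 6, 24, 48, 72 h,
optionally 30 replicates per group.  The initial spheroid volume is not
published; the default w0 = 0.002 (≈30% of the fitted carrying capacity
0.0066) is a plausible post-culture size.  Default noise is multiplicative
lognormal with σ = 0.05 (median-unbiased, `exp(σZ)`), the usual
proportional-error model for burden measurements; the source states no
noise model, so this is a package choice.  Additive noise truncates at
zero.  Generation is bit-reproducible given the seed.

What the generator does **not** emulate: replicate-level assay artifacts
(plate position, edge effects), raw diameter measurements behind the
ellipsoid volume formula, inter-animal variability, or dose-timing jitter.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated error model, not robustness to real
measurement pathologies.

## Problem sizes and tolerances used in the checks

Trajectory comparisons use 801–8001-point grids over the 40-day horizon;
equilibrium runs integrate to t = 2000 at rtol 1e−10; Monte-Carlo phase
means use 1e5 draws (3-SE criterion); noisy recovery uses 20 replicates at
σ = 5% with single-start fits; the delay-ordering scan uses a single dose
at day 5, logistic growth (λ0 = 0.25, u_max = 1, w0 = 0.3) and potency
2λ0/4032.3 — chosen so the post-dose minimum is interior and well resolved
for every chain length n = 1..8.

## Known limitations

* The mean-p Coxian reduction discards per-compartment heterogeneity; only
  the average continuation probability is identifiable here.
* No saturating drug-effect model: predictions at concentrations well
  above those fitted (where effect saturation matters) are out of scope.
* Stability is local/spectral plus simulation probes; no Lyapunov
  certificates.
* Erlang-kernel convolution and chain agree to quadrature error only; the
  oracle is a verification tool, not a production integrator.
* No population (mixed-effects) or Bayesian estimation.
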