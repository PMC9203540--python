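# coxtcm

Transit-compartment models (TCMs) of drug-perturbed tumor growth with
**Erlang** and **Coxian** delay kernels: simulation, pharmacokinetic (PK)
driving, equilibrium/stability analysis under constant infusion, and
parameter estimation — built for PKPD modellers who want the delayed-death
cascade itself, not just a black-box fit.

## The model

A tumor is split into proliferating mass `u(t)` and a cascade of damaged
compartments `y_1 .. y_n`.  Drug exposure moves mass out of `u` at rate
`k_out(C, u) = η C u`; growth follows either the Simeoni dual-regime law

    k_in(u, w) = λ0 u / (1 + ((λ0/λ1) w)^φ)^(1/φ),      w = u + Σ y_i,

(exponential below the threshold `w_th = λ1/λ0`, linear above) or logistic
growth `λ0 (1 − w/u_max) u`.  The damaged mass obeys the distributed-delay
master equation

    dy/dt = k_out(C, u) − (k_out * f)(t),

where `f` is the age-at-death density of a damaged cell.  Choosing `f`:

* **Erlang(n, k1)** — the linear chain trick turns the convolution into the
  classical chain `dy_i/dt = k1 (y_{i−1} − y_i)`; mean residence time `n/k1`.
* **Coxian** — each transition continues with probability `p` and exits
  (sudden death) with probability `1 − p`:
  `dy_i/dt = p k1 y_{i−1} − k1 y_i`.  `p = 1` recovers the Erlang chain
  exactly; `p < 1` produces shorter, more flexible delays.

Drug concentration comes from a two-compartment PK model with bolus or
infusion dosing, or is held constant for infusion/equilibrium analysis.
Under a constant concentration `C̄` the fate is decided by the threshold
`λ0/η`: above it the tumor is eradicated, below it a nonzero equilibrium
`ȳ_i = (η C̄ ū / k1) p^{i−1}` exists and is asymptotically stable for the
tested cascade sizes.

## Worked example

```python
import dataclasses
import numpy as np
import coxtcm as cx

cfg = cx.bundled_config("mouse150")        # ten daily boluses from day 13
dom = cfg.to_domain()
conc = cx.BolusConcentration(dom["pk"], dom["schedule"])
grid = np.linspace(0, 40, 401)

for p in (1.0, 0.44268):                   # Erlang vs fitted Coxian
    tcm = dataclasses.replace(dom["tcm"], p=p)
    traj = cx.simulate_tcm("coxian", dom["growth"], dom["mortality"], tcm,
                           conc, dom["w0"], grid, atol=1e-12)
    print(p, [round(float(np.interp(d, traj.t, traj.w)), 4)
              for d in (13, 20, 30, 40)])
```

prints

```
1.0     [0.3121, 0.2674, 0.089, 0.016]
0.44268 [0.3121, 0.101, 0.0172, 0.0023]
```

tumor weight (g) at days 13/20/30/40: both chains start the treatment phase
at 0.312 g, but the Coxian cascade (`p ≈ 0.443`) eliminates damaged cells
on the way down the chain and the burden falls roughly five-fold faster
during the drug-effect window.  Equilibrium analysis under constant
infusion at half the threshold concentration:

```python
mort = cx.MortalityParams(eta=0.25 / 4032.3)
eq = cx.equilibria_simeoni(dom["growth"], mort,
                           cx.TCMParams(4, 0.2859, 0.44268), 2016.15)
print(eq.regime, round(eq.ubar, 4), round(eq.wbar, 4))
# zero-plus-nonzero 2.099 3.6824
```

so below threshold the tumor persists at `w̄ ≈ 3.68 g` (and
`stability_classify` reports the state as locally asymptotically stable).

A command-line surface mirrors the library:

```bash
coxtcm simulate -c mouse150 -o traj.csv
coxtcm sweep -c mouse150 --param p --values 0,0.2,0.4,0.6,0.8,1 --fix n=4 -o sweep.csv
coxtcm equilibrium -c spheroid --cbar 10 --cbar 40 -o eq.csv
coxtcm generate -c spheroid -o obs.csv --seed 3
coxtcm fit -c spheroid --data obs.csv --free p=0.5:0:1 -o fit.json
```

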