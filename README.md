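# spatialrecovery

Tools for studying how spatially extended populations recover from pulse
disturbances — for theoretical and spatial ecologists who want to know
whether a metapopulation's stability is governed by its local dynamics, by
rescue from undisturbed regions, or by dispersal-driven mixing.

## The framework

The model is a single-species reaction–diffusion metapopulation

    ∂N/∂t = r N F(N) + d ∇²N,     F(N) = (1 − N/K)(N/K)^γ

on a 1D landscape of size L or on a dispersal network (a bistable growth
law with an Allee threshold is also provided). A pulse disturbance of
spatial extent σ and local intensity ρ (overall strength s = σρ) knocks
the system off its equilibrium N = K; the package measures the return time
to 99% of equilibrium biomass and decomposes the recovered biomass into
three regime contributions:

* **Isolated (IR)** — what a dispersal-free twin would have recovered alone;
* **Rescue (RR)** — recovery carried by fronts propagating from undisturbed
  into disturbed regions;
* **Mixing (MR)** — recovery occurring after dispersal has homogenized the
  system.

Dimensional analysis predicts the transitions. With the effective system
size ℓ_eff = L·√(r/d), the nondimensional front speed u and width λ
(dimensional scales √(rd) and √(d/r)), and the dispersal-free recovery
time τ₀ (in units of 1/r):

    IR:  ℓ_eff > 2uτ₀        RR:  2uτ₀ > ℓ_eff > λ        MR:  λ > ℓ_eff

The package measures u, λ, τ₀ from simulations, maps return time and
regime contributions across parameter space, and applies the framework to
two richer settings: habitat fragmentation on random spatial networks
(mean degree α and mean shortest path β as proxies for d and L), and a
stochastic predator–prey metapopulation where repeated localized predator
removals raise survival only near the RR–MR transition.

## Worked example

```python
from spatialrecovery import (
    Disturbance, GrowthModel, ModelParams, classify, decompose,
    effective_size, front_metrics, local_timescale,
)
from spatialrecovery.model import default_lattice

growth = GrowthModel(kind="power_logistic", K=1.0, gamma=3.0)
params = ModelParams(r=1.0, d=1.0, growth=growth)
domain = default_lattice(100.0, params)
dist = Disturbance(sigma=0.5, rho=0.9)

dec = decompose(params, domain, dist)
print(f"return time {dec.return_time:.1f}, "
      f"f_IR={dec.f_IR:.3f} f_RR={dec.f_RR:.3f} f_MR={dec.f_MR:.3f}")

fm = front_metrics(params, rho=0.9)
tau0 = local_timescale(growth, rho=0.9).tau0
pred = classify(effective_size(100.0, 1.0, 1.0), fm.u, fm.lam, tau0)
print(f"u={fm.u:.3f} lam={fm.lam:.2f} tau0={tau0:.0f} -> {pred.regime}")
```

prints

```
return time 60.8, f_IR=0.007 f_RR=0.993 f_MR=0.000
u=0.432 lam=7.45 tau0=398 -> RR
```

i.e. at (L, r, d) = (100, 1, 1) a half-system disturbance of intensity 0.9
recovers almost entirely through rescue fronts (f_RR ≈ 0.99), and the
analytic classification agrees: ℓ_eff = 100 sits between the front width
λ ≈ 7.5 and the front reach 2uτ₀ ≈ 344.

A CLI mirrors the library:

```
spatialrecovery decompose --d 1 --r 1 --length 100 --outdir results
spatialrecovery regime-map --config my_sweep.yaml
```

Subcommands: `simulate`, `decompose`, `front-metrics`, `return-time-map`,
`regime-map`, `fragment`, `predprey`. Every run writes a tidy CSV plus a
JSON sidecar with the resolved configuration, its hash and the seed;
stochastic experiments refuse to run without an explicit seed.

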