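# stochpd

Stochastic pharmacodynamics of a heterogeneous tumour-cell population under
targeted drug treatment: closed-form extinction-time theory, exact
event-driven simulation, and dose/recovery regimen analysis.

## The problem

Ordinary-differential-equation PK-PD models average away two features that
matter for small cell populations: stochasticity (the same treatment can end
in cure or regrowth) and heterogeneity (cells differ in their susceptibility).
`stochpd` models a population of tumour cells in which every cell `i` carries
a scaled *regulator value* `k_i ∈ (0, 1)` — a viability-linked attribute such
as normalised phosphorylated ERK under a MEK inhibitor. Drug exposure drives
`k_i` down; low `k_i` makes the cell mortal. The natural endpoint of such a
model is the extinction time of the population — a quantity deterministic
models do not possess.

## Model

**Sustained dose, no division.** With drug always present,
`k_i(t) = k_i(0) e^{−δt}`. A cell whose regulator value is below the death
threshold (default 1/4) is "in the death pool" and dies with rate μ, so a cell
starting at `k` enters the pool at `t_k = log(4k)/δ` (zero if already below)
and its survival probability is `s(t,k) = e^{−μ(t−t_k)}` for `t > t_k`. With
initial values uniform on (0, 1) the marginal survival is

    S(t) = 1 − (μ/4)(e^{δt} − e^{−μt})/(δ+μ)      δt ≤ log 4
    S(t) = A e^{−μt}                               δt ≥ log 4,

with `A = (4^{μ/δ} + μ/(4δ))/(1 + μ/δ)`. For a cohort of n independent cells
the extinction time τ_n (the maximum of n lifetimes) has exact CDF
`(1 − S(t))^n`; for large n, `μ(τ_n − t_max)` with `t_max = log(nA)/μ` is
approximately Gumbel, giving

    E τ_n ≈ (log nA + γ)/μ,   var τ_n ≈ π²/(6μ²),
    t_p = t_max − log(log(1/p))/μ,

and a direct inverse-transform sampler `(−log(−log U) + log nA)/μ` for
extinction times that bypasses simulation entirely.

**Multiple doses with recovery and division.** Doses of duration `T_d` repeat
every `T`; between doses `k_i` relaxes toward its baseline `k_i(0)` with rate
α, and cells above the division threshold (default 1/2) divide with rate λ.
The peak values at cycle starts obey `k_{n+1} = a k_0 + b k_n` with
`a = 1 − e^{−α(T−T_d)}`, `b = e^{−δT_d} e^{−α(T−T_d)}`, converging to
`K = a k_0/(1−b)`. Each cycle selects for high-baseline cells — an adaptation
akin to drug resistance without any mutation. Whether the population
ultimately dies is decided by the per-cycle growth exponent of the fittest
lineage, `r(k_0) = λ·(division-pool time) − μ·(death-pool time)` at the
asymptotic cycle; the *critical death rate* μ_c solves `sup_{k0} r(k_0) = 0`.

All simulators are exact (no time discretisation): trajectories are piecewise
exponential, so threshold crossings are closed-form and event times are drawn
from piecewise-constant hazards.

## Worked example

```python
import numpy as np
from stochpd import (ModelParams, DoseSchedule, extinction_moments,
                     gumbel_quantile, extinction_ensemble, estimate_critical_mu)

p = ModelParams(mu=0.2, lam=0.0, delta=1.0)
m = extinction_moments(1000, p)
print(f"A        = {m.A:.4f}")
print(f"t_max    = {m.t_max:.2f}")
print(f"E[tau_n] = {m.mean_tau_n:.2f}   sd = {m.var_tau_n**0.5:.2f}")
print(f"t50      = {gumbel_quantile(0.50, 1000, p):.2f}")
print(f"t99      = {gumbel_quantile(0.99, 1000, p):.2f}")
taus = extinction_ensemble(1000, 1000, p, np.random.default_rng(0))
print(f"simulated mean over 1000 cohorts = {taus.mean():.2f}")

pm = ModelParams(mu=1.0, lam=0.25, delta=2.5, alpha=2.0)
sch = DoseSchedule.cycles(T=3.0, T_d=1.0)
print(f"mu_c(lam=0.25) = {estimate_critical_mu(sch, pm).mu_c:.3f}")
```

prints

```
A        = 1.1413
t_max    = 35.20
E[tau_n] = 38.09   sd = 6.41
t50      = 37.03
t99      = 58.20
simulated mean over 1000 cohorts = 38.15
mu_c(lam=0.25) = 0.887
```

Read: with death rate μ=0.2 and drug-action rate δ=1, a 1000-cell cohort is
most likely eliminated around t ≈ 35 (time in units of 1/μ-scale rates); the
median clearance time is ≈ 37 and 99% of cohorts are clear by ≈ 58. The
simulated ensemble mean (38.15) agrees with the closed form (38.09). Under
the 3-unit dose/recovery cycle, a division rate λ=0.25 requires a
drug-induced death rate above μ_c ≈ 0.887 for eventual extinction — so μ=1
eradicates (slowly), while the same schedule with λ=0.4 (μ_c ≈ 1.42) regrows.

A CLI mirrors the library:

```sh
stochpd analytic --mu 0.2 --delta 1 --lam 0 --n0 1000 --out out/
stochpd multidose --lam 0.25 --n0 100 --horizon 30 --seed 1 --out out/
stochpd critical-mu --lam 0.25 --out out/
```

Every CSV/JSON output embeds the full configuration, seed and package version.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's reference quantity from scratch — the closed-form
survival prefactor A at μ=0.2, δ=1, reported to the printed precision — and
runs a small simulated-cohort sanity check of the extinction-time mean.
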