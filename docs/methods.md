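# Methods

## Model and assumptions

A population of tumour cells is treated with a drug whose molecular effect is
summarised by a single per-cell state, the regulator value `k ∈ (0, 1)`
(e.g. normalised pERK). The dynamics combine a deterministic layer (each
cell's `k(t)`) with a stochastic layer (death and division events at
state-dependent rates):

- **Dose phases** (drug present at constant level): `dk/dt = −δk`, so
  `k(t) = k(t0) e^{−δ(t−t0)}`. No pharmacokinetics: drug concentration is
  constant within a dose and zero outside.
- **Recovery phases**: `k` relaxes toward the cell's natural baseline `k0`
  with rate α: `k(t) = k0 − (k0 − k(t0)) e^{−α(t−t0)}`. The baseline is a
  permanent, heritable property of the lineage ("cells remember their
  natural value"); `k` never exceeds `k0`.
- **Death**: cells with `k` below the death threshold `k_death` (default
  1/4) die with rate μ (step hazard `w0`). A linear variant `w1(k) =
  μ·max(0, 1 − k/k_death)` is provided: zero at the threshold, μ at `k = 0`,
  with a configurable slope. The thresholds are in principle arbitrary
  calibration constants; the defaults (1/4 and 1/2) match the agent-based
  model the framework abstracts.
- **Division** (multiple-dose model only): cells with `k` above `k_div`
  (default 1/2) divide with rate λ. Cells in `(k_death, k_div)` neither die
  nor divide. Under a sustained dose every `k` eventually falls below
  `k_death`, so division is irrelevant there and the sustained model sets
  λ = 0.
- **Initial condition**: baselines `k0` i.i.d. uniform on (0, 1) (pluggable
  sampler).

Parameters, units: μ, λ, δ, α are rates (1/time). Typical scales: 1/δ
(drug takes effect) minutes–hours; 1/μ, 1/λ (death, division) hours–days.
Defaults follow the multiple-dose simulation values μ=1, λ=0.4, δ=2.5, α=2,
T=3, T_d=1.

## Closed forms (sustained dose, step hazard)

With `c = k_death` and uniform baselines, entry into the death pool occurs at
`t_k = max(0, log(k/c)/δ)` and

- `S(t) = 1 − (μc/(δ+μ))(e^{δt} − e^{−μt})` for `δt ≤ log(1/c)`, and
  `S(t) = A e^{−μt}` after, with
  `A = (c^{−μ/δ} + cμ/δ)/(1 + μ/δ)` (equal to `∫ e^{μ t_k} dk`; A = 1 in the
  δ ≫ μ limit).
- Death-time density `f = −S′`; the early branch is
  `(μc/(δ+μ))(δe^{δt} + μe^{−μt})`. Note the plus sign: only this form is
  continuous at the branch point, integrates to one, and gives `f(0) = μc`
  (initial death-pool fraction times μ). A published version of this formula
  carries a minus-sign typo; the package implements the derivative.
- Single-cell moments: `E τ1 = (log(1/c) − (1−c))/δ + 1/μ`. The quoted
  variance `1/μ²` is the fixed-delay approximation that treats the pool-entry
  time as deterministic; the exact variance adds `var(t_k) ≈ 0.2444/δ²`
  (at c = 1/4), i.e. +0.98% at μ/δ = 0.2. `mean_var_single(exact_var=True)`
  returns the exact value; the default mirrors the standard formula.
- Cohort extinction: exact CDF `(1 − S(t))^n` for all t; in the late regime
  this is `(1 − Ae^{−μt})^n`. Moments via harmonic sums
  `E τ_n = (log A + H_n)/μ`, `var τ_n = H_n^{(2)}/μ²`, with the large-n forms
  `(log nA + γ)/μ` and `π²/(6μ²)` returned alongside and flagged by name.
- Gumbel limit: `μ(τ_n − t_max)` with `t_max = log(nA)/μ` is asymptotically
  standard Gumbel; quantiles `t_p = t_max − log log(1/p)/μ` (so
  `t50 − t_max = 0.3665/μ`, `t99 − t_max = 4.600/μ`,
  `t01 − t_max = −1.527/μ`; the last is sometimes quoted rounded as
  −1.50/μ). The sampler draws `(−log(−log U) + log nA)/μ`.

Regime handling: the product forms above require `δt > log(1/c)`; the API
raises `RegimeError` there unless called with `strict=False`, which switches
to the exact `(1 − S)^n` forms valid everywhere.

## Simulators

**Sustained dose** (death only): each lifetime is `t_k` plus an
exponential(μ) residence time — exact, vectorised, O(n); no event loop. The
linear-hazard variant inverts the closed-form integrated hazard by Brent
root-finding (xtol 1e−10). Ensembles and mean trajectories reuse the same
vectorised draw.

**Multiple doses**: a daughter inherits the mother's current `k` *and* the
founder's baseline `k0`. Because the dynamics are memoryless given
`(k, k0)`, every cell of a lineage then shares the founder's deterministic
trajectory — the inheritance rule is not stated by the source framework; this
choice (the natural reading of lineages recovering to the founder's value) is
what makes exact simulation cheap, and is localised in
`multidose.hazard_segments` should a different rule be wanted. Per lineage,
hazards are piecewise constant between cycle boundaries and the closed-form
threshold crossings; per cell, events are drawn segment-by-segment as
competing exponentials (division spawns a cell starting in the same segment;
no division latency). Determinism: the caller's generator is `spawn`ed per
founder and cells are processed in a fixed LIFO order, so a seed fixes the
realisation exactly. A configurable cap (default 10^6 cells ever created)
guards supercritical runs; exceeding it raises `PopulationCapError` rather
than returning a truncated realisation.

## Critical death rate

The per-cycle pool occupancies of a lineage converge (geometrically, ratio
`b`) to those of the asymptotic cycle whose peak is `K = a k0/(1−b)`. The
package scores each lineage by its asymptotic per-cycle log-growth
`r(k0; μ) = λ·T_div(k0) − μ·T_death(k0)` and defines μ_c as the root of
`sup_{k0} r = 0` — the smallest death rate at which even the fittest lineage
declines. Numerically: occupancies in closed form on a 512-point `k0` grid,
root by bisection (default tol 1e−8; `g(μ)` is piecewise-linear and
monotone). Degenerate outcomes are reported explicitly: μ_c = 0 when growth
is negative throughout the bracket (e.g. λ = 0), an infinite sentinel when
some lineage has zero asymptotic death-pool time (the drug can never
eliminate it). Because initial baselines are uniform, values arbitrarily
close to the fittest `k0 = 1` are present in any large cohort, so the
supremum over the grid is the operative criterion; this deterministic
criterion is validated against stochastic ensembles in the test suite
(extinction at 1.2 μ_c, survival and growth at 0.8 μ_c).

## Synthetic data

There is no external data; the "data" are simulated cohorts. The generator
defaults are the stated world of the model: uniform (0,1) baselines, the
simulation parameter values above, and seeds passed explicitly everywhere.
What the generator does **not** emulate: measurement noise, pharmacokinetic
variation of drug level within a dose, cell–cell interaction, spatial
structure, or heritable change of `k0` (resistance arises purely by selection
on standing heterogeneity). A green distributional test therefore
establishes internal consistency of simulator and theory, not fidelity to any
particular experimental system.

## Numerical choices

- Exact threshold equality `k = k_death` counts as *outside* the death pool
  (the step hazard is defined by strict inequalities; measure-zero choice).
- Infinite times use `math.inf` as the distinguished sentinel (compares
  greater than any finite time).
- Branch continuity of `S` and `f` at `δt = log(1/c)` holds to 1e−12 and is
  asserted over a (μ, δ) grid; per-branch evaluation clips the argument so
  the dormant branch cannot overflow.
- `T_d = 0` (never dosed) and `T_d = T` (no recovery) are both valid; the
  latter reproduces the sustained model exactly and is tested
  distributionally.
- Statistical tests use fixed seeds chosen in advance; chi-square
  goodness-of-fit uses the probability-integral transform with 40
  equiprobable bins at α = 0.01.

## Known limitations

- The multidose event engine supports the step death hazard only; the linear
  variant is implemented for the sustained-dose path (closed-form integrated
  hazard), where its exact published parameterisation was unavailable and the
  slope is left configurable.
- The Gumbel sampler is an approximation for small n (bias ~1/n); use the
  exact CDF forms or the simulator below n ≈ 100 if tail precision matters.
- μ_c is a deterministic mean-field criterion for lineage growth; near μ_c,
  stochastic extinction of modest cohorts remains possible on either side.
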