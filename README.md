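# switchfix

Exact fixation statistics and mutation–selection equilibria for finite
populations evolving in randomly switching environments.

## The problem

A well-mixed population of fixed size *N* contains two types, a mutant *A*
and a wild-type *B*. The population evolves by a one-step birth–death
process with per-step probabilities *T*⁺<sub>i,σ</sub> (i → i+1) and
*T*⁻<sub>i,σ</sub> (i → i−1) that depend on the current state σ of an
**environment** — a finite-state Markov chain (switching matrix
μ<sub>σ→σ′</sub> in discrete time, rates m<sub>σ→σ′</sub> in continuous
time) that evolves independently of the population. Without mutation the
monomorphic states i = 0 and i = N are absorbing, and the quantities of
interest are the fixation probability φ<sub>i,σ</sub>, the mean
unconditional fixation time t<sub>i,σ</sub> and the mean conditional
fixation time τ<sup>A</sup><sub>i,σ</sub> (averaged over realisations that
fix). With mutation, the joint chain instead converges to a stationary
distribution ρ<sub>i,σ</sub>.

This is the natural stochastic framework for questions like: *does a
fluctuating selection landscape help or hinder a rare mutant?* The bundled
application is the frequency-dependent Moran process for a 2×2 game whose
payoff matrix switches between a **coexistence game** (σ = +1) and a
**coordination game** (σ = −1), with payoffs a<sub>σ</sub> = d<sub>σ</sub> = 1,
b<sub>σ</sub> = 1 + σb, c<sub>σ</sub> = 1 + σc and exponential fitness
f = e<sup>βπ</sup>. A striking property of this system is that the fixation
probability of a single mutant can be *maximised at an intermediate
switching speed* — higher than in either frozen environment.

## What the package computes

- **`env_model`** — validated discrete/continuous environment chains,
  the two-state telegraph shorthand (p₊, p₋), stationary occupancy.
- **`game_model`** — expected payoffs, exponential fitness, Moran
  transition tables with and without mutation, gradient of selection,
  selection-balance point i\* solving π_A(i) = π_B(i).
- **`fixation_discrete`** — exact φ, t, τ<sup>A</sup> from the first-step
  balance equations of the joint (i, σ) chain, by sparse LU with iterative
  refinement (residual ≤ 1e-10); plus the affine forward recursion of the
  same equations (arbitrary precision) as an independent cross-check.
- **`fixation_continuous`** — the same three quantities when birth–death
  events and environment switches are separate rate-driven events.
- **`effective_theory`** — fast-switching approximation through
  occupancy-weighted effective transition probabilities
  T±<sub>i,eff</sub> = (p₋ T±<sub>i,+1</sub> + p₊ T±<sub>i,−1</sub>)/(p₊+p₋),
  with the classical one-environment closed forms for φ and the mean times.
- **`stationary`** — exact joint stationary law (eigenvector at eigenvalue 1),
  single-environment product forms, the slow-switching weighted average,
  the fast-switching effective law, and the L2 distance diagnostic
  (time-averaged over the second half of a simulated series).
- **`simulate`** — seeded, numba-accelerated Monte Carlo of the joint
  process (discrete steps and Gillespie), ensemble estimators with standard
  errors, empirical distribution series Q<sub>i</sub>(t).
- **`cli_io`** — YAML configs, sweep orchestration and a `switchfix`
  console command (`fixation`, `stationary`, `simulate`, `sweep`,
  `balance-point`).

## Worked example

```python
import switchfix as sf

spec  = sf.GameSpec.switching_game(b=0.5, c=0.9, beta=0.5, N=50)
model = sf.birth_death_model(spec)

bp = sf.selection_balance_point(spec, +1)
print(bp.i_star_real, bp.i_star_int)        # 17.8571 -> state 18

for p_plus in (1e-3, 1e-2, 1e-1):
    sol = sf.solve_fixation(model, sf.two_env_chain(p_plus, 0.01))
    print(p_plus, sol.phi[1], sol.t_cond_generations[1])
```

prints (φ₁ per starting environment, τ<sup>A</sup>₁ in generations):

```
p+=0.001  phi1(+1)=0.01213  phi1(-1)=0.00760   tau1 ~  86 generations
p+=0.01   phi1(+1)=0.02813  phi1(-1)=0.01926   tau1 ~  46 generations
p+=0.1    phi1(+1)=0.00894  phi1(-1)=0.00804   tau1 ~  27 generations
```

The single-mutant fixation probability peaks near p₊ ≈ p₋ = 0.01 — the
switching environment beats both frozen environments — while the
conditional fixation time falls monotonically as more time is spent in the
coordination game. A Monte Carlo cross-check agrees within its binomial
standard error:

```python
est = sf.estimate_fixation(model, sf.two_env_chain(0.01, 0.01),
                           i0=1, sigma0=+1, n_runs=100_000, seed=1)
# est.phi_hat = 0.02797 +/- 0.00052   (exact: 0.02813)
```

In the fast-switching regime the effective theory is accurate: at
p₊ = p₋ = 0.1 the closed form gives φ₁ = 0.02057 against the exact
0.02137 / 0.02042 (starting from σ = +1 / −1), a relative error under 4%.

The same model with mutation (`u=0.02`) has a non-trivial stationary law:

```bash
switchfix stationary --config examples/mutation.yaml --out stationary.csv
```

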