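# Methods

## Model

The state of the system is the pair (i, σ): i ∈ {0, …, N} mutants in a
population of fixed size N, and σ one of Ω environment states. Two time
conventions are supported.

**Discrete time.** In one elementary step the population first makes a
birth–death move using the transition probabilities of the *step-start*
environment (i → i+1 with T⁺_{i,σ}, i → i−1 with T⁻_{i,σ}, otherwise
stays), and the environment then moves with its stochastic matrix
μ_{σ→σ′}. The joint one-step kernel therefore factorises as
R_{(i,σ)→(i±1,σ′)} = T±_{i,σ} μ_{σ→σ′} and
R_{(i,σ)→(i,σ′)} = (1 − T⁺ − T⁻) μ_{σ→σ′}. The simulator implements
exactly this factorisation, so solver and sampler describe the identical
chain; any other event ordering would silently bias their comparison.

**Continuous time.** Birth–death events (rates T̃±_{i,σ}) and environment
switches (rates m_{σ→σ′}, σ′ ≠ σ) are separate competing exponential
events; the generator's diagonal is minus the total exit rate (standard
rate-matrix convention — the model description leaves it implicit). How the
continuous rates relate numerically to discrete per-step probabilities is a
modelling choice, not a mathematical one; the package treats them as free
inputs and offers `BirthDeathModel.as_continuous()` for the convention
"reinterpret the per-step probabilities as rates".

Environment dynamics are independent of the population state;
time-inhomogeneous or state-coupled switching is out of scope.

## Fixation solvers

Without mutation, i = 0 and i = N are absorbing and interior T± are
required strictly positive. First-step analysis gives linear balance
equations, e.g. for the fixation probability

φ_{i,σ} = Σ_{σ′} μ_{σ→σ′} [T⁺_{i,σ} φ_{i+1,σ′} + T⁻_{i,σ} φ_{i−1,σ′}
          + (1 − T⁺ − T⁻) φ_{i,σ′}],  φ_{0,σ} = 0, φ_{N,σ} = 1.

The mean unconditional time t obeys the same operator with inhomogeneity 1;
the conditional time enters through θ = φ·τ^A, which obeys it with
inhomogeneity φ and zero boundaries. The **primary solver** assembles the
sparse joint kernel, restricts to interior states, and solves with sparse
LU plus iterative refinement to an infinity-norm residual ≤ 1e-10 (residual
and refinement count are reported in the solution diagnostics). This path
needs no invertibility of μ and scales comfortably to hundreds of states.

The **recursion solver** propagates the same equations forward in i as an
affine map of the unknown i = 1 slice and closes with the boundary
condition at i = N. It requires μ⁻¹ (two-state chains with p₊ + p₋ = 1 are
rejected with a pointer to the direct solver; singularity is detected by a
condition-number threshold of 1e12 rather than an exact zero, for
floating-point robustness). The forward map is exponentially
ill-conditioned in N — in float64 it loses all accuracy already at N = 50
for fast switching — so it runs in arbitrary precision (mpmath, default
60 + 2N decimal digits). It exists purely as an independent cross-check of
the direct path and agrees with it to ~1e-10 across the default sweep grid.

Continuous time uses the analogous backward equations with the total exit
rate on the diagonal; times accrue as mean exponential holding times. No
diffusion approximation is used anywhere — the switching process has no
continuum limit, and mean times from a diffusion limit would be wrong.

Times are computed in elementary steps (model time in the continuous case)
and also reported in generations, with 1 generation = N steps.

## Effective fast-switching theory

For the two-state telegraph environment the asymptotic occupancies are
p₋/(p₊+p₋) and p₊/(p₊+p₋); weighting the per-environment transition
probabilities with them yields the effective chain. The one-environment
closed forms (φ_i from cumulative products of γ_j = T⁻_j/T⁺_j; the nested
sums for t and θ evaluated by the equivalent first-order recursion
d_i = γ_i d_{i−1} − r_i/T⁺_i with an affine closure) are *exact* for the
effective chain; the approximation is entirely the replacement of the
switching model by it. Fixation probabilities are evaluated in log space
(cumulative log-γ plus log-sum-exp), so strongly biased chains neither
overflow nor produce NaNs; probabilities below float64 range underflow to
zero, which is the correct representable answer. The time recursion uses
direct products and is intended for the moderate N where the effective
theory is used here (N ≲ a few hundred with |log γ| ≲ 1).

The occupancy-weighting logic extends verbatim to Ω > 2 via the chain's
stationary occupancy; because only the two-state case is derived in the
underlying theory, the general version lives behind the explicitly named
`effective_rates_general` extension.

There is no sharp threshold for "fast" switching. The package's own
validated regime, asserted in the tests, is: relative error of φ₁ below 5%
at p₊ = p₋ ≥ 0.1 for the default game (N = 50, β = 0.5, b = 0.5, c = 0.9),
decreasing toward p = 0.5; at p ≤ 1e-4 the exact solution depends on the
initial environment and the effective value cannot match both.

## Mutation and stationary distributions

Mutation acts at the birth step: the offspring inherits the parental type
with probability 1 − u. This convention makes the escape probability from
either monomorphic state exactly u and reduces continuously to the
mutation-free process at u = 0. With u > 0 the joint chain is irreducible
and its stationary law is the left eigenvector of R at eigenvalue 1,
computed by a direct solve of (Rᵀ − I)ρ = 0 with the normalisation row
appended, followed by shifted inverse iteration if the eigen-residual
exceeds 1e-10 (relevant only for nearly reducible chains at very slow
switching); the residual is always reported. Reducible joint chains (e.g. a
frozen multi-state environment) are rejected — the frozen case is handled
per environment through the Ω = 1 chain, where the eigen-solution equals
the single-environment product form ρ_i ∝ ∏_{j≤i} T⁺_{j−1}/T⁻_j
(evaluated in log space).

Two approximations are provided: the occupancy-weighted average of the
single-environment product forms (slow switching) and the product form of
the effective chain with mutation (fast switching). The distance between an
empirical distribution over i and a candidate law is the Euclidean (L2)
norm of the difference; it is a pluggable function (`norm="l1"`) because
reasonable conventions differ, and it compares marginal-in-i distributions.
Time averages discard the first half of the series to remove the initial
condition.

## Simulation

The Monte Carlo kernels are numba-jitted. Per-run seeds are derived from
the master seed with `numpy.random.SeedSequence`, giving reproducible,
order-independent ensembles; identical (seed, config) pairs are
bit-identical. Estimators: φ̂ = fixed/n with binomial standard error;
unconditional and conditional mean times with sample standard errors (the
conditional mean averages fixed runs only). The initial environment is an
explicit required policy (a label, or a draw from the stationary occupancy)
because fixation probabilities depend on σ(0) at slow switching.

`ensemble_distribution` records the ensemble distribution over i once per
generation by default. Its initial condition defaults to i₀ = 0 with σ(0)
drawn from the stationary occupancy; since the first half of the series is
discarded before any distance is computed, the steady-state diagnostics are
insensitive to this choice for the run lengths used here.

## Problem sizes and numerical choices

- Default study conditions follow the headline game: N = 50, β = 0.5,
  b = 0.5, c = 0.9, p₋ = 0.01 for fixation sweeps; u = 0.02,
  T = 2×10³ generations for stationary diagnostics.
- The stationary-regime test compares against ensembles of 10⁴ runs over
  T = 2×10³ generations; ordering of the two approximations is already
  unambiguous at this ensemble size (distances differ by an order of
  magnitude in each regime).
- Oracle-equivalence tests use dense fundamental-matrix and
  Doob-conditioned-chain constructions at N ≤ 12, Ω ≤ 3, where dense
  linear algebra is exact to ~1e-12.
- Linear-solve residual target 1e-10 with at most 10 refinement steps;
  stochastic-matrix validation tolerance 1e-12; balance-point integer ties
  (x.5) round toward N/2.

## What the synthetic conditions do and do not show

All quantitative tests run on the Moran switching game and on randomized
transition tables drawn uniformly from well-conditioned ranges. These
exercise the solvers' correctness exhaustively at desk scale, but they do
not probe: extremely large N (where the recursion cross-check is
impractical and closed-form time sums can overflow), near-degenerate models
with interior transition probabilities approaching 0 or 1, heavy-tailed
payoff structures, or environment chains with more states than the games
studied here (the general-Ω code paths are tested at Ω ≤ 3). Conclusions
about real biological populations additionally depend on the modelling
assumptions themselves — fixed N, well-mixed interactions,
population-independent switching — which no test here can validate.
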