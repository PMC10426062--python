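# Methods

## Model

A haploid population of `N` agents evolves one binary heritable trait,
social learning, against a `B`-armed Bernoulli bandit environment. Exactly
one arm is optimal and pays 1 with probability `pi_high`; all others pay 1
with probability `pi_low`. The four uncertainty parameters are the
per-generation environmental change probability `u`, the selection-set size
`B`, the non-optimal payoff `pi_low` (ambiguity = `pi_high - pi_low`;
ambiguity grows as `pi_low` approaches `pi_high`), and the effective
lifespan `L` (learning opportunities per generation).

Per generation:

1. **Lifetimes.** Each agent takes `L` steps. At each step it samples an arm
   from the Boltzmann distribution `P(b) ∝ exp(beta * est[b])` over its
   running-mean payoff estimates, receives a Bernoulli payoff, increments
   that arm's observation count, and then moves the estimate toward the
   payoff by `1/count` (so from a naive start the estimate is exactly the
   arithmetic mean of observed payoffs). Agents do not interact within a
   generation; the inner loop is therefore vectorized across the population
   with no change to the model.
2. **Reproduction.** `N` parents are drawn with replacement, each draw
   proportional to lifetime net payoff. If every agent earned zero (possible
   when `pi_low = 0` and `L` is small) proportional selection is undefined
   and the draw falls back to uniform. Children inherit the trait without
   mutation.
3. **Transmission.** Each social child independently samples `N_T` distinct
   prospective teachers uniformly from the parent generation (without
   replacement; `N_T > N` is rejected), takes the one with the greatest net
   payoff (ties broken uniformly), copies its estimates verbatim, and sets
   each arm's count to 1 where the teacher had at least one observation and
   0 otherwise. Treating inherited knowledge as a single observation keeps
   social learners flexible: their next individual observation of an arm
   carries weight 1/2, so outdated inherited estimates are revised quickly.
   Asocial children are born naive (all estimates and counts zero — a zero
   estimate encodes "no information", consistent with the count).
4. **Environmental change.** After reproduction and die-off, with
   probability `u` a new optimal arm is drawn uniformly from the `B - 1`
   other arms (the incumbent is excluded).

Fixation is checked on each newborn child generation — including the
initial one — before it lives; a homogeneous initial population therefore
fixates at generation 0, and `generations` counts completed (lived) parent
generations. Trials that hit the generation cap (default 10,000) are
recorded as censored, excluded from both the numerator and denominator of
the fixation frequency, and flagged with a warning when they exceed 1% of
an ensemble.

## Parameters and defaults

| Parameter | Meaning | Default | Rationale |
|---|---|---|---|
| `pi_high` | optimal-arm payoff probability | 0.9 | fixed across all experiments |
| `beta` | softmax greediness (per unit of estimated payoff, payoffs in [0,1]) | 10 | strongly exploitative but still exploratory for similar estimates |
| `N_T` | prospective-teacher sample size | 5 | small subset: full-population access is not guaranteed |
| `N` | population size | 100 | desk-scale; drift is visible but selection dominates at the effect sizes studied |
| `max_generations` | censoring cap | 10,000 | fixation is almost sure but unbounded |
| sweep grids | `u` {0.0..0.9}, `B` {2,4,10}, `pi_low` {0.1,0.45,0.8}, `L` {1,4,8,20} | — | bracket the regimes where each uncertainty axis changes the outcome |
| `n_trials` | trials per grid point | 1000 (100 with `--fast`) | binomial SE on rho_hat ≤ 0.016 at 1000 trials |

## Outcome measures

Per parameter combination: `rho_hat` (social fixations / fixated trials),
mean generations to fixation (a strength-of-selection proxy: slower
fixation = weaker selection), and the final lived generation's population
mean of `net_payoff / L`. The **social-learning ceiling** `u_c` is the
smallest grid `u` with `rho_hat < 0.01` — a minimum over grid points by
definition, not a crossing, and grid-relative: when no grid point
qualifies, the sentinel `above_grid` is returned and downstream reporting
may substitute the smallest value consistent with the grid resolution
(max grid `u` + step). Homogeneous references initialize the whole
population to one trait (which persists — there is no mutation), run 100
generations so payoffs stabilize, and average the last generation's
normalized payoff across trials. The geometric moving average used for
payoff time-series diagnostics is a trailing window-3 geometric mean,
applied to per-generation class means (social / asocial / all); a
generation with an empty class yields a missing value, not a zero, while a
zero payoff inside a window legitimately annihilates that window's mean.

## Seeding and determinism

Every trial's generator is `SeedSequence(base_seed, spawn_key=(combo_key,
trial_index))`, where `combo_key` is a CRC-32 of the canonical parameter
string. Ensembles are therefore reproducible trial-by-trial, independent of
sweep order, and any two runs with identical configuration and seed produce
byte-identical output files. Homogeneous references XOR an additional
trait tag into the key so they do not share streams with the main
ensembles.

## Numerical choices

- Softmax is computed shift-invariantly (row max subtracted before
  exponentiation), so it cannot overflow for any finite `beta`.
- Arm choice samples against the unnormalized cumulative weights; the index
  is clamped to `B - 1` to guard the rare floating-point edge where the
  sampled point rounds onto the total.
- Teacher tie-breaking adds U(0,1) jitter to the integer net payoffs:
  distinct integers are never reordered and exact ties resolve uniformly.
- Uniform `N_T`-subsets come from taking the `N_T` smallest of `N` iid
  uniform keys per child.

## What the simulator emulates — and what it does not

All inputs are synthetic by construction: the model *is* the data
generator. The bandit world idealizes real decision environments — payoffs
are binary with a single optimal option and one payoff tier below it,
environmental change is memoryless, generations are non-overlapping, and
social transmission copies latent payoff estimates rather than observable
behaviour. Passing tests therefore demonstrate the internal logic of the
evolutionary mechanism (drift neutrality, selection response to each
uncertainty axis), not quantitative predictions for any empirical system.

## Problem sizes in the checks

The bundled checks run at desk scale: 100–200 trials per parameter
combination for directional and monotonicity checks and for the ceiling
computation (binomial SE ≈ 0.03–0.05 on rho_hat), and 2000 trials for the
neutral-drift oracle (99% CI half-width 0.029). The drift check uses
`N = 20`: the fixation-probability-equals-initial-frequency identity holds
for any `N`, and a small population shortens absorption times. Ensemble
statistics at these sizes are noisier than at 1000 trials per combination
but every assertion carries an explicit binomial confidence band.

## Known limitations

- Only two payoff tiers; no payoff-variance manipulation or graded payoffs.
- No mutation, horizontal transmission, conformity, spatial or group
  structure; extensions along these axes would change the reported ceilings.
- `rho_hat` conditions on fixation; with the default cap censoring is
  practically absent in the swept regimes, but extremely weak selection
  (e.g. `pi_low` very close to `pi_high` with large `N`) can censor and is
  surfaced rather than silently absorbed.
- The ceiling is grid-relative; a bisection refinement between the last
  grid point with `rho_hat >= 0.01` and the first below it can sharpen it
  at extra simulation cost.
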