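# Methods

## Model

`culturesim` simulates discrete-time cultural evolution in a population of
`N` agents. Each agent holds exactly one cultural variant — an integer id
into a run-specific pool of `pool_size` (default 100) variants — and has no
memory of earlier variants. Learner type is homogeneous within a
population; mixed populations are out of scope.

**Variant pool.** Each payoff is `round(2x²) + 1` with
`x ~ Exponential(rate = payoff_rate)` (default rate 1). The transform gives
a heavy-tailed integer payoff distribution with a hard minimum of 1 (so
payoff-proportional choice is always well defined) and, at the defaults,
`P(payoff ≤ t) ≈ 1 − exp(−√((t−0.5)/2))`, which puts the median of the
maximum over 100 variants at ≈ 50. A fresh pool is generated every run;
payoffs are objective pool properties with no agent-specific noise.

**Update rule.** Agents update one at a time within a step, by default in
fixed index order `0..N−1` every step (an off-by-default switch re-draws
the order each step). Sequential updating means agent `i` sees the already
updated holdings of agents that moved earlier in the same step, and one
agent may serve as model for several others. Each update:

1. With probability `payoff_bias` the agent is *critical*: it draws a model
   and an innovated variant and adopts one of {own, model's, innovated}
   with probability proportional to payoff. Duplicate candidate ids keep
   separate roulette slots, so coinciding candidates add their masses —
   the only reading that keeps the three-way proportional rule total.
2. Otherwise the uncritical default decides: copier → model's variant,
   innovator → fresh uniform draw from the full pool, maintainer → own
   variant. Candidates are drawn lazily — only the branch that needs a
   model (or an innovation) draws one — which is observationally
   equivalent to eager drawing but cheaper and keeps the random stream
   interpretable.
3. Production error: with probability `error_rate` (default 0.02) the
   adopted variant is replaced by a uniform draw from the full pool,
   *including* the variant being produced. Error is applied once, after
   the choice, on both branches.

Innovation samples uniformly from the full pool with no exclusion of the
agent's current variant; the self-collision probability of `1/pool_size`
is immaterial at the default pool size.

**Model selection.** Unstructured populations select a model uniformly
from the other `N−1` agents (self excluded). Structured populations place
agents at unit spacing on a circular line (first and last agents are
neighbours) and draw a continuous `Normal(0, σ)` offset, rounded
half-away-from-zero to an integer; zero offsets — and the (for realistic
σ, essentially impossible) full-circle offsets that would wrap back to the
focal agent — are redrawn, so an agent is never its own model. Nearest-
integer rounding with zero rejection reproduces the effective
neighbourhood sizes of ≈ 6, 16, 25 and 33 distinct models over 200 draws
on a 200-ring for σ = 1, 3, 5, 7 (`estimate_neighbourhood_size` measures
this directly). Rounding ties have probability zero for continuous draws,
so the half-away convention (also used in the payoff transform, where it
matches the printed minimum of 1) is a tie-break of no numerical
consequence.

**Recording.** Gini-Simpson diversity `1 − Σ (n_v/N)²` — the plain index,
not the finite-sample-corrected one, since only the plain form attains the
`1 − 1/N` maxima (0.9, 0.95, 0.99, 0.995 for N = 10, 20, 100, 200) — and
mean variant payoff are recorded after all `N` agents have updated, plus a
`t = 0` record of the initial population so plotted trajectories start at
near-maximal diversity.

## Parameters

| parameter | symbol | default | meaning |
|---|---|---|---|
| `payoff_bias` | b | — | probability an update is critical (0–1, study grid 0, 0.2, …, 1) |
| `learner_type` | t | — | uncritical default: copier / innovator / maintainer |
| `error_rate` | e | 0.02 | probability of mis-producing (uniform pool resample) |
| `pool_size` | — | 100 | number of possible variants |
| `population_size` | N | 100 | number of agents (≥ 2; study grid 10, 20, 100, 200) |
| `structure_sigma` | σ | None | Gaussian offset sd on the ring; None = unstructured (study grid 1, 3, 5, 7 at N = 200) |
| `n_steps` | — | 200 | time steps per run |
| `payoff_rate` | λ | 1.0 | exponential rate behind payoffs |
| `seed` | — | 0 | master seed of the run's single random stream |

## Randomness and reproducibility

Each run owns one `numpy.random.Generator` seeded from `config.seed`; all
draws (pool, initial variants, branch decisions, model/innovation draws,
roulette, error) come from that stream in a fixed call order, so identical
config ⇒ bit-identical trajectory. Sweeps derive each replicate's seed as
`SeedSequence((base_seed, cell_index, replicate_index))` reduced mod 2³¹,
so any cell or single replicate is reproducible in isolation and results
are independent of execution order. The sweep CSV's JSON sidecar records
the grid, seed rule and engine version; replaying it reproduces the CSV
byte-for-byte.

## Problem sizes

The full study design is 72-cell grids at 10,000 replicates; the package
supports that scale (`run_sweep` at defaults), and its own checks run the
same grids at reduced replicate counts chosen for desk-scale runs: 500
replicates for the unstructured N = 10 orderings, 200 for the structured
N = 200, σ = 1 cell, and 10,000 for the cheap scalar quantities (pool
maxima, neighbourhood sizes). At these counts the learner-type orderings
reported by the study separate by many standard errors, so the reduced
scale does not change any qualitative conclusion; per-step means carry
standard errors in all sweep output for exactly this reason.

## Numerical and design choices

- **Fixed update order** is the simplest reading of "sequential" and makes
  small cases hand-traceable (two error-free uncritical copiers end a step
  both holding the second agent's initial variant). Re-randomised order is
  available but off by default.
- **Critical-vs-uncritical is decided per update**, not per run: a b = 0.2
  agent behaves critically on 20% of its updates in expectation.
- **Monotonicity in b plateaus.** Expected final payoff for maintainers
  rises steeply from b = 0 to b ≈ 0.4 and then flattens; at 5,000
  replicates b = 0.8 and b = 1.0 are statistically indistinguishable. The
  monotonicity check therefore asserts a significant rise at the low end
  and the absence of any significant decrease, rather than strict ordering
  of noisy sample means.
- **Degenerate inputs**: `pool_size = 1` (everyone holds variant 0),
  `n_steps = 0` (trajectory is the single initial record) and
  `population_size = 2` are all valid; `population_size = 1` is rejected
  because an agent must have at least one possible model.
- The engine exposes the payoff lookup as the single point where payoffs
  enter choice, reserved as the hook for payoff-modifying extensions
  (evaluation or learning costs); no cost model is implemented.

## What the simulations do and do not show

The generator *is* the study system — there is no external data. Runs
emulate idealised cultural transmission: one variant per agent, a closed
and static variant pool, objective payoffs, homogeneous learner types and
synchronous lockstep generations of sequential updates. Passing checks
show the engine's dynamics (drift, fixation, adaptive filtering, the
maintainer advantage under weak payoff bias and small neighbourhoods) are
internally correct and reproducible; they say nothing about real human
populations, where variant spaces are open-ended, payoffs are noisy and
subjective, and strategies mix within groups. Ring-with-Gaussian-offsets
is the only structured topology; arbitrary networks are out of scope.
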