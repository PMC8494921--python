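"""Core dynamics of the cultural-evolution engine.

A population of agents each holds one cultural variant, an integer id into a
fixed pool of ``pool_size`` variants whose payoffs are drawn once per run from
a transformed exponential distribution.  On every time step each agent, in
sequence, either behaves *critically* (with probability ``payoff_bias``:
choosing among its own, a model's and a freshly innovated variant with
probability proportional to payoff) or falls back on its uncritical default —
copy, innovate, or maintain — and finally may mis-produce the adopted variant
with probability ``error_rate``, adopting a uniform-random pool variant
instead.

Updating is sequential within a time step: agent ``i`` sees the holdings of
agents ``0..i-1`` as already updated this step.  All randomness for a run
comes from a single :class:`numpy.random.Generator` seeded from the config,
so a run is exactly reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEARNER_TYPES",
    "PayoffPool",
    "SimulationConfig",
    "PopulationState",
    "CandidateSet",
    "Trajectory",
    "generate_payoff_pool",
    "initialize_population",
    "innovate_variant",
    "critical_choice",
    "critical_choice_probabilities",
    "uncritical_choice",
    "apply_production_error",
    "update_agent",
    "run_time_step",
    "run_simulation",
]

#: Recognised uncritical default strategies.
LEARNER_TYPES = ("copier", "innovator", "maintainer")

#: Signature of a model-selection rule: (focal agent index, rng) -> model index.
ModelSelector = Callable[[int, np.random.Generator], int]


@dataclass(frozen=True)
class PayoffPool:
    """The pool of all possible variants and their integer payoffs.

    ``payoffs[v]`` is the payoff of variant id ``v``; ids run ``0..size-1``.
    Payoffs are unitless integer scores, always >= 1, and fixed for the
    duration of a run (a fresh pool is generated for every run).
    """

    payoffs: np.ndarray

    def __post_init__(self) -> None:
        payoffs = np.asarray(self.payoffs, dtype=np.int64)
        if payoffs.ndim != 1 or payoffs.size < 1:
            raise ValueError("payoff pool must be a non-empty 1-D sequence")
        if (payoffs < 1).any():
            raise ValueError("all payoffs must be >= 1")
        object.__setattr__(self, "payoffs", payoffs)

    @property
    def size(self) -> int:
        return int(self.payoffs.size)

    def __len__(self) -> int:
        return self.size

    def payoff_of(self, variant: int) -> int:
        return int(self.payoffs[variant])


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one simulation run.

    Parameters
    ----------
    payoff_bias : float in [0, 1]
        Probability ``b`` that an agent's update is critical (payoff-
        proportional choice among own, model's and innovated variant).
    learner_type : {"copier", "innovator", "maintainer"}
        Uncritical default behaviour ``t``; homogeneous across the population.
    error_rate : float in [0, 1], default 0.02
        Probability ``e`` that the adopted variant is replaced by a uniform-
        random pool variant (production/copying error).
    pool_size : int, default 100
        Number of possible variants.
    population_size : int, default 100
        Number of agents ``N``; at least 2 so every agent has a possible model.
    structure_sigma : float or None, default None
        If None the population is unstructured (models uniform over the other
        agents).  Otherwise agents sit on a ring and models are drawn via
        rounded zero-truncated Gaussian offsets with this standard deviation.
    n_steps : int, default 200
        Number of time steps.
    payoff_rate : float, default 1.0
        Rate lambda of the exponential distribution behind variant payoffs.
    seed : int, default 0
        Master seed for the run's single random stream.
    randomize_update_order : bool, default False
        If True, the within-step update order is re-drawn uniformly each step
        instead of the default fixed order ``0..N-1``.
    """

    payoff_bias: float
    learner_type: str
    error_rate: float = 0.02
    pool_size: int = 100
    population_size: int = 100
    structure_sigma: Optional[float] = None
    n_steps: int = 200
    payoff_rate: float = 1.0
    seed: int = 0
    randomize_update_order: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.payoff_bias <= 1.0:
            raise ValueError(f"payoff_bias must be in [0, 1], got {self.payoff_bias}")
        if self.learner_type not in LEARNER_TYPES:
            raise ValueError(
                f"learner_type must be one of {LEARNER_TYPES}, got {self.learner_type!r}"
            )
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError(f"error_rate must be in [0, 1], got {self.error_rate}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.structure_sigma is not None and not self.structure_sigma > 0:
            raise ValueError("structure_sigma must be positive when given")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if not self.payoff_rate > 0:
            raise ValueError("payoff_rate must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class PopulationState:
    """Ordered variant holdings of the agents at one point in time."""

    variants: np.ndarray
    pool: PayoffPool

    def __post_init__(self) -> None:
        variants = np.asarray(self.variants, dtype=np.int64)
        if variants.ndim != 1 or variants.size < 1:
            raise ValueError("variants must be a non-empty 1-D sequence")
        if (variants < 0).any() or (variants >= self.pool.size).any():
            raise ValueError("every variant id must index the pool")
        self.variants = variants

    @property
    def n_agents(self) -> int:
        return int(self.variants.size)

    def copy(self) -> "PopulationState":
        return PopulationState(self.variants.copy(), self.pool)


class CandidateSet(NamedTuple):
    """The three candidate variants of one critical update.

    Slots are (own, model, innovated); each is a ``(variant_id, payoff)``
    pair.  Duplicate variant ids are allowed and keep separate slots, so the
    roulette masses of coinciding candidates add.
    """

    own: tuple[int, int]
    model: tuple[int, int]
    innovated: tuple[int, int]

    @classmethod
    def from_ids(
        cls, own: int, model: int, innovated: int, pool: PayoffPool
    ) -> "CandidateSet":
        return cls(
            (own, pool.payoff_of(own)),
            (model, pool.payoff_of(model)),
            (innovated, pool.payoff_of(innovated)),
        )


def _payoff_transform(x: float | np.ndarray) -> np.ndarray:
    # round(2x^2) + 1 with round-half-away-from-zero; 2x^2 >= 0 so
    # floor(. + 0.5) implements it.
    return np.floor(2.0 * np.square(x) + 0.5).astype(np.int64) + 1


def generate_payoff_pool(
    pool_size: int, payoff_rate: float, rng: np.random.Generator
) -> PayoffPool:
    """Draw a fresh variant pool.

    Each payoff is ``round(2 x^2) + 1`` for ``x`` exponential with rate
    ``payoff_rate``: a long-tailed integer distribution with minimum 1 and,
    at the default rate 1 and pool size 100, a per-pool maximum typically
    around 50.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if not payoff_rate > 0:
        raise ValueError("payoff_rate must be positive")
    x = rng.exponential(scale=1.0 / payoff_rate, size=pool_size)
    return PayoffPool(_payoff_transform(x))


def initialize_population(
    config: SimulationConfig, pool: PayoffPool, rng: np.random.Generator
) -> PopulationState:
    """Assign each agent an independent uniform-random variant (with replacement)."""
    variants = rng.integers(0, pool.size, size=config.population_size, dtype=np.int64)
    return PopulationState(variants, pool)


def innovate_variant(pool: PayoffPool, rng: np.random.Generator) -> int:
    """Draw a uniform-random variant id from the full pool.

    Innovation samples from all possible variants, so the innovated variant
    may coincide with the agent's current or the model's variant.
    """
    if pool.size < 1:
        raise ValueError("pool must be non-empty")
    return int(rng.integers(0, pool.size))


def critical_choice_probabilities(candidates: CandidateSet) -> np.ndarray:
    """Exact slot probabilities of :func:`critical_choice` (own, model, innovated)."""
    weights = np.array(
        [candidates.own[1], candidates.model[1], candidates.innovated[1]], dtype=float
    )
    if (weights <= 0).any():
        raise ValueError("all candidate payoffs must be >= 1")
    return weights / weights.sum()


def critical_choice(candidates: CandidateSet, rng: np.random.Generator) -> int:
    """Payoff-proportional roulette over the three candidate slots.

    Each slot is chosen with probability ``payoff / (p_s + p_m + p_n)``;
    e.g. payoffs (10, 6, 4) give the first slot probability 10/20 = 0.5.
    """
    (own_id, p_s), (model_id, p_m), (innov_id, p_n) = candidates
    if p_s <= 0 or p_m <= 0 or p_n <= 0:
        raise ValueError("all candidate payoffs must be >= 1")
    r = rng.random() * (p_s + p_m + p_n)
    if r < p_s:
        return own_id
    if r < p_s + p_m:
        return model_id
    return innov_id


def uncritical_choice(learner_type: str, candidates: CandidateSet) -> int:
    """Resolve an uncritical update: the default strategy picks its slot.

    Payoffs are never inspected: a maintainer keeps its own variant, a copier
    takes the model's, an innovator takes the innovated one.
    """
    if learner_type == "maintainer":
        return candidates.own[0]
    if learner_type == "copier":
        return candidates.model[0]
    if learner_type == "innovator":
        return candidates.innovated[0]
    raise ValueError(f"unknown learner type {learner_type!r}")


def apply_production_error(
    chosen: int, error_rate: float, pool: PayoffPool, rng: np.random.Generator
) -> int:
    """With probability ``error_rate`` replace the adopted variant.

    The replacement is uniform over the full pool, including the variant the
    agent was trying to produce.
    """
    if error_rate > 0.0 and rng.random() < error_rate:
        return int(rng.integers(0, pool.size))
    return chosen


def update_agent(
    agent_index: int,
    state: PopulationState,
    config: SimulationConfig,
    model_selector: ModelSelector,
    rng: np.random.Generator,
) -> int:
    """Run one agent's update and write the adopted variant into ``state``.

    With probability ``payoff_bias`` the update is critical: a model and an
    innovated variant are drawn and the adopted variant comes from the
    payoff-proportional roulette over (own, model's, innovated).  Otherwise
    the uncritical default applies, drawing only the candidate it needs
    (copier: a model; innovator: an innovation; maintainer: nothing).
    Production error is applied last, to whichever variant was chosen.
    """
    variants = state.variants
    pool = state.pool
    b = config.payoff_bias
    if rng.random() < b:
        model_index = model_selector(agent_index, rng)
        candidates = CandidateSet.from_ids(
            int(variants[agent_index]),
            int(variants[model_index]),
            innovate_variant(pool, rng),
            pool,
        )
        chosen = critical_choice(candidates, rng)
    else:
        learner_type = config.learner_type
        if learner_type == "copier":
            chosen = int(variants[model_selector(agent_index, rng)])
        elif learner_type == "innovator":
            chosen = innovate_variant(pool, rng)
        else:  # maintainer
            chosen = int(variants[agent_index])
    chosen = apply_production_error(chosen, config.error_rate, pool, rng)
    variants[agent_index] = chosen
    return chosen


def run_time_step(
    state: PopulationState,
    config: SimulationConfig,
    model_selector: ModelSelector,
    rng: np.random.Generator,
) -> PopulationState:
    """Update every agent once, sequentially, in place.

    The default order is the fixed index order ``0..N-1`` every step; a later
    agent can therefore copy from an earlier agent whose variant already
    changed this step, and the same model may serve multiple agents.  With
    ``randomize_update_order`` the order is a fresh uniform permutation.
    """
    if config.randomize_update_order:
        order = rng.permutation(state.n_agents)
    else:
        order = range(state.n_agents)
    for agent_index in order:
        update_agent(int(agent_index), state, config, model_selector, rng)
    return state


@dataclass
class Trajectory:
    """Per-step population summaries of one run.

    Index 0 is the initial (pre-update) state; index ``t`` is the end of time
    step ``t``.  ``diversity`` is the Gini-Simpson index, ``mean_payoff`` the
    population mean of the agents' variant payoffs.
    """

    config: SimulationConfig
    pool: PayoffPool
    diversity: np.ndarray
    mean_payoff: np.ndarray
    final_state: PopulationState = field(repr=False)

    @property
    def time_steps(self) -> np.ndarray:
        return np.arange(self.diversity.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_step": self.time_steps,
                "diversity": self.diversity,
                "mean_payoff": self.mean_payoff,
            }
        )


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run one complete simulation: fresh pool, random start, n_steps updates.

    Records diversity and mean payoff at t=0 (the initial population) and at
    the end of each time step.  Bit-identical output for identical config.
    """
    from .metrics import gini_simpson, mean_payoff
    from .neighbourhoods import make_model_selector

    rng = np.random.default_rng(config.seed)
    pool = generate_payoff_pool(config.pool_size, config.payoff_rate, rng)
    state = initialize_population(config, pool, rng)
    selector = make_model_selector(config)

    n_records = config.n_steps + 1
    diversity = np.empty(n_records)
    payoff = np.empty(n_records)
    diversity[0] = gini_simpson(state.variants)
    payoff[0] = mean_payoff(state.variants, pool)
    for t in range(1, n_records):
        run_time_step(state, config, selector, rng)
        diversity[t] = gini_simpson(state.variants)
        payoff[t] = mean_payoff(state.variants, pool)
    return Trajectory(config, pool, diversity, payoff, state)
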