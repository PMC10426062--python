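"""One evolutionary trial: lifetimes, reproduction, transmission, fixation.

A trial starts from a population whose social-learning trait is assigned by
an independent fair coin per agent. Each generation, all agents perform
``lifespan`` softmax-guided behaviour choices (agents act independently, so
the inner loop is vectorized across the population without changing the
model). Then N parents are drawn with replacement in proportion to lifetime
net payoff, each child inherits its parent's trait without mutation, social
children copy beliefs from a payoff-biased teacher sample of the parent
generation, the parents die, and the environment may shift its optimal
behaviour. The trial ends when the child generation is homogeneous in the
trait (fixation) or a generation cap is hit (censoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .agents import AgentState, CognitionConfig
from .environment import EnvironmentConfig, EnvironmentState, init_environment, maybe_change_optimal

__all__ = [
    "SimConfig",
    "Population",
    "TrialResult",
    "SOCIAL_FIXATION",
    "ASOCIAL_FIXATION",
    "CENSORED",
    "run_generation",
    "select_reproducers",
    "select_teacher",
    "step_intergenerational",
    "check_fixation",
    "run_trial",
]

SOCIAL_FIXATION = "social_fixation"
ASOCIAL_FIXATION = "asocial_fixation"
CENSORED = "censored"


@dataclass(frozen=True)
class SimConfig:
    """Trial-level configuration: population size, cognition, environment."""

    n_agents: int
    env: EnvironmentConfig
    cognition: CognitionConfig = field(default_factory=CognitionConfig)
    max_generations: int = 10_000
    seed: Optional[int] = None
    record_timeseries: bool = False

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError(f"n_agents must be >= 2, got {self.n_agents}")
        if self.cognition.n_teachers > self.n_agents:
            raise ValueError(
                f"n_teachers ({self.cognition.n_teachers}) cannot exceed "
                f"n_agents ({self.n_agents}) when sampling without replacement"
            )
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


class Population:
    """Array-backed population: row i holds agent i's state.

    Fields mirror :class:`~banditevo.agents.AgentState` stacked across the
    population: ``social`` (N,), ``est`` (N, B), ``count`` (N, B) and
    ``net`` (N,).
    """

    __slots__ = ("social", "est", "count", "net")

    def __init__(self, social: np.ndarray, est: np.ndarray, count: np.ndarray, net: np.ndarray):
        self.social = social
        self.est = est
        self.count = count
        self.net = net

    @classmethod
    def naive(cls, social: np.ndarray, n_arms: int) -> "Population":
        """All-naive population with the given trait vector."""
        social = np.asarray(social, dtype=np.int8)
        n = social.shape[0]
        return cls(
            social=social,
            est=np.zeros((n, n_arms)),
            count=np.zeros((n, n_arms), dtype=np.int64),
            net=np.zeros(n, dtype=np.int64),
        )

    @classmethod
    def from_agents(cls, agents: list[AgentState]) -> "Population":
        return cls(
            social=np.array([int(a.social) for a in agents], dtype=np.int8),
            est=np.array([a.est_payoff for a in agents], dtype=float),
            count=np.array([a.count for a in agents], dtype=np.int64),
            net=np.array([a.net_payoff for a in agents], dtype=np.int64),
        )

    def agent(self, i: int) -> AgentState:
        """A copy of agent i as a standalone :class:`AgentState`."""
        return AgentState(
            social=bool(self.social[i]),
            est_payoff=self.est[i].copy(),
            count=self.count[i].copy(),
            net_payoff=int(self.net[i]),
        )

    @property
    def size(self) -> int:
        return self.social.shape[0]

    @property
    def n_social(self) -> int:
        return int(self.social.sum())


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one evolutionary trial.

    ``generations`` counts completed (lived) parent generations at the
    moment fixation was detected on their children; a population that is
    homogeneous at initialization fixates at generation 0.
    ``mean_normalized_payoff`` is the final lived generation's population
    mean of net_payoff / lifespan (NaN if no generation was lived).
    """

    outcome: str
    generations: int
    mean_normalized_payoff: float
    timeseries: Optional[pd.DataFrame] = None


def run_generation(
    pop: Population,
    env: EnvironmentState,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Population:
    """Let every agent live one generation of ``lifespan`` time steps.

    Each step, every agent draws a behaviour from its softmax distribution,
    receives a Bernoulli payoff, and updates its count and running-mean
    estimate for that behaviour. The environment does not change within a
    generation. Mutates and returns ``pop``.
    """
    n, b = pop.est.shape
    beta = cfg.cognition.beta
    pi = cfg.env.arm_payoff_probs(env.optimal_arm)
    rows = np.arange(n)
    est, count = pop.est, pop.count
    for _ in range(cfg.env.lifespan):
        z = beta * est
        z -= z.max(axis=1, keepdims=True)
        w = np.exp(z)
        cum = np.cumsum(w, axis=1)
        r = rng.random(n) * cum[:, -1]
        choice = np.minimum((cum < r[:, None]).sum(axis=1), b - 1)
        payoff = (rng.random(n) < pi[choice]).astype(np.int64)
        count[rows, choice] += 1
        e = est[rows, choice]
        est[rows, choice] = e + (payoff - e) / count[rows, choice]
        pop.net += payoff
    return pop


def select_reproducers(pop: Population, rng: np.random.Generator) -> np.ndarray:
    """N independent parent draws with replacement, fitness-proportional.

    Each draw picks agent i with probability net_i / sum(net); when every
    net payoff is zero (possible with pi_low = 0 and short lifespans) the
    proportional rule is undefined and selection falls back to uniform.
    """
    n = pop.size
    if n == 0:
        raise ValueError("empty population")
    total = int(pop.net.sum())
    if total == 0:
        return rng.integers(0, n, size=n)
    cum = np.cumsum(pop.net)
    return np.searchsorted(cum, rng.random(n) * total, side="right")


def _sample_teachers(
    pop: Population, n_teachers: int, n_children: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized teacher choice for ``n_children`` social newborns.

    Each child independently samples n_teachers distinct prospective
    teachers uniformly from the parent population, then takes the one with
    the greatest net payoff, ties broken uniformly. The uniform random
    subset comes from the smallest-keys trick; adding U(0,1) jitter to the
    integer net payoffs breaks ties uniformly without reordering distinct
    values.
    """
    n = pop.size
    keys = rng.random((n_children, n))
    cand = np.argpartition(keys, n_teachers - 1, axis=1)[:, :n_teachers]
    score = pop.net[cand] + rng.random((n_children, n_teachers))
    return cand[np.arange(n_children), score.argmax(axis=1)]


def select_teacher(pop: Population, n_teachers: int, rng: np.random.Generator) -> int:
    """One child's teacher: best net payoff among a uniform sample of
    ``n_teachers`` distinct candidates, ties broken uniformly."""
    if n_teachers > pop.size:
        raise ValueError(f"n_teachers ({n_teachers}) exceeds population size ({pop.size})")
    return int(_sample_teachers(pop, n_teachers, 1, rng)[0])


def step_intergenerational(
    pop: Population,
    env: EnvironmentState,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[Population, EnvironmentState]:
    """Reproduce, transmit, die off, then maybe shift the environment.

    Children inherit the trait without mutation. Social children copy their
    teacher's estimates with counts clamped to {0, 1}; asocial children are
    naive. The environmental change process runs last, so inherited beliefs
    can already be outdated when the children start to live.
    """
    parents = select_reproducers(pop, rng)
    child_social = pop.social[parents]
    child = Population.naive(child_social, pop.est.shape[1])
    social_rows = np.flatnonzero(child_social == 1)
    if social_rows.size:
        teachers = _sample_teachers(pop, cfg.cognition.n_teachers, social_rows.size, rng)
        child.est[social_rows] = pop.est[teachers]
        child.count[social_rows] = (pop.count[teachers] > 0).astype(np.int64)
    maybe_change_optimal(env, cfg.env, rng)
    return child, env


def check_fixation(pop: Population) -> Optional[str]:
    """Fixation state of the trait: all-social, all-asocial, or neither."""
    s = pop.n_social
    if s == pop.size:
        return SOCIAL_FIXATION
    if s == 0:
        return ASOCIAL_FIXATION
    return None


def run_trial(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    init_social: Optional[np.ndarray] = None,
) -> TrialResult:
    """Run one trial to fixation (or to the generation cap).

    ``init_social`` overrides the default fair-coin trait initialization;
    it is the hook used for homogeneous reference populations and tests.
    Fixation is checked on each newborn child generation (including the
    initial one) before it lives.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    env = init_environment(cfg.env, rng)
    if init_social is None:
        social = rng.integers(0, 2, size=cfg.n_agents).astype(np.int8)
    else:
        social = np.asarray(init_social, dtype=np.int8)
        if social.shape[0] != cfg.n_agents:
            raise ValueError("init_social length must equal n_agents")
    pop = Population.naive(social, cfg.env.n_arms)

    records: list[tuple] = []
    outcome = check_fixation(pop)
    generation = 0
    last_mean = float("nan")
    while outcome is None and generation < cfg.max_generations:
        run_generation(pop, env, cfg, rng)
        generation += 1
        norm = pop.net / cfg.env.lifespan
        last_mean = float(norm.mean())
        if cfg.record_timeseries:
            soc = pop.social == 1
            records.append(
                (
                    generation,
                    last_mean,
                    float(norm[soc].mean()) if soc.any() else np.nan,
                    float(norm[~soc].mean()) if (~soc).any() else np.nan,
                    int(soc.sum()),
                    env.changed_this_generation,
                )
            )
        pop, env = step_intergenerational(pop, env, cfg, rng)
        outcome = check_fixation(pop)
    if outcome is None:
        outcome = CENSORED

    timeseries = None
    if cfg.record_timeseries:
        timeseries = pd.DataFrame(
            records,
            columns=[
                "generation",
                "mean_payoff",
                "mean_payoff_social",
                "mean_payoff_asocial",
                "n_social",
                "env_changed",
            ],
        )
    return TrialResult(
        outcome=outcome,
        generations=generation,
        mean_normalized_payoff=last_mean,
        timeseries=timeseries,
    )
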