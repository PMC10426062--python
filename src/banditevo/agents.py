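"""Agent state and within-lifetime cognition.

Every agent learns individually by softmax (Boltzmann) exploration over its
running-mean payoff estimates. Agents carrying the heritable social-learning
trait additionally seed those estimates at birth from a teacher of the
previous generation; asocial learners start life naive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgentState",
    "CognitionConfig",
    "softmax_probabilities",
    "choose_behaviour",
    "update_estimate",
    "init_naive_agent",
    "transmit_from_teacher",
]


@dataclass(frozen=True)
class CognitionConfig:
    """Cognitive constants held fixed within a simulation.

    Parameters
    ----------
    beta:
        Softmax greediness (>= 0). Large beta concentrates choice on the
        behaviour with the highest estimated payoff; beta = 0 is uniform
        exploration.
    n_teachers:
        Number of prospective teachers N_T a newborn social learner
        samples before picking the best-paying one.
    """

    beta: float = 10.0
    n_teachers: int = 5

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.n_teachers < 1:
            raise ValueError(f"n_teachers must be >= 1, got {self.n_teachers}")


@dataclass
class AgentState:
    """One agent's heritable trait and learned statistics.

    Attributes
    ----------
    social:
        Heritable social-learning trait s (True = social learner).
    est_payoff:
        Length-B running means of observed payoffs per behaviour; an arm
        never observed has estimate 0 (zero encodes "no information",
        matching count 0).
    count:
        Length-B observation counts per behaviour.
    net_payoff:
        Cumulative payoff this generation (integer; payoffs are 0/1).
    """

    social: bool
    est_payoff: np.ndarray
    count: np.ndarray
    net_payoff: int = 0

    @property
    def n_arms(self) -> int:
        return self.est_payoff.shape[0]


def softmax_probabilities(est_payoff: np.ndarray, beta: float) -> np.ndarray:
    """Boltzmann choice distribution: P(b) proportional to exp(beta * est[b]).

    Computed shift-invariantly (max subtracted before exponentiation) so it
    is overflow-safe for any finite beta and estimates.
    """
    est = np.asarray(est_payoff, dtype=float)
    if est.size == 0:
        raise ValueError("empty estimate vector")
    if not np.all(np.isfinite(est)):
        raise ValueError("estimates must be finite")
    z = beta * est
    w = np.exp(z - z.max())
    return w / w.sum()


def choose_behaviour(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an arm index from a choice distribution."""
    probs = np.asarray(probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("probs is not a probability distribution")
    cum = np.cumsum(probs)
    idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
    return min(idx, probs.size - 1)


def update_estimate(agent: AgentState, arm: int, payoff: int) -> AgentState:
    """Record one observed payoff for ``arm`` via moving arithmetic averaging.

    The count is incremented first; the estimate then moves toward the
    payoff by 1/count, so after k observations from a naive start the
    estimate is exactly the arithmetic mean of the k payoffs. The agent's
    net payoff accumulates. Mutates and returns ``agent``.
    """
    if payoff not in (0, 1):
        raise ValueError(f"payoff must be 0 or 1, got {payoff}")
    agent.count[arm] += 1
    agent.est_payoff[arm] += (payoff - agent.est_payoff[arm]) / agent.count[arm]
    agent.net_payoff += payoff
    return agent


def init_naive_agent(n_arms: int, social: bool) -> AgentState:
    """A newborn with no payoff information: all estimates and counts zero."""
    if n_arms < 1:
        raise ValueError(f"n_arms must be >= 1, got {n_arms}")
    return AgentState(
        social=social,
        est_payoff=np.zeros(n_arms),
        count=np.zeros(n_arms, dtype=np.int64),
        net_payoff=0,
    )


def transmit_from_teacher(teacher: AgentState) -> AgentState:
    """Build a newborn social learner from a teacher's lifetime statistics.

    The child adopts the teacher's mean-payoff estimates verbatim but
    treats each informed arm as a single observation: its count is 1 where
    the teacher has at least one observation and 0 otherwise. Weighting
    transmitted information as one observation keeps social learners
    flexible — their next individual observation of an arm carries weight
    1/2, so outdated inherited estimates are quickly revised.
    """
    return AgentState(
        social=True,
        est_payoff=teacher.est_payoff.copy(),
        count=(teacher.count > 0).astype(np.int64),
        net_payoff=0,
    )
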