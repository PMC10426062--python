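"""Multi-armed Bernoulli bandit environment with stochastic regime shifts.

The world affords ``n_arms`` behaviours. Exactly one of them (the *optimal*
behaviour) pays off 1 with probability ``pi_high``; every other behaviour
pays off 1 with probability ``pi_low``. Between generations the identity of
the optimal behaviour changes with probability ``u`` (the environmental
variability), the new optimum being drawn uniformly from the other arms.

Arms are indexed 0..n_arms-1 internally; user-facing tables report 1-based
indices, matching the b in 1..B convention of the behavioural literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnvironmentConfig",
    "EnvironmentState",
    "init_environment",
    "draw_payoff",
    "maybe_change_optimal",
]


@dataclass(frozen=True)
class EnvironmentConfig:
    """Fixed environmental parameters of one simulation.

    Parameters
    ----------
    n_arms:
        Selection-set size B, the number of available behaviours. Must be
        >= 1; evolutionary experiments use B >= 2 (B = 1 is allowed for
        degenerate-dynamics testing only).
    pi_high:
        Expected payoff of the optimal behaviour, in [0, 1].
    pi_low:
        Expected payoff of every non-optimal behaviour, in [0, 1]. The
        payoff ambiguity is ``pi_high - pi_low``; it shrinks (ambiguity
        grows) as pi_low approaches pi_high.
    u:
        Per-generation probability that a new optimal behaviour is drawn
        (the current optimum is excluded from redraw).
    lifespan:
        Effective lifespan L: the number of behaviour/learning
        opportunities each agent gets per generation.
    """

    n_arms: int
    pi_high: float = 0.9
    pi_low: float = 0.1
    u: float = 0.1
    lifespan: int = 4

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise ValueError(f"n_arms must be >= 1, got {self.n_arms}")
        for name in ("pi_high", "pi_low", "u"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.pi_low > self.pi_high:
            raise ValueError(
                f"pi_low ({self.pi_low}) must not exceed pi_high ({self.pi_high})"
            )
        if self.lifespan < 1:
            raise ValueError(f"lifespan must be >= 1, got {self.lifespan}")
        if self.n_arms == 1 and self.u > 0:
            raise ValueError("u > 0 requires n_arms >= 2 (no alternative arm exists)")

    @property
    def ambiguity(self) -> float:
        """Payoff gap pi_high - pi_low (small gap = high ambiguity)."""
        return self.pi_high - self.pi_low

    def arm_payoff_probs(self, optimal_arm: int) -> np.ndarray:
        """Length-n_arms vector of Bernoulli success probabilities."""
        probs = np.full(self.n_arms, self.pi_low)
        probs[optimal_arm] = self.pi_high
        return probs


@dataclass
class EnvironmentState:
    """Mutable environment state: which arm is currently optimal.

    ``changed_this_generation`` flags whether the optimum moved at the most
    recent generation boundary; it exists to annotate time series and plays
    no role in the dynamics.
    """

    optimal_arm: int
    changed_this_generation: bool = field(default=False)


def init_environment(config: EnvironmentConfig, rng: np.random.Generator) -> EnvironmentState:
    """Draw the initial optimal behaviour uniformly at random."""
    return EnvironmentState(optimal_arm=int(rng.integers(config.n_arms)))


def draw_payoff(
    env: EnvironmentState,
    config: EnvironmentConfig,
    arm: int,
    rng: np.random.Generator,
) -> int:
    """Bernoulli payoff for performing ``arm`` once: 1 w.p. pi_high if the
    arm is optimal, else 1 w.p. pi_low."""
    if not 0 <= arm < config.n_arms:
        raise IndexError(f"arm {arm} out of range for n_arms={config.n_arms}")
    p = config.pi_high if arm == env.optimal_arm else config.pi_low
    return int(rng.random() < p)


def maybe_change_optimal(
    env: EnvironmentState,
    config: EnvironmentConfig,
    rng: np.random.Generator,
) -> EnvironmentState:
    """Apply the between-generation change process in place.

    With probability ``u`` a new optimal arm is drawn uniformly from the
    n_arms - 1 arms other than the current one, and
    ``changed_this_generation`` is set; otherwise the state is unchanged
    and the flag cleared. Called exactly once per generation boundary,
    after reproduction and die-off.
    """
    if rng.random() < config.u:
        if config.n_arms < 2:
            raise ValueError("cannot change optimal arm with a single arm")
        # uniform over the other n_arms - 1 arms
        shift = int(rng.integers(1, config.n_arms))
        env.optimal_arm = (env.optimal_arm + shift) % config.n_arms
        env.changed_this_generation = True
    else:
        env.changed_this_generation = False
    return env
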