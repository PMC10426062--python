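"""Parameter sweeps, ensemble statistics and the social-learning ceiling.

An *ensemble* is a batch of independent trials at one parameter
combination; its headline statistic is the social-learning fixation
frequency rho_hat — the fraction of fixated trials that ended all-social.
A *sweep* enumerates a grid over the four uncertainty axes (u, B, pi_low,
L) and tabulates rho_hat, mean generations to fixation, and mean normalized
payoff per combination. The *social-learning ceiling* u_c is the smallest
grid value of u at which rho_hat falls below 1%.

Seeding: every trial draws its generator from
``SeedSequence(base_seed, spawn_key=(combo_key, trial_index))`` where
``combo_key`` is a CRC-32 of the canonical parameter string, so each
combination's trials are reproducible independently of sweep order.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .agents import CognitionConfig
from .dynamics import (
    ASOCIAL_FIXATION,
    CENSORED,
    SOCIAL_FIXATION,
    Population,
    SimConfig,
    run_generation,
    run_trial,
    step_intergenerational,
)
from .environment import EnvironmentConfig, init_environment

__all__ = [
    "SweepSpec",
    "EnsembleSummary",
    "CeilingResult",
    "ABOVE_GRID",
    "make_sim_config",
    "run_ensemble",
    "social_learning_ceiling",
    "ceiling_scan",
    "homogeneous_reference",
    "geometric_moving_average",
    "run_sweep",
]

logger = logging.getLogger(__name__)

ABOVE_GRID = "above_grid"

_REFERENCE_GENERATIONS = 100  # burn-in length for homogeneous reference payoffs


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for a full sweep over the four uncertainty axes.

    Defaults cover the standard design: environmental variability u from 0
    to 0.9, selection-set sizes B in {2, 4, 10}, non-optimal payoffs pi_low
    in {0.1, 0.45, 0.8} against a fixed pi_high = 0.9, and lifespans L in
    {1, 4, 8, 20}; 1000 trials per combination with N = 100 agents,
    softmax greediness beta = 10 and N_T = 5 prospective teachers.
    """

    u: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(10))
    B: tuple[int, ...] = (2, 4, 10)
    pi_low: tuple[float, ...] = (0.1, 0.45, 0.8)
    L: tuple[int, ...] = (1, 4, 8, 20)
    pi_high: float = 0.9
    N: int = 100
    N_T: int = 5
    beta: float = 10.0
    n_trials: int = 1000
    seed: int = 0
    max_generations: int = 10_000

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("u", "B", "pi_low", "L"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid '{name}' is empty")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SweepSpec":
        """Load a spec from YAML; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for grid in ("u", "B", "pi_low", "L"):
            if grid in raw and not isinstance(raw[grid], (list, tuple)):
                raw[grid] = [raw[grid]]
            if grid in raw:
                raw[grid] = tuple(raw[grid])
        return cls(**raw)

    def combinations(self) -> list[tuple[float, int, float, int]]:
        """All (u, B, pi_low, L) grid points, each exactly once."""
        return list(itertools.product(self.u, self.B, self.pi_low, self.L))


@dataclass(frozen=True)
class EnsembleSummary:
    """Aggregates over one parameter combination's fixated trials.

    ``rho_hat`` is social fixations / fixated trials; censored trials are
    excluded from both numerator and denominator and counted separately.
    """

    u: float
    B: int
    pi_low: float
    L: int
    pi_high: float
    N: int
    N_T: int
    beta: float
    n_trials: int
    rho_hat: float
    mean_generations: float
    mean_normalized_payoff: float
    n_censored: int


@dataclass(frozen=True)
class CeilingResult:
    """Ceiling estimate for one (B, pi_low, L) slice of a sweep."""

    B: int
    pi_low: float
    L: int
    u_grid: tuple[float, ...]
    rho_by_u: dict[float, float]
    u_c: Union[float, str]


def make_sim_config(
    u: float,
    B: int,
    pi_low: float,
    L: int,
    pi_high: float = 0.9,
    N: int = 100,
    N_T: int = 5,
    beta: float = 10.0,
    max_generations: int = 10_000,
    record_timeseries: bool = False,
) -> SimConfig:
    """Assemble a trial configuration from sweep-level scalars."""
    return SimConfig(
        n_agents=N,
        env=EnvironmentConfig(n_arms=B, pi_high=pi_high, pi_low=pi_low, u=u, lifespan=L),
        cognition=CognitionConfig(beta=beta, n_teachers=N_T),
        max_generations=max_generations,
        record_timeseries=record_timeseries,
    )


def _combo_key(cfg: SimConfig) -> int:
    """Stable 32-bit key identifying a parameter combination."""
    env, cog = cfg.env, cfg.cognition
    canon = (
        f"u={env.u!r},B={env.n_arms!r},pi_low={env.pi_low!r},L={env.lifespan!r},"
        f"pi_high={env.pi_high!r},N={cfg.n_agents!r},N_T={cog.n_teachers!r},beta={cog.beta!r}"
    )
    return zlib.crc32(canon.encode())


def _trial_rng(base_seed: int, combo_key: int, trial: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(combo_key, trial)))


def run_ensemble(cfg: SimConfig, n_trials: int, base_seed: int) -> EnsembleSummary:
    """Run ``n_trials`` independent trials and aggregate their fates."""
    key = _combo_key(cfg)
    n_social = n_asocial = n_censored = 0
    generations: list[int] = []
    payoffs: list[float] = []
    for t in range(n_trials):
        result = run_trial(cfg, rng=_trial_rng(base_seed, key, t))
        if result.outcome == CENSORED:
            n_censored += 1
            continue
        if result.outcome == SOCIAL_FIXATION:
            n_social += 1
        else:
            n_asocial += 1
        generations.append(result.generations)
        if np.isfinite(result.mean_normalized_payoff):
            payoffs.append(result.mean_normalized_payoff)
    n_fixated = n_social + n_asocial
    if n_censored > 0.01 * n_trials:
        logger.warning(
            "combination u=%s B=%s pi_low=%s L=%s: %d/%d trials censored at the "
            "generation cap; rho_hat excludes them",
            cfg.env.u, cfg.env.n_arms, cfg.env.pi_low, cfg.env.lifespan,
            n_censored, n_trials,
        )
    return EnsembleSummary(
        u=cfg.env.u,
        B=cfg.env.n_arms,
        pi_low=cfg.env.pi_low,
        L=cfg.env.lifespan,
        pi_high=cfg.env.pi_high,
        N=cfg.n_agents,
        N_T=cfg.cognition.n_teachers,
        beta=cfg.cognition.beta,
        n_trials=n_trials,
        rho_hat=n_social / n_fixated if n_fixated else float("nan"),
        mean_generations=float(np.mean(generations)) if generations else float("nan"),
        mean_normalized_payoff=float(np.mean(payoffs)) if payoffs else float("nan"),
        n_censored=n_censored,
    )


def social_learning_ceiling(rho_by_u: dict[float, float]) -> Union[float, str]:
    """Smallest grid u at which social learning fixates in < 1% of trials.

    The definition is the minimum qualifying grid point, not a crossing:
    if the lowest u already has rho_hat < 0.01 it is returned. When no
    grid point qualifies the ceiling lies above the grid and the sentinel
    :data:`ABOVE_GRID` is returned.
    """
    if not rho_by_u:
        raise ValueError("empty rho_by_u map")
    for u in sorted(rho_by_u):
        if rho_by_u[u] < 0.01:
            return u
    return ABOVE_GRID


def ceiling_scan(spec: SweepSpec) -> list[CeilingResult]:
    """Estimate the ceiling on the spec's u grid for every (B, pi_low, L)."""
    results = []
    for B, pi_low, L in itertools.product(spec.B, spec.pi_low, spec.L):
        rho_by_u: dict[float, float] = {}
        for u in spec.u:
            cfg = make_sim_config(
                u, B, pi_low, L,
                pi_high=spec.pi_high, N=spec.N, N_T=spec.N_T, beta=spec.beta,
                max_generations=spec.max_generations,
            )
            rho_by_u[u] = run_ensemble(cfg, spec.n_trials, spec.seed).rho_hat
        results.append(
            CeilingResult(
                B=B, pi_low=pi_low, L=L,
                u_grid=tuple(sorted(rho_by_u)),
                rho_by_u=rho_by_u,
                u_c=social_learning_ceiling(rho_by_u),
            )
        )
    return results


def homogeneous_reference(
    cfg: SimConfig,
    trait: str,
    n_trials: int,
    base_seed: int,
    n_generations: int = _REFERENCE_GENERATIONS,
) -> float:
    """Expected normalized payoff of an all-social or all-asocial population.

    Each trial initializes every agent with the same trait (which persists:
    there is no mutation), lives ``n_generations`` generations with the
    usual reproduction/transmission/environment dynamics, and reports the
    last generation's population mean of net_payoff / lifespan. Returns
    the mean over trials.
    """
    if trait not in ("social", "asocial"):
        raise ValueError(f"trait must be 'social' or 'asocial', got {trait!r}")
    s_value = 1 if trait == "social" else 0
    key = zlib.crc32(f"reference:{trait}".encode()) ^ _combo_key(cfg)
    means = np.empty(n_trials)
    for t in range(n_trials):
        rng = _trial_rng(base_seed, key, t)
        env = init_environment(cfg.env, rng)
        pop = Population.naive(np.full(cfg.n_agents, s_value, dtype=np.int8), cfg.env.n_arms)
        for g in range(n_generations):
            run_generation(pop, env, cfg, rng)
            if g < n_generations - 1:
                pop, env = step_intergenerational(pop, env, cfg, rng)
        means[t] = pop.net.mean() / cfg.env.lifespan
    return float(means.mean())


def geometric_moving_average(series, window: int) -> np.ndarray:
    """Trailing geometric mean over a fixed window.

    Output element t (0-based) is the window-th root of the product of
    ``series[t : t + window]``; the first ``window - 1`` input positions
    have no defined value and are omitted, so the output is shorter than
    the input by ``window - 1``. Any zero in a window makes that output 0.
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if x.ndim != 1 or x.size < window:
        raise ValueError("series must be 1-D with length >= window")
    if np.any(x < 0):
        raise ValueError("geometric moving average requires non-negative input")
    windows = np.lib.stride_tricks.sliding_window_view(x, window)
    return windows.prod(axis=1) ** (1.0 / window)


def run_sweep(spec: SweepSpec, out_dir: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """Run every grid combination and return the tidy result table.

    One row per (u, B, pi_low, L) with the fixed parameters, rho_hat, mean
    generations to fixation, mean normalized payoff and the censoring
    count. If ``out_dir`` is given, writes ``sweep.csv`` plus a
    ``manifest.json`` recording the spec, seed and package version.
    """
    combos = spec.combinations()
    rows = []
    for i, (u, B, pi_low, L) in enumerate(combos, 1):
        cfg = make_sim_config(
            u, B, pi_low, L,
            pi_high=spec.pi_high, N=spec.N, N_T=spec.N_T, beta=spec.beta,
            max_generations=spec.max_generations,
        )
        summary = run_ensemble(cfg, spec.n_trials, spec.seed)
        logger.info(
            "[%d/%d] u=%.2f B=%d pi_low=%.2f L=%d: rho_hat=%.3f "
            "mean_gens=%.1f censored=%d",
            i, len(combos), u, B, pi_low, L,
            summary.rho_hat, summary.mean_generations, summary.n_censored,
        )
        rows.append(dataclasses.asdict(summary))
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "sweep.csv", index=False)
        from . import __version__

        manifest = {"spec": dataclasses.asdict(spec), "seed": spec.seed, "version": __version__}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return table
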